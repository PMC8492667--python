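"""Discrete-event turbidostat simulator and growth-rate estimation.

Mirrors the bioreactor platform's behaviour: cultures either grow freely
(batch), grow to an upper optical density and are instantaneously diluted to
a lower one (grow-and-dilute), or are held at exactly constant density with
the dilution rate tracking the population growth rate (constant_od).  The
growth rate is recovered from OD logs by fitting a line to log(OD) versus
time within each inter-dilution segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .models import (
    DiffParams,
    GaudiParams,
    GaudiState,
    IntegrationError,
    LightProgram,
    Trajectory,
    TwoReactorParams,
    ValidationError,
)

__all__ = [
    "TurbidostatConfig",
    "CultureLog",
    "DifferentiationCulture",
    "TwoReactorCulture",
    "GaudiCulture",
    "run_turbidostat",
    "estimate_growth_rate",
]

logger = logging.getLogger(__name__)

# OD units per unit total concentration; the platform's OD is treated as
# directly proportional to total (live + dead) biomass concentration.
OD_PER_CONCENTRATION = 1.0


@dataclass(frozen=True)
class TurbidostatConfig:
    od_upper: float = 0.6
    od_lower: float = 0.4
    mode: str = "grow_dilute"  # batch | grow_dilute | constant_od
    sample_interval_h: float = 1.0  # cadence of cytometry sampling
    log_dt_h: float = 0.1  # cadence of OD / LED logging

    def __post_init__(self) -> None:
        if not (0 < self.od_lower < self.od_upper):
            raise ValidationError("need 0 < od_lower < od_upper")
        if self.mode not in ("batch", "grow_dilute", "constant_od"):
            raise ValidationError(f"unknown turbidostat mode {self.mode!r}")
        if self.log_dt_h <= 0 or self.sample_interval_h <= 0:
            raise ValidationError("log_dt_h and sample_interval_h must be > 0")


@dataclass
class CultureLog:
    """CSV-serialisable record of a reactor run plus the hidden truth."""

    od_series: pd.DataFrame  # time_h, od
    led_series: pd.DataFrame  # time_h, u
    dilution_events: pd.DataFrame  # time_h, od_before, od_after
    trajectory: Trajectory  # hidden composition truth (per species + extras)
    warnings: list[str] = field(default_factory=list)

    def write_csvs(self, outdir) -> None:
        outdir = str(outdir)
        self.od_series.to_csv(
            f"{outdir}/od_log.csv", index=False, float_format="%.10g"
        )
        self.led_series.to_csv(
            f"{outdir}/led_log.csv", index=False, float_format="%.10g"
        )
        self.dilution_events.to_csv(
            f"{outdir}/dilution_log.csv", index=False, float_format="%.10g"
        )
        self.trajectory.to_csv(f"{outdir}/composition.csv")


# ---------------------------------------------------------------------------
# Culture models (plants): biological dynamics without reactor dilution
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationCulture:
    """Core strain: both species grow at mu; light converts nondiff -> diff."""

    params: DiffParams = field(default_factory=DiffParams)
    mu: float = 0.4
    species: tuple[str, ...] = ("nondiff", "diff")

    def rhs(self, y: np.ndarray, u: float) -> np.ndarray:
        n, d = y
        r = (self.params.k * u + self.params.lam) * n
        return np.array([self.mu * n - r, self.mu * d + r])

    def exchange(self, y: np.ndarray, u: float) -> np.ndarray:
        return np.zeros_like(y)


@dataclass
class TwoReactorCulture:
    """Control reactor fed non-differentiated cells from a dark reservoir.

    The reservoir inflow (rate phi, in units of culture volumes per hour)
    adds non-differentiated cells; together with the constant-density
    dilution this yields df/dt = (k*u+lam)(1-f) - phi*f for the
    differentiated fraction.  Only meaningful in constant_od mode.
    """

    params: TwoReactorParams = field(default_factory=TwoReactorParams)
    mu: float = 0.4
    species: tuple[str, ...] = ("nondiff", "diff")

    def rhs(self, y: np.ndarray, u: float) -> np.ndarray:
        n, d = y
        p = self.params.diff
        r = (p.k * u + p.lam) * n
        return np.array([self.mu * n - r, self.mu * d + r])

    def exchange(self, y: np.ndarray, u: float) -> np.ndarray:
        influx = self.params.phi * y.sum()
        return np.array([influx, 0.0])


@dataclass
class GaudiCulture:
    """GAuDi strain: differentiated cells arrest, then die or escape."""

    params: GaudiParams = field(default_factory=GaudiParams)
    species: tuple[str, ...] = ("nondiff", "diff", "escaped", "dead")

    def rhs(self, y: np.ndarray, u: float) -> np.ndarray:
        p = self.params
        n, d, e, x = y
        r = p.k * u + p.lam
        return np.array(
            [
                (p.mu - r) * n,
                r * n + (p.mu_d - p.gamma_x - p.gamma_e) * d,
                p.gamma_e * d + p.mu * e,
                p.gamma_x * d,
            ]
        )

    def exchange(self, y: np.ndarray, u: float) -> np.ndarray:
        return np.zeros_like(y)


def _growth_and_influx(culture, y: np.ndarray, u: float) -> float:
    """d(total)/dt from biology plus exchange, per unit total."""
    total = y.sum()
    return (culture.rhs(y, u).sum() + culture.exchange(y, u).sum()) / total


def advance_culture(
    culture,
    y0: np.ndarray,
    t0: float,
    t1: float,
    program: LightProgram,
    config: TurbidostatConfig,
    warnings_out: list[str] | None = None,
):
    """Advance a culture from t0 to t1 under the given light and mode.

    Returns ``(times, states, dilution_events, y_end)`` where ``times`` is a
    dense internal grid (log_dt cadence plus event times) and states the
    concentrations per species at those times.
    """
    mode = config.mode
    warned = {"flag": False}

    def full_rhs(t, y, u):
        bio = culture.rhs(y, u) + culture.exchange(y, u)
        if mode != "constant_od":
            return bio
        delta = bio.sum() / y.sum()
        if delta <= 0:
            if not warned["flag"]:
                warned["flag"] = True
                msg = f"non-growing culture at t={t:.3f} h: zero dilution"
                logger.warning(msg)
                if warnings_out is not None:
                    warnings_out.append(msg)
            delta = 0.0
        return bio - delta * y

    knots = sorted(
        {t0, t1, *(b for b in program.breakpoints() if t0 < b < t1)}
    )
    n_log = max(int(round((t1 - t0) / config.log_dt_h)), 1)
    log_times = t0 + np.arange(n_log + 1) * (t1 - t0) / n_log

    times: list[float] = [t0]
    states: list[np.ndarray] = [np.asarray(y0, dtype=float)]
    events: list[tuple[float, float, float]] = []
    y = np.asarray(y0, dtype=float).copy()

    for a, b in zip(knots, knots[1:]):
        useg = float(program.u((a + b) / 2.0))
        t_cur = a
        while t_cur < b - 1e-12:
            ev = None
            if mode == "grow_dilute":
                def hit_upper(t, yy):
                    return yy.sum() * OD_PER_CONCENTRATION - config.od_upper

                hit_upper.terminal = True
                hit_upper.direction = 1
                ev = [hit_upper]
            sol = solve_ivp(
                lambda t, yy: full_rhs(t, yy, useg),
                (t_cur, b),
                y,
                method="RK45",
                dense_output=True,
                events=ev,
                rtol=1e-10,
                atol=1e-12,
            )
            if not sol.success:
                raise IntegrationError(
                    f"culture integration failed at t={t_cur:.4g}: {sol.message}"
                )
            t_end = sol.t[-1]
            inner = log_times[(log_times > t_cur) & (log_times <= t_end)]
            for tt in inner:
                times.append(float(tt))
                states.append(sol.sol(tt))
            y = sol.y[:, -1]
            if mode == "grow_dilute" and sol.status == 1:
                od_before = y.sum() * OD_PER_CONCENTRATION
                factor = config.od_lower / od_before
                times.append(float(t_end))
                states.append(y.copy())
                y = y * factor  # instantaneous, composition-preserving
                times.append(float(t_end))
                states.append(y.copy())
                events.append((float(t_end), od_before, config.od_lower))
            t_cur = t_end
    return np.array(times), np.vstack(states), events, y


def run_turbidostat(
    culture,
    config: TurbidostatConfig,
    program: LightProgram,
    duration_h: float,
    s0,
) -> CultureLog:
    """Run a culture in the configured reactor mode for ``duration_h`` hours.

    ``s0`` is a per-species concentration vector (OD-equivalent units) in the
    order of ``culture.species``; a :class:`GaudiState` is also accepted for
    GAuDi cultures.
    """
    if duration_h <= 0:
        raise ValidationError("duration_h must be > 0")
    if isinstance(s0, GaudiState):
        s0 = s0.as_array()
    y0 = np.asarray(s0, dtype=float)
    if len(y0) != len(culture.species) or np.any(y0 < 0) or y0.sum() <= 0:
        raise ValidationError(
            f"s0 must be {len(culture.species)} non-negative concentrations "
            "with positive total"
        )
    if isinstance(culture, TwoReactorCulture) and config.mode != "constant_od":
        raise ValidationError(
            "TwoReactorCulture is defined for constant_od mode only"
        )

    warnings_out: list[str] = []
    times, states, events, _ = advance_culture(
        culture, y0, 0.0, duration_h, program, config, warnings_out
    )

    totals = states.sum(axis=1)
    od = totals * OD_PER_CONCENTRATION
    od_series = pd.DataFrame({"time_h": times, "od": od})
    led_series = pd.DataFrame(
        {"time_h": times, "u": np.asarray(program.u(times), dtype=float)}
    )
    dilution_events = pd.DataFrame(
        events, columns=["time_h", "od_before", "od_after"]
    )

    data: dict[str, np.ndarray] = {}
    for i, name in enumerate(culture.species):
        data[name] = states[:, i]
        data[f"frac_{name}"] = states[:, i] / totals
    data["od"] = od
    u_arr = np.asarray(program.u(times), dtype=float)
    delta = np.array(
        [
            max(_growth_and_influx(culture, yy, uu), 0.0)
            if config.mode == "constant_od"
            else 0.0
            for yy, uu in zip(states, u_arr)
        ]
    )
    data["dilution_rate_per_h"] = delta
    traj = Trajectory(times, data)
    return CultureLog(od_series, led_series, dilution_events, traj, warnings_out)


# ---------------------------------------------------------------------------
# Growth-rate estimation from OD logs
# ---------------------------------------------------------------------------


def estimate_growth_rate(
    log: CultureLog, window_h: float = 4.0
) -> pd.DataFrame:
    """Per-segment growth rates from the slope of log(OD) versus time.

    The OD series is split at dilution events; within each segment with at
    least three points a least-squares line is fitted to log(OD).  Returns a
    frame with one row per usable segment (t_start, t_end, t_mid,
    growth_rate, n_points) plus a trailing-window average ``growth_rate_windowed``
    over ``window_h`` hours.  Segments with fewer than three points are
    skipped and reported via logging.
    """
    od = log.od_series
    cut_times = sorted(log.dilution_events["time_h"].tolist())
    edges = [-np.inf, *cut_times, np.inf]
    rows = []
    n_skipped = 0
    for a, b in zip(edges, edges[1:]):
        seg = od[(od["time_h"] > a) & (od["time_h"] <= b)]
        # a dilution event logs od_before and od_after at the same instant;
        # the pre-dilution value closes this segment, the other opens the next
        seg = seg.drop_duplicates(subset="time_h", keep="first")
        seg = seg[seg["od"] > 0]
        if len(seg) < 3:
            n_skipped += 1
            continue
        res = linregress(seg["time_h"].to_numpy(), np.log(seg["od"].to_numpy()))
        rows.append(
            {
                "t_start": float(seg["time_h"].iloc[0]),
                "t_end": float(seg["time_h"].iloc[-1]),
                "t_mid": float(seg["time_h"].mean()),
                "growth_rate": float(res.slope),
                "n_points": int(len(seg)),
            }
        )
    if n_skipped:
        logger.warning(
            "estimate_growth_rate: skipped %d segment(s) with < 3 OD points",
            n_skipped,
        )
    out = pd.DataFrame(
        rows, columns=["t_start", "t_end", "t_mid", "growth_rate", "n_points"]
    )
    if len(out):
        windowed = [
            out[
                (out["t_mid"] > t - window_h) & (out["t_mid"] <= t)
            ]["growth_rate"].mean()
            for t in out["t_mid"]
        ]
        out["growth_rate_windowed"] = windowed
    else:
        out["growth_rate_windowed"] = pd.Series(dtype=float)
    return out
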