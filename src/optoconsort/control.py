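"""Receding-horizon model-predictive control of consortium composition.

At each sampling time the controller (i) estimates the *current* state from
the delayed cytometry measurement by integrating the model forward over the
total delay tau = sampling delay + observation delay using the light
actually applied in that window, and (ii) optimises the next light duty
cycles (default: 10 cycles of 30 min, a 5 h horizon) to minimise the squared
deviation of predicted fractions from the set point on a 5-min prediction
grid.  Duties are realised as ON-at-start-of-cycle segments, and all
optimised segments covering the inter-sample interval are applied.

The controller's internal predictors are exact (piecewise closed form) for
the scalar models and fixed-step RK4 for the growth-arrest model, which
keeps the objective smooth and fast; the plant itself is integrated with the
adaptive reference solver.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import cytometry
from .models import (
    DiffParams,
    GaudiParams,
    GaudiState,
    LightProgram,
    MIN_PER_H,
    Trajectory,
    TwoReactorParams,
    ValidationError,
    fraction_trajectory_exact,
    rk4_gaudi,
)
from .synthetic_data import FluorescenceModel, composition_at, generate_events
from .turbidostat import TurbidostatConfig, advance_culture

__all__ = [
    "MPCConfig",
    "ClosedLoopResult",
    "estimate_state",
    "GaudiStateEstimator",
    "optimize_light_sequence",
    "ClosedLoopPlant",
    "run_closed_loop",
    "time_to_band",
    "hold_after_entry",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MPCConfig:
    """Receding-horizon controller settings."""

    n_cycles: int = 10
    cycle_period_min: float = 30.0
    sampling_interval_h: float = 1.0  # 1 h two-reactor, 2 h single-reactor
    tau_sampling_min: float = 20.0  # sample -> finished analysis latency
    prediction_dt_min: float = 5.0
    setpoints: tuple[tuple[float, float], ...] = ((0.0, 0.4),)

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.cycle_period_min <= 0:
            raise ValidationError("need n_cycles >= 1 and cycle_period > 0")
        if self.sampling_interval_h <= 0 or self.prediction_dt_min <= 0:
            raise ValidationError("sampling and prediction intervals must be > 0")
        if self.tau_sampling_min < 0:
            raise ValidationError("tau_sampling_min must be >= 0")
        for _, target in self.setpoints:
            if not (0.0 <= target <= 1.0):
                raise ValidationError("set points must be fractions in [0, 1]")
        # the horizon is n_cycles * cycle_period by construction
        if not self.setpoints:
            raise ValidationError("need at least one set point")

    @property
    def cycle_period_h(self) -> float:
        return self.cycle_period_min / MIN_PER_H

    @property
    def horizon_h(self) -> float:
        return self.n_cycles * self.cycle_period_h

    def target_at(self, t):
        """Piecewise-constant set point schedule."""
        t_arr = np.asarray(t, dtype=float)
        out = np.full_like(t_arr, self.setpoints[0][1], dtype=float)
        for t_from, target in sorted(self.setpoints):
            out = np.where(t_arr >= t_from, target, out)
        return float(out) if t_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# State estimation from delayed measurements
# ---------------------------------------------------------------------------


def _scalar_rates(params) -> tuple[float, float, float]:
    if isinstance(params, TwoReactorParams):
        return params.diff.k, params.diff.lam, params.phi
    if isinstance(params, DiffParams):
        return params.k, params.lam, 0.0
    raise ValidationError(f"unsupported scalar model params {type(params)!r}")


def estimate_state(
    f_measured: float,
    t_now: float,
    light_history: LightProgram,
    params,
    tau_min: float,
) -> float:
    """Current fraction estimate from a delayed measurement.

    Takes ``f_measured`` as the model state at ``t_now - tau`` and integrates
    the model forward over the window of length tau ending now, using the
    light applied in that window.
    """
    if tau_min < 0:
        raise ValidationError("tau_min must be >= 0")
    f_measured = float(np.clip(f_measured, 0.0, 1.0))
    tau_h = tau_min / MIN_PER_H
    if tau_h == 0:
        return f_measured
    t0 = t_now - tau_h
    if t0 < -1e-9 and light_history.on_time_between(t0, 0.0) > 0:
        raise ValidationError("light history does not cover the tau window")
    k, lam, phi = _scalar_rates(params)
    grid = np.array([t0, t_now])
    f = fraction_trajectory_exact(k, lam, phi, light_history, f_measured, grid)
    return float(f[-1])


class GaudiStateEstimator:
    """Tracks a full GAuDi state estimate from delayed live-fraction data.

    The estimator maintains an internal model trajectory under the applied
    light.  At each sample it reads its own state at the measurement's
    effective time (sample time minus the observation delay), re-balances the
    live differentiated split to match the measurement, and integrates
    forward over the total delay to "now".
    """

    def __init__(self, params: GaudiParams, s0: GaudiState, t0: float = 0.0):
        self.params = params
        self._t = np.array([t0])
        self._y = s0.as_array()[None, :]

    def state_at(self, t: float) -> np.ndarray:
        return np.array(
            [np.interp(t, self._t, self._y[:, i]) for i in range(4)]
        )

    def update(
        self,
        measured_live_diff: float,
        t_sample: float,
        t_now: float,
        applied: LightProgram,
    ) -> np.ndarray:
        m = float(np.clip(measured_live_diff, 0.0, 1.0))
        tau_obs_h = self.params.tau_frac_min / MIN_PER_H
        t_eff = max(t_sample - tau_obs_h, float(self._t[0]))
        y = self.state_at(t_eff)
        n, d, e, x = y
        live = n + d + e
        if live > 0:
            d_new = m * live
            rest = live - d_new
            ne = n + e
            if ne > 0:
                n, e = n * rest / ne, e * rest / ne
            else:
                n, e = rest, 0.0
            y = np.array([n, d_new, e, x])
        grid = np.linspace(
            t_eff, t_now, max(int((t_now - t_eff) / 0.05) + 2, 2)
        )
        ys = rk4_gaudi(self.params, applied, y, grid)
        keep = self._t < t_eff - 1e-12
        self._t = np.concatenate([self._t[keep], grid])
        self._y = np.vstack([self._y[keep], ys])
        return ys[-1]

    def extend(self, t_to: float, applied: LightProgram) -> None:
        """Roll the internal trajectory forward without a measurement."""
        t_last = float(self._t[-1])
        if t_to <= t_last + 1e-12:
            return
        grid = np.linspace(
            t_last, t_to, max(int((t_to - t_last) / 0.05) + 2, 2)
        )
        ys = rk4_gaudi(self.params, applied, self._y[-1], grid)
        self._t = np.concatenate([self._t, grid[1:]])
        self._y = np.vstack([self._y, ys[1:]])


# ---------------------------------------------------------------------------
# Duty-cycle optimisation
# ---------------------------------------------------------------------------


def optimize_light_sequence(
    predict_fn,
    t_now: float,
    cfg: MPCConfig,
    warm_start: np.ndarray | None = None,
) -> np.ndarray:
    """Optimise duty fractions over the horizon against the set point.

    ``predict_fn(program, t_grid) -> fractions`` predicts the controlled
    observable from the current state estimate under a candidate future
    light program.  Minimises the squared set-point error on the prediction
    grid with L-BFGS-B under box bounds [0, 1]; falls back to the warm start
    if the optimiser fails.
    """
    P = cfg.cycle_period_h
    n = cfg.n_cycles
    dt = cfg.prediction_dt_min / MIN_PER_H
    n_pred = max(int(round(cfg.horizon_h / dt)), 1)
    grid = t_now + dt * np.arange(1, n_pred + 1)
    targets = cfg.target_at(grid)

    def objective(duties):
        prog = LightProgram.from_duty_cycles(duties, t_now, P)
        f = predict_fn(prog, grid)
        return float(np.sum((f - targets) ** 2))

    x0 = (
        np.clip(np.asarray(warm_start, float), 0.0, 1.0)
        if warm_start is not None
        else np.full(n, 0.5)
    )
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * n,
        options={"eps": 1e-6, "maxfun": 400},
    )
    if not res.success and warm_start is not None:
        logger.warning(
            "duty optimisation did not converge (%s); keeping warm start",
            res.message,
        )
        return x0
    return np.clip(res.x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Closed loop against the synthetic plant
# ---------------------------------------------------------------------------


@dataclass
class ClosedLoopPlant:
    """Constant-density culture advanced incrementally under applied light."""

    culture: object
    s0: np.ndarray
    config: TurbidostatConfig = field(
        default_factory=lambda: TurbidostatConfig(mode="constant_od", log_dt_h=0.05)
    )

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self._t = [0.0]
        self._y = [self.s0.copy()]
        self.warnings: list[str] = []

    @property
    def t_last(self) -> float:
        return self._t[-1]

    def advance_to(self, t1: float, program: LightProgram) -> None:
        t0 = self.t_last
        if t1 <= t0 + 1e-12:
            return
        times, states, _, _ = advance_culture(
            self.culture, self._y[-1], t0, t1, program, self.config,
            self.warnings,
        )
        self._t.extend(times[1:].tolist())
        self._y.extend(list(states[1:]))

    def trajectory(self) -> Trajectory:
        t = np.array(self._t)
        y = np.vstack(self._y)
        totals = y.sum(axis=1)
        data = {}
        for i, name in enumerate(self.culture.species):
            data[name] = y[:, i]
            data[f"frac_{name}"] = y[:, i] / totals
        data["od"] = totals
        return Trajectory(t, data)


@dataclass
class ClosedLoopResult:
    """Audit trail of a closed-loop run."""

    log: pd.DataFrame
    applied_program: LightProgram
    plant_trajectory: Trajectory

    def write_csvs(self, outdir) -> None:
        outdir = str(outdir)
        self.log.to_csv(
            f"{outdir}/closed_loop_log.csv", index=False, float_format="%.10g"
        )
        self.plant_trajectory.to_csv(f"{outdir}/composition.csv")
        pd.DataFrame(
            list(self.applied_program.segments),
            columns=["t_start_h", "t_end_h", "u"],
        ).to_csv(f"{outdir}/led_log.csv", index=False, float_format="%.10g")


def _measure(
    traj: Trajectory,
    fm: FluorescenceModel,
    t_s: float,
    scheme: str,
    n_events: int,
    seed,
    perfect: bool,
) -> float:
    comp = composition_at(traj, fm, t_s)
    if perfect:
        if scheme == "gaudi":
            by = dict(zip(fm.species, comp))
            live = by["nondiff"] + by["diff"] + by["escaped"]
            return by["diff"] / live
        return float(comp[list(fm.species).index("diff")])
    events = generate_events(comp, fm, n_events, seed, time_h=t_s)
    ev = cytometry.unmix(events, fm.spillover)
    gate = cytometry.kde_gate(ev)
    labels = cytometry.classify_events(
        ev[gate.keep], scheme="gaudi" if scheme == "gaudi" else "core"
    )
    est = cytometry.estimate_composition(
        labels, scheme="gaudi" if scheme == "gaudi" else "core"
    )
    return (
        est.live_diff_fraction if scheme == "gaudi" else est.fractions["diff"]
    )


def run_closed_loop(
    plant: ClosedLoopPlant,
    cfg: MPCConfig,
    controller_params,
    duration_h: float,
    fm: FluorescenceModel,
    seed: int = 1,
    events_per_sample: int = 5000,
    perfect_measurement: bool = False,
    force_dark: bool = False,
) -> ClosedLoopResult:
    """Run the full loop: sample -> analyse -> estimate -> optimise -> apply.

    ``controller_params`` selects the internal model: TwoReactorParams /
    DiffParams (scalar fraction models) or GaudiParams (single-reactor
    growth-arrest loop, controlling the live differentiated fraction).
    """
    if duration_h <= 0:
        raise ValidationError("duration_h must be > 0")
    gaudi_mode = isinstance(controller_params, GaudiParams)
    scheme = "gaudi" if gaudi_mode else "core"
    P = cfg.cycle_period_h
    tau_samp_h = cfg.tau_sampling_min / MIN_PER_H
    n_apply = max(int(math.ceil(cfg.sampling_interval_h / P - 1e-9)), 1)

    sample_times = np.arange(0.0, duration_h + 1e-9, cfg.sampling_interval_h)
    seeds = np.random.SeedSequence(seed).spawn(len(sample_times))

    if gaudi_mode:
        estimator = GaudiStateEstimator(
            controller_params, GaudiState.from_array(plant.s0)
        )
        tau_total_min = controller_params.tau_frac_min + cfg.tau_sampling_min
    else:
        k, lam, phi = _scalar_rates(controller_params)
        tau_obs = (
            controller_params.diff.tau_obs_min
            if isinstance(controller_params, TwoReactorParams)
            else controller_params.tau_obs_min
        )
        tau_total_min = tau_obs + cfg.tau_sampling_min

    applied_segments: list[tuple[float, float, float]] = []
    warm: np.ndarray | None = None
    rows = []

    for i, t_s in enumerate(sample_times):
        applied = LightProgram(tuple(applied_segments))
        plant.advance_to(t_s, applied)
        measured = _measure(
            plant.trajectory(),
            fm,
            t_s,
            scheme,
            events_per_sample,
            seeds[i],
            perfect_measurement,
        )
        t_now = t_s + tau_samp_h

        if gaudi_mode:
            y_now = estimator.update(measured, t_s, t_now, applied)
            state_est = GaudiState.from_array(y_now).live_diff_fraction

            def predict_fn(prog, grid, y0=y_now, t0=t_now):
                gg = np.concatenate([[t0], grid])
                ys = rk4_gaudi(controller_params, prog, y0, gg)[1:]
                live = ys[:, :3].sum(axis=1)
                return ys[:, 1] / live

        else:
            f_now = estimate_state(
                measured, t_now, applied, controller_params, tau_total_min
            )
            state_est = f_now

            def predict_fn(prog, grid, f0=f_now, t0=t_now):
                gg = np.concatenate([[t0], grid])
                return fraction_trajectory_exact(k, lam, phi, prog, f0, gg)[1:]

        if force_dark:
            duties = np.zeros(cfg.n_cycles)
        else:
            duties = optimize_light_sequence(predict_fn, t_now, cfg, warm)

        cutoff = t_now + n_apply * P
        new_prog = LightProgram.from_duty_cycles(duties, t_now, P)
        applied_segments.extend(
            seg for seg in new_prog.segments if seg[0] < cutoff - 1e-9
        )

        row = {
            "time_h": float(t_s),
            "measured_fraction": float(measured),
            "setpoint": float(cfg.target_at(t_s)),
            "state_estimate": float(state_est),
            "decision_time_h": float(t_now),
        }
        for j, dval in enumerate(duties):
            row[f"duty_{j}"] = float(dval)
        rows.append(row)

        warm = np.concatenate(
            [duties[n_apply:], np.repeat(duties[-1], n_apply)]
        )

    final_program = LightProgram(tuple(applied_segments))
    plant.advance_to(duration_h, final_program)
    log = pd.DataFrame(rows)
    return ClosedLoopResult(log, final_program, plant.trajectory())


# ---------------------------------------------------------------------------
# Closed-loop metrics
# ---------------------------------------------------------------------------


def time_to_band(log: pd.DataFrame, band: float) -> float | None:
    """First sample time whose measurement is within +/- band of the set
    point."""
    err = (log["measured_fraction"] - log["setpoint"]).abs()
    hit = log.loc[err <= band, "time_h"]
    return float(hit.iloc[0]) if len(hit) else None


def hold_after_entry(
    log: pd.DataFrame, band: float, t_end: float | None = None
) -> float:
    """Length of the initial in-band interval after first entry.

    Measured from the first in-band sample to the first subsequent
    out-of-band sample (or the end of the run).  Returns 0.0 if the band is
    never entered.
    """
    t_enter = time_to_band(log, band)
    if t_enter is None:
        return 0.0
    err = (log["measured_fraction"] - log["setpoint"]).abs()
    after = log["time_h"] > t_enter
    out = log.loc[after & (err > band), "time_h"]
    t_stop = float(out.iloc[0]) if len(out) else float(
        t_end if t_end is not None else log["time_h"].iloc[-1]
    )
    return t_stop - t_enter
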