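"""Deterministic ODE models of light-driven recombination.

This module is the single source of truth for all dynamics used by the
turbidostat simulator, the parameter fitter and the model-predictive
controller.  Four model variants are provided:

* a one-parameter differentiation model ``df/dt = (k*u(t) + lam) * (1 - f)``
  describing the fraction ``f`` of cells whose recombination cassette has
  excised under a light input ``u(t)``;
* a two-reactor variant with an extra ``- phi*f`` term accounting for a
  constant inflow of non-differentiated cells from a reservoir reactor;
* a four-species growth-arrest-upon-differentiation (GAuDi) model in which
  differentiated cells arrest, then die or escape, simulated at constant
  culture density with the dilution rate equal to the population-weighted
  growth rate;
* an independent two-cassette model producing a four-species consortium.

Time is measured in hours everywhere; delays are configured in minutes and
converted internally.  Light ``u`` is normalised to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ValidationError",
    "IntegrationError",
    "LightProgram",
    "Trajectory",
    "DiffParams",
    "TwoReactorParams",
    "GaudiParams",
    "GaudiState",
    "MultiCassetteParams",
    "MultiCassetteState",
    "closed_form_fraction",
    "simulate_differentiation",
    "simulate_two_reactor",
    "simulate_gaudi",
    "simulate_multicassette",
    "apply_observation_delay",
    "MIN_PER_H",
]

MIN_PER_H = 60.0

# Rate bounds used for validation and by the fitting module.
RATE_LOWER = 1e-10
RATE_UPPER = 10.0


class ValidationError(ValueError):
    """Raised when model inputs violate a documented precondition."""


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces invalid states."""


# ---------------------------------------------------------------------------
# Light programs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LightProgram:
    """Piecewise-constant light input u(t) in [0, 1].

    ``segments`` is a sequence of ``(t_start_h, t_end_h, u)`` triples; u is 0
    outside all segments.  Segments must be non-overlapping and ordered in
    time (contiguous segments are allowed).
    """

    segments: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(
            (float(a), float(b), float(u)) for a, b, u in self.segments
        )
        segs = tuple(sorted(segs, key=lambda s: s[0]))
        for a, b, u in segs:
            if not (b > a):
                raise ValidationError(f"segment end {b} must exceed start {a}")
            if a < 0:
                raise ValidationError("segment start times must be >= 0")
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"light level u={u} outside [0, 1]")
        for (a0, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if a1 < b0 - 1e-12:
                raise ValidationError("light segments overlap")
        object.__setattr__(self, "segments", segs)

    # -- constructors -------------------------------------------------------

    @classmethod
    def dark(cls) -> "LightProgram":
        return cls(())

    @classmethod
    def constant(cls, u: float, duration_h: float) -> "LightProgram":
        if u == 0:
            return cls(())
        return cls(((0.0, float(duration_h), float(u)),))

    @classmethod
    def single_pulse(
        cls, duration_h: float, start_h: float = 0.0, u: float = 1.0
    ) -> "LightProgram":
        return cls(((float(start_h), float(start_h) + float(duration_h), u),))

    @classmethod
    def from_duty_cycles(
        cls,
        duties: "np.ndarray | list[float]",
        t_start_h: float,
        cycle_period_h: float,
    ) -> "LightProgram":
        """Realize duty fractions as ON-at-start-of-cycle segments."""
        segs = []
        for i, d in enumerate(np.clip(np.asarray(duties, float), 0.0, 1.0)):
            if d <= 0:
                continue
            a = t_start_h + i * cycle_period_h
            segs.append((a, a + d * cycle_period_h, 1.0))
        return cls(tuple(segs))

    # -- evaluation ----------------------------------------------------------

    def u(self, t):
        """Light level at time(s) ``t`` (scalar or array)."""
        t_arr = np.asarray(t, dtype=float)
        out = np.zeros_like(t_arr)
        for a, b, u in self.segments:
            out = np.where((t_arr >= a) & (t_arr < b), u, out)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def on_time_between(self, t0: float, t1: float) -> float:
        """Exact integral of u(t) dt over [t0, t1] (weighted ON time, hours)."""
        total = 0.0
        for a, b, u in self.segments:
            total += u * max(0.0, min(b, t1) - max(a, t0))
        return total

    def total_on_time(self) -> float:
        return sum(u * (b - a) for a, b, u in self.segments)

    def breakpoints(self) -> list[float]:
        pts: set[float] = set()
        for a, b, _ in self.segments:
            pts.add(a)
            pts.add(b)
        return sorted(pts)

    def concat(self, other: "LightProgram") -> "LightProgram":
        return LightProgram(self.segments + other.segments)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Named time series on a common grid (time in hours)."""

    time_h: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        for name, col in self.data.items():
            col = np.asarray(col, dtype=float)
            if col.shape != self.time_h.shape:
                raise ValidationError(
                    f"column {name!r} length does not match time grid"
                )
            self.data[name] = col

    @property
    def columns(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def value_at(self, t, column: str):
        """Linear interpolation, clamped to the first/last grid value."""
        return np.interp(t, self.time_h, self.data[column])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time_h, **self.data})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


def _check_rate(name: str, value: float, lower: float = 0.0) -> None:
    if not np.isfinite(value) or value < lower:
        raise ValidationError(f"{name}={value} must be finite and >= {lower}")


@dataclass(frozen=True)
class DiffParams:
    """Core differentiation model: rate k, basal leak lam, observation delay."""

    k: float = 1.2  # differentiation rate under full light (1/h)
    lam: float = 0.0  # basal (dark) differentiation rate (1/h)
    tau_obs_min: float = 60.0  # fluorescence observation delay (min)

    def __post_init__(self) -> None:
        if not (RATE_LOWER <= self.k <= RATE_UPPER):
            raise ValidationError(
                f"k={self.k} outside [{RATE_LOWER}, {RATE_UPPER}]"
            )
        _check_rate("lam", self.lam)
        _check_rate("tau_obs_min", self.tau_obs_min)


@dataclass(frozen=True)
class TwoReactorParams:
    """Two-reactor setup: reservoir inflow dilutes the differentiated pool."""

    diff: DiffParams = field(default_factory=DiffParams)
    phi: float = 0.2  # reservoir inflow dilution rate (1/h)

    def __post_init__(self) -> None:
        _check_rate("phi", self.phi)


@dataclass(frozen=True)
class GaudiParams:
    """Growth-arrest-upon-differentiation model parameters (rates in 1/h)."""

    k: float = 1.2
    lam: float = 1e-3  # basal leak; GAuDi strain shows dark leakiness
    mu: float = 0.4  # growth rate of non-differentiated and escaped cells
    mu_d: float = 0.005  # residual growth rate of arrested cells
    gamma_x: float = 0.01  # death rate of arrested cells
    # Escape rate: calibrated so escapers (which regrow at mu) overtake the
    # live population ~15-20 h after differentiation under continuous light
    # while the culture growth rate over hours 8-12 stays below 0.04 1/h.
    gamma_e: float = 2e-4
    tau_frac_min: float = 120.0  # delay of diff / non-diff observables (min)
    tau_dead_min: float = 360.0  # delay of the dead observable (min)
    tau_mu_min: float = 300.0  # delay of the growth-rate observable (min)

    def __post_init__(self) -> None:
        for name in ("k", "lam", "mu", "mu_d", "gamma_x", "gamma_e"):
            _check_rate(name, getattr(self, name))
        if self.mu_d > self.mu:
            raise ValidationError("mu_d must not exceed mu")
        for name in ("tau_frac_min", "tau_dead_min", "tau_mu_min"):
            _check_rate(name, getattr(self, name))


@dataclass(frozen=True)
class GaudiState:
    """Concentrations (OD-equivalent units) of the four GAuDi species."""

    n: float  # non-differentiated
    d: float  # differentiated (growth-arrested)
    e: float  # escaped (cassette lost, growth restored)
    x: float  # dead

    def __post_init__(self) -> None:
        for name in ("n", "d", "e", "x"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"GaudiState.{name}={v} must be >= 0")
        if self.total <= 0:
            raise ValidationError("GaudiState total concentration must be > 0")

    @property
    def total(self) -> float:
        return self.n + self.d + self.e + self.x

    @property
    def live(self) -> float:
        return self.n + self.d + self.e

    @property
    def live_diff_fraction(self) -> float:
        return self.d / self.live

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.d, self.e, self.x], dtype=float)

    @classmethod
    def from_array(cls, y) -> "GaudiState":
        n, d, e, x = (max(float(v), 0.0) for v in y)
        return cls(n, d, e, x)


@dataclass(frozen=True)
class MultiCassetteParams:
    """Per-cassette recombination rates for the two-cassette programmes."""

    kC: float = 1.2
    kN: float = 1.2

    def __post_init__(self) -> None:
        for name in ("kC", "kN"):
            v = getattr(self, name)
            if not (RATE_LOWER <= v <= RATE_UPPER):
                raise ValidationError(
                    f"{name}={v} outside [{RATE_LOWER}, {RATE_UPPER}]"
                )


@dataclass(frozen=True)
class MultiCassetteState:
    """Per-cassette recombination probabilities; cassettes are independent."""

    pC: float = 0.0
    pN: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pC", "pN"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def fractions(self) -> dict[str, float]:
        pC, pN = self.pC, self.pN
        return {
            "f_CN": (1 - pC) * (1 - pN),
            "f_CbarN": pC * (1 - pN),
            "f_CNbar": (1 - pC) * pN,
            "f_CbarNbar": pC * pN,
        }


# ---------------------------------------------------------------------------
# Closed form and piecewise integration
# ---------------------------------------------------------------------------


def closed_form_fraction(k: float, on_time_h: float, f0: float = 0.0) -> float:
    """Differentiated fraction after a cumulative ON time (memoryless).

    Solves df/dt = k*(1-f) for a total light exposure ``on_time_h``:
    ``f = 1 - (1 - f0) * exp(-k * on_time_h)``.  Depends only on the total ON
    time, not on how pulses are distributed.
    """
    if not np.isfinite(k) or k < 0:
        raise ValidationError(f"k={k} must be finite and >= 0")
    if not np.isfinite(on_time_h) or on_time_h < 0:
        raise ValidationError(f"on_time_h={on_time_h} must be >= 0")
    if not (0.0 <= f0 <= 1.0):
        raise ValidationError(f"f0={f0} outside [0, 1]")
    return 1.0 - (1.0 - f0) * math.exp(-k * on_time_h)


def _check_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError("t_grid must be a 1-D array with >= 2 points")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("t_grid must be strictly increasing")
    return t


def _integrate_segments(rhs, y0, t_grid, program, rtol=1e-10, atol=1e-12):
    """Integrate dy/dt = rhs(t, y, u) with u constant per program segment.

    Integrates knot-to-knot with dense output so the solver never steps
    across a light discontinuity, evaluating the grid points inside each
    span and carrying the endpoint state forward.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    t0, tf = t_grid[0], t_grid[-1]
    knots = sorted({t0, tf, *(b for b in program.breakpoints() if t0 < b < tf)})
    out = np.empty((len(t_grid), len(y0)))
    out[0] = y0
    y = y0.copy()
    for a, b in zip(knots, knots[1:]):
        useg = float(program.u((a + b) / 2.0))
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, useg),
            (a, b),
            y,
            method="RK45",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed on [{a:.4g}, {b:.4g}]: {sol.message}"
            )
        mask = (t_grid > a) & (t_grid <= b)
        if mask.any():
            out[mask] = sol.sol(t_grid[mask]).T
        y = sol.y[:, -1]
        if np.any(~np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={b:.4g}")
    return out


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------


def simulate_differentiation(
    params: DiffParams,
    program: LightProgram,
    f0: float,
    t_grid,
) -> Trajectory:
    """Simulate df/dt = (k*u(t) + lam) * (1 - f) on the given grid."""
    t = _check_grid(t_grid)
    if not (0.0 <= f0 <= 1.0):
        raise ValidationError(f"f0={f0} outside [0, 1]")
    k, lam = params.k, params.lam

    def rhs(_t, y, u):
        return [(k * u + lam) * (1.0 - y[0])]

    f = _integrate_segments(rhs, [f0], t, program)[:, 0]
    f = _clip_fraction(f, "f")
    return Trajectory(t, {"f": f})


def simulate_two_reactor(
    params: TwoReactorParams,
    program: LightProgram,
    f0: float,
    t_grid,
) -> Trajectory:
    """Control-reactor fraction with reservoir inflow:
    df/dt = (k*u + lam)*(1 - f) - phi*f."""
    t = _check_grid(t_grid)
    if not (0.0 <= f0 <= 1.0):
        raise ValidationError(f"f0={f0} outside [0, 1]")
    k, lam, phi = params.diff.k, params.diff.lam, params.phi

    def rhs(_t, y, u):
        return [(k * u + lam) * (1.0 - y[0]) - phi * y[0]]

    f = _integrate_segments(rhs, [f0], t, program)[:, 0]
    f = _clip_fraction(f, "f")
    return Trajectory(t, {"f": f})


def gaudi_rhs(y, u: float, p: GaudiParams) -> np.ndarray:
    """Constant-density GAuDi dynamics with dilution delta = weighted growth."""
    n, d, e, x = y
    total = n + d + e + x
    delta = (p.mu * n + p.mu_d * d + p.mu * e) / total
    r = p.k * u + p.lam
    dn = (p.mu - r - delta) * n
    dd = r * n + (p.mu_d - p.gamma_x - p.gamma_e - delta) * d
    de = p.gamma_e * d + (p.mu - delta) * e
    dx = p.gamma_x * d - delta * x
    return np.array([dn, dd, de, dx])


def simulate_gaudi(
    params: GaudiParams,
    program: LightProgram,
    s0: GaudiState,
    t_grid,
) -> Trajectory:
    """Simulate the four-species GAuDi model at constant total density.

    Returns a trajectory with columns n, d, e, x, dilution_rate_per_h,
    live_diff_fraction, dead_fraction and total.
    """
    t = _check_grid(t_grid)
    p = params

    def rhs(_t, y, u):
        return gaudi_rhs(y, u, p)

    ys = _integrate_segments(rhs, s0.as_array(), t, program, rtol=1e-10)
    total0 = s0.total
    neg = ys.min()
    if neg < -1e-7 * total0:
        raise IntegrationError(
            f"negative GAuDi state excursion {neg:.3e} beyond tolerance "
            f"(total={total0:.3e}); check parameters/grid"
        )
    ys = np.clip(ys, 0.0, None)
    totals = ys.sum(axis=1)
    drift = np.max(np.abs(totals - total0)) / total0
    if drift > 1e-6:
        raise IntegrationError(
            f"GAuDi total-concentration drift {drift:.2e} exceeds tolerance"
        )
    n, d, e, x = ys.T
    delta = (p.mu * n + p.mu_d * d + p.mu * e) / totals
    live = n + d + e
    return Trajectory(
        t,
        {
            "n": n,
            "d": d,
            "e": e,
            "x": x,
            "total": totals,
            "dilution_rate_per_h": delta,
            "live_diff_fraction": d / live,
            "dead_fraction": x / totals,
        },
    )


def simulate_multicassette(
    params: MultiCassetteParams,
    program: LightProgram,
    s0: MultiCassetteState,
    t_grid,
) -> Trajectory:
    """Two independent cassettes: dpC/dt = kC*u*(1-pC), dpN/dt = kN*u*(1-pN)."""
    t = _check_grid(t_grid)
    kC, kN = params.kC, params.kN

    def rhs(_t, y, u):
        return [kC * u * (1.0 - y[0]), kN * u * (1.0 - y[1])]

    ys = _integrate_segments(rhs, [s0.pC, s0.pN], t, program)
    pC = _clip_fraction(ys[:, 0], "pC")
    pN = _clip_fraction(ys[:, 1], "pN")
    return Trajectory(
        t,
        {
            "pC": pC,
            "pN": pN,
            "f_CN": (1 - pC) * (1 - pN),
            "f_CbarN": pC * (1 - pN),
            "f_CNbar": (1 - pC) * pN,
            "f_CbarNbar": pC * pN,
        },
    )


def apply_observation_delay(traj: Trajectory, tau_min: float) -> Trajectory:
    """Shift a trajectory in time: observed(t) = true(t - tau).

    Values before ``t0 + tau`` are clamped to the initial value, mirroring a
    maturation delay during which the pre-existing state is still observed.
    """
    if tau_min < 0:
        raise ValidationError("tau_min must be >= 0")
    tau_h = tau_min / MIN_PER_H
    t = traj.time_h
    shifted = {
        name: np.interp(t - tau_h, t, col) for name, col in traj.data.items()
    }
    return Trajectory(t.copy(), shifted)


def _clip_fraction(arr: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    if arr.min() < -tol or arr.max() > 1 + tol:
        raise IntegrationError(
            f"{name} left [0, 1] beyond tolerance: "
            f"min={arr.min():.3e}, max={arr.max():.3e}"
        )
    return np.clip(arr, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Fast fixed-step integration (used by the controller and the GAuDi fitter)
# ---------------------------------------------------------------------------


def rk4_gaudi(
    params: GaudiParams,
    program: LightProgram,
    y0: np.ndarray,
    t_grid: np.ndarray,
    dt_max_h: float = 1.0 / 30.0,
) -> np.ndarray:
    """Fixed-step RK4 integration of the GAuDi model.

    Deterministic and smooth in the parameters, which makes it suitable
    inside finite-difference optimisation loops (MPC objective, fitting).
    Accuracy at the default step is far better than the noise floor of any
    fitted dataset; the reference simulator remains :func:`simulate_gaudi`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    p = params
    out = np.empty((len(t_grid), 4))
    y = np.asarray(y0, dtype=float).copy()
    out[0] = y
    knots = sorted(
        {
            t_grid[0],
            t_grid[-1],
            *(b for b in program.breakpoints() if t_grid[0] < b < t_grid[-1]),
            *t_grid,
        }
    )
    gi = 1
    for a, b in zip(knots, knots[1:]):
        if b <= a:
            continue
        u = float(program.u((a + b) / 2.0))
        span = b - a
        nsub = max(1, int(math.ceil(span / dt_max_h)))
        h = span / nsub
        for _ in range(nsub):
            k1 = gaudi_rhs(y, u, p)
            k2 = gaudi_rhs(y + 0.5 * h * k1, u, p)
            k3 = gaudi_rhs(y + 0.5 * h * k2, u, p)
            k4 = gaudi_rhs(y + h * k3, u, p)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        y = np.clip(y, 0.0, None)
        while gi < len(t_grid) and t_grid[gi] <= b + 1e-12:
            out[gi] = y
            gi += 1
    while gi < len(t_grid):
        out[gi] = y
        gi += 1
    return out


def step_fraction_linear(
    f0: float,
    a: float,
    b: float,
    dt: float,
) -> float:
    """Exact step of the scalar linear ODE f' = a - b*f over dt hours."""
    if b <= 0:
        return f0 + a * dt
    fin = a / b
    return fin + (f0 - fin) * math.exp(-b * dt)


def fraction_trajectory_exact(
    k: float,
    lam: float,
    phi: float,
    program: LightProgram,
    f0: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Exact piecewise solution of df/dt = (k*u+lam)(1-f) - phi*f.

    Used by the controller's internal predictor; exact for piecewise-constant
    light, hence fast and perfectly smooth in the duty parameters.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty(len(t_grid))
    out[0] = f0
    knots = sorted(
        {
            t_grid[0],
            t_grid[-1],
            *(b for b in program.breakpoints() if t_grid[0] < b < t_grid[-1]),
            *t_grid,
        }
    )
    f = f0
    gi = 1
    for a_t, b_t in zip(knots, knots[1:]):
        if b_t <= a_t:
            continue
        u = float(program.u((a_t + b_t) / 2.0))
        rate_in = k * u + lam
        f = step_fraction_linear(f, rate_in, rate_in + phi, b_t - a_t)
        while gi < len(t_grid) and t_grid[gi] <= b_t + 1e-12:
            out[gi] = f
            gi += 1
    while gi < len(t_grid):
        out[gi] = f
        gi += 1
    return np.clip(out, 0.0, 1.0)
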