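"""Synthetic plant trajectories and cytometry event tables.

Emulates the study conditions of the turbidostat platform: cultures sampled
every 1-2 h, 5000 events per sample, log-normal per-species fluorescence
with linear channel spillover, a scatter debris cluster, per-species
maturation/observation delays, and the pulsed light programmes used for
characterisation.  Everything is seeded explicitly; no global random state
is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import CHANNELS
from .models import (
    LightProgram,
    MIN_PER_H,
    Trajectory,
    ValidationError,
    closed_form_fraction,
)

__all__ = [
    "FluorescenceModel",
    "SampleSchedule",
    "generate_events",
    "sample_plant",
    "make_single_pulse_dataset",
    "make_repeated_pulse_program",
    "default_spillover",
    "DEFAULT_PULSE_DURATIONS_MIN",
]

# Fluorescence levels: "on" species sit ~10x above the 200 a.u. threshold,
# "off" species ~10x below, so misclassification is negligible by design.
_LOG_ON = float(np.log(2000.0))
_LOG_OFF = float(np.log(20.0))
_LOG_SD = 0.4

DEFAULT_PULSE_DURATIONS_MIN = (15, 30, 45, 60, 75, 90, 120, 180)


def default_spillover(leak: float = 0.08) -> np.ndarray:
    """Symmetric off-diagonal spillover mimicking post-acquisition
    deconvolution needs."""
    S = np.full((3, 3), leak)
    np.fill_diagonal(S, 1.0)
    return S


def _signal(cerulean: bool, neongreen: bool, scarlet: bool) -> np.ndarray:
    return np.array(
        [
            _LOG_ON if cerulean else _LOG_OFF,
            _LOG_ON if neongreen else _LOG_OFF,
            _LOG_ON if scarlet else _LOG_OFF,
        ]
    )


@dataclass
class FluorescenceModel:
    """Measurement model standing in for the benchtop cytometer.

    ``log_mean[s]`` / ``log_sd[s]`` give the natural-log mean and sd of the
    true fluorophore signal of species ``s`` in each channel (order
    :data:`optoconsort.cytometry.CHANNELS`); measured channels are
    ``spillover @ true``.  ``maturation_delay_min[s]`` is the species-level
    observation delay: a sample at time t reports the composition at
    (t - delay), which is how fluorophore maturation enters the data.
    """

    species: tuple[str, ...]
    log_mean: dict[str, np.ndarray]
    log_sd: dict[str, np.ndarray]
    spillover: np.ndarray = field(default_factory=default_spillover)
    debris_fraction: float = 0.1
    maturation_delay_min: dict[str, float] = field(default_factory=dict)
    # scatter clusters in (log FSC, log SSC): cells tight, debris displaced
    # low and broad
    cell_scatter_log_mean: tuple[float, float] = (
        float(np.log(5e4)),
        float(np.log(2e4)),
    )
    cell_scatter_log_sd: tuple[float, float] = (0.25, 0.3)
    debris_scatter_log_mean: tuple[float, float] = (
        float(np.log(2e3)),
        float(np.log(8e2)),
    )
    debris_scatter_log_sd: tuple[float, float] = (0.6, 0.6)
    debris_log_fluor: float = _LOG_OFF

    def __post_init__(self) -> None:
        if not (0.0 <= self.debris_fraction <= 0.5):
            raise ValidationError("debris_fraction must be in [0, 0.5]")
        S = np.asarray(self.spillover, dtype=float)
        if S.shape != (3, 3) or np.linalg.cond(S) > 1e12:
            raise ValidationError("spillover must be an invertible 3x3 matrix")
        for i in range(3):
            if S[i, i] <= np.abs(S[i]).sum() - np.abs(S[i, i]):
                raise ValidationError("spillover must be diagonally dominant")
        self.spillover = S
        for s in self.species:
            if s not in self.log_mean or s not in self.log_sd:
                raise ValidationError(f"missing fluorescence model for {s!r}")
            if np.any(np.asarray(self.log_sd[s]) <= 0):
                raise ValidationError("log_sd entries must be > 0")
            self.maturation_delay_min.setdefault(s, 60.0)

    # -- study-condition defaults -------------------------------------------

    @classmethod
    def default_core(cls) -> "FluorescenceModel":
        """Core strain: mCerulean before recombination, mNeonGreen after."""
        species = ("nondiff", "diff")
        return cls(
            species=species,
            log_mean={
                "nondiff": _signal(True, False, False),
                "diff": _signal(False, True, False),
            },
            log_sd={s: np.full(3, _LOG_SD) for s in species},
            maturation_delay_min={"nondiff": 60.0, "diff": 60.0},
        )

    @classmethod
    def default_gaudi(cls) -> "FluorescenceModel":
        """GAuDi strain: mScarlet-I marks differentiation; dead cells carry
        neither live marker; escapers lose the cassette and look
        non-differentiated.  The dead observable matures much later."""
        species = ("nondiff", "diff", "escaped", "dead")
        return cls(
            species=species,
            log_mean={
                "nondiff": _signal(True, False, False),
                "diff": _signal(False, False, True),
                "escaped": _signal(True, False, False),
                "dead": _signal(False, False, False),
            },
            log_sd={s: np.full(3, _LOG_SD) for s in species},
            maturation_delay_min={
                "nondiff": 120.0,
                "diff": 120.0,
                "escaped": 120.0,
                "dead": 360.0,
            },
        )

    @classmethod
    def default_multicassette(cls) -> "FluorescenceModel":
        """Two cassettes: recombined C turns mNeonGreen on, recombined N
        turns mScarlet-I on; the intact strain shows mCerulean."""
        species = ("CN", "CbarN", "CNbar", "CbarNbar")
        return cls(
            species=species,
            log_mean={
                "CN": _signal(True, False, False),
                "CbarN": _signal(True, True, False),
                "CNbar": _signal(False, False, True),
                "CbarNbar": _signal(False, True, True),
            },
            log_sd={s: np.full(3, _LOG_SD) for s in species},
            maturation_delay_min={s: 60.0 for s in species},
        )


@dataclass(frozen=True)
class SampleSchedule:
    """Cytometry sampling plan: times (h), events per sample and base seed."""

    sample_times_h: tuple[float, ...]
    events_per_sample: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_sample < 100:
            raise ValidationError("events_per_sample must be >= 100")
        if any(t < 0 for t in self.sample_times_h):
            raise ValidationError("sample times must be >= 0")


def generate_events(
    composition,
    fm: FluorescenceModel,
    n: int,
    seed,
    time_h: float = 0.0,
) -> pd.DataFrame:
    """Draw one synthetic cytometry sample of ``n`` events.

    ``composition`` maps species to fractions (dict or array in
    ``fm.species`` order) and must sum to 1.  Species labels are drawn
    multinomially; true fluorophore signals log-normally per species;
    measured channels are ``spillover @ true``.  A ``debris_fraction`` share
    of events is replaced by a displaced low-scatter debris cluster with
    background fluorescence.  Ground-truth ``species`` and ``is_debris``
    columns are kept for validation; downstream analysis never reads them.
    """
    if isinstance(composition, dict):
        p = np.array([composition.get(s, 0.0) for s in fm.species], dtype=float)
    else:
        p = np.asarray(composition, dtype=float)
    if len(p) != len(fm.species) or np.any(p < -1e-12):
        raise ValidationError(
            f"composition must give non-negative fractions for {fm.species}"
        )
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"composition sums to {p.sum():.6f}, not 1")
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    if n < 1:
        raise ValidationError("n must be >= 1")

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(fm.species), size=n, p=p)
    log_mu = np.stack([np.asarray(fm.log_mean[s]) for s in fm.species])
    log_sd = np.stack([np.asarray(fm.log_sd[s]) for s in fm.species])
    true = np.exp(rng.normal(log_mu[idx], log_sd[idx]))

    is_debris = rng.random(n) < fm.debris_fraction
    n_deb = int(is_debris.sum())
    if n_deb:
        true[is_debris] = np.exp(
            rng.normal(fm.debris_log_fluor, _LOG_SD, size=(n_deb, 3))
        )
    measured = true @ fm.spillover.T

    fsc = np.exp(
        rng.normal(fm.cell_scatter_log_mean[0], fm.cell_scatter_log_sd[0], n)
    )
    ssc = np.exp(
        rng.normal(fm.cell_scatter_log_mean[1], fm.cell_scatter_log_sd[1], n)
    )
    if n_deb:
        fsc[is_debris] = np.exp(
            rng.normal(
                fm.debris_scatter_log_mean[0],
                fm.debris_scatter_log_sd[0],
                n_deb,
            )
        )
        ssc[is_debris] = np.exp(
            rng.normal(
                fm.debris_scatter_log_mean[1],
                fm.debris_scatter_log_sd[1],
                n_deb,
            )
        )

    order = rng.permutation(n)
    species = np.array(fm.species, dtype=object)[idx]
    return pd.DataFrame(
        {
            "time_h": np.full(n, float(time_h)),
            "fsc": fsc[order],
            "ssc": ssc[order],
            CHANNELS[0]: measured[order, 0],
            CHANNELS[1]: measured[order, 1],
            CHANNELS[2]: measured[order, 2],
            "species": species[order],
            "is_debris": is_debris[order],
        }
    )


def composition_at(
    traj: Trajectory, fm: FluorescenceModel, t: float
) -> np.ndarray:
    """True composition seen by the cytometer at sample time ``t``.

    Each species fraction is read at ``t - maturation_delay`` (clamped to the
    trajectory start) and the vector renormalised, so slowly maturing
    observables (e.g. the dead class) lag faster ones.
    """
    fracs = np.array(
        [
            float(
                traj.value_at(
                    t - fm.maturation_delay_min[s] / MIN_PER_H, f"frac_{s}"
                )
            )
            for s in fm.species
        ]
    )
    fracs = np.clip(fracs, 0.0, None)
    if fracs.sum() <= 0:
        raise ValidationError("degenerate composition at sample time")
    return fracs / fracs.sum()


def sample_plant(
    traj: Trajectory,
    schedule: SampleSchedule,
    fm: FluorescenceModel,
) -> list[tuple[float, pd.DataFrame]]:
    """Sample a plant trajectory at scheduled times with observation delay.

    ``traj`` must carry one ``frac_<species>`` column per model species (as
    produced by :func:`optoconsort.turbidostat.run_turbidostat`).
    """
    t_max = float(traj.time_h[-1])
    for t in schedule.sample_times_h:
        if t > t_max + 1e-9:
            raise ValidationError(
                f"sample time {t} h outside simulated duration {t_max} h"
            )
    seeds = np.random.SeedSequence(schedule.seed).spawn(
        len(schedule.sample_times_h)
    )
    out = []
    for t, ss in zip(schedule.sample_times_h, seeds):
        comp = composition_at(traj, fm, t)
        out.append(
            (
                t,
                generate_events(
                    comp, fm, schedule.events_per_sample, ss, time_h=t
                ),
            )
        )
    return out


def make_single_pulse_dataset(
    durations_min=DEFAULT_PULSE_DURATIONS_MIN,
    k_true: float = 1.2,
    noise_sd: float = 0.02,
    seed: int = 0,
    f0: float = 0.0,
) -> pd.DataFrame:
    """Steady-state differentiated fractions after single light pulses.

    Reproduces the single-pulse characterisation experiments: each pulse
    duration yields the closed-form steady-state fraction plus additive
    Gaussian reactor-to-reactor noise truncated to [0, 1].
    """
    durations = np.asarray(durations_min, dtype=float)
    if np.any(durations <= 0):
        raise ValidationError("pulse durations must be > 0 minutes")
    rng = np.random.default_rng(seed)
    frac = np.array(
        [closed_form_fraction(k_true, d / MIN_PER_H, f0) for d in durations]
    )
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=len(frac))
    return pd.DataFrame(
        {"duration_min": durations, "fraction": np.clip(frac, 0.0, 1.0)}
    )


def make_repeated_pulse_program(
    pulse_min: float, interval_min: float, n_pulses: int, start_h: float = 0.0
) -> LightProgram:
    """Repeated pulses: ``n_pulses`` ON blocks of ``pulse_min`` minutes whose
    starts are ``interval_min`` minutes apart."""
    if n_pulses < 1:
        raise ValidationError("n_pulses must be >= 1")
    if pulse_min <= 0:
        raise ValidationError("pulse_min must be > 0")
    if interval_min < pulse_min:
        raise ValidationError("interval_min must be >= pulse_min")
    segs = []
    for i in range(n_pulses):
        a = start_h + i * interval_min / MIN_PER_H
        segs.append((a, a + pulse_min / MIN_PER_H, 1.0))
    return LightProgram(tuple(segs))
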