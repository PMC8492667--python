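"""Flow-cytometry event analysis: unmixing, gating, classification.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``time_h, fsc, ssc, ch_cerulean, ch_neongreen, ch_scarlet`` (fluorescence in
arbitrary units).  The analysis chain is

    unmix (spectral deconvolution)  ->  kde_gate (scatter gating)
        ->  classify_events (per-event labels)  ->  estimate_composition

Classification uses fixed fluorescence thresholds with a strict ">"
comparison: a cell is differentiated when its mNeonGreen signal exceeds
200 arbitrary units (the analogous convention applies to the mScarlet-I and
mCerulean channels in the growth-arrest and two-cassette schemes).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .models import ValidationError

__all__ = [
    "CHANNELS",
    "ThresholdSet",
    "GateResult",
    "unmix",
    "kde_gate",
    "classify_events",
    "estimate_composition",
    "CompositionEstimate",
    "SCHEMES",
    "MICROSCOPY_NEONGREEN_THRESHOLD",
]

CHANNELS = ("ch_cerulean", "ch_neongreen", "ch_scarlet")

SCHEMES = ("core", "gaudi", "multicassette")

# Recorded for completeness: the microscopy pipeline (out of scope here)
# classifies cells as differentiated above 300 arb. units mNeonGreen.
MICROSCOPY_NEONGREEN_THRESHOLD = 300.0


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel classification thresholds (arbitrary units)."""

    neongreen: float = 200.0
    scarlet: float = 200.0
    cerulean: float = 200.0

    def __post_init__(self) -> None:
        for name in ("neongreen", "scarlet", "cerulean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be > 0")


@dataclass
class GateResult:
    keep: np.ndarray  # boolean mask over events
    retained_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.retained_fraction <= 1):
            raise ValidationError("retained_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Spectral unmixing
# ---------------------------------------------------------------------------


def unmix(events: pd.DataFrame, spillover: np.ndarray) -> pd.DataFrame:
    """Invert channel spillover: measured = S @ true per event.

    ``spillover[i, j]`` is the contribution of true fluorophore j to measured
    channel i (channel order :data:`CHANNELS`).  Returns a copy of the event
    table with the fluorescence channels replaced by the unmixed signals.
    """
    S = np.asarray(spillover, dtype=float)
    if S.shape != (3, 3):
        raise ValidationError("spillover must be a 3x3 matrix")
    if np.linalg.cond(S) > 1e12:
        raise ValidationError("spillover matrix is singular or near-singular")
    measured = events.loc[:, list(CHANNELS)].to_numpy(dtype=float)
    true = np.linalg.solve(S, measured.T).T
    out = events.copy()
    out.loc[:, list(CHANNELS)] = true
    return out


# ---------------------------------------------------------------------------
# Kernel-density scatter gating
# ---------------------------------------------------------------------------


def kde_gate(
    events: pd.DataFrame,
    q: float = 0.9,
    grid_size: int = 64,
    train_max: int = 2000,
) -> GateResult:
    """Keep events in the high-density region around the main scatter mode.

    A Gaussian KDE (Silverman bandwidth) is estimated on
    (log FSC, log SSC).  Events are kept when their local density is at least
    the level enclosing fraction ``q`` of the total density mass (the
    (1 - q) quantile of per-event densities) *and* they fall in the
    grid-connected density region containing the global mode.  The second
    condition removes displaced debris clusters regardless of their mass.

    Degenerate (near-constant) scatter keeps all events with a warning.
    """
    n = len(events)
    if n < 100:
        raise ValidationError("kde_gate requires at least 100 events")
    if not (0 < q < 1):
        raise ValidationError("q must be in (0, 1)")
    xy = np.column_stack(
        [
            np.log(np.clip(events["fsc"].to_numpy(dtype=float), 1e-12, None)),
            np.log(np.clip(events["ssc"].to_numpy(dtype=float), 1e-12, None)),
        ]
    )
    if np.ptp(xy[:, 0]) < 1e-9 and np.ptp(xy[:, 1]) < 1e-9:
        _warnings.warn(
            "degenerate scatter (constant FSC/SSC); keeping all events",
            stacklevel=2,
        )
        return GateResult(np.ones(n, dtype=bool), 1.0)

    # deterministic training subsample keeps the gate fast on large tables
    stride = max(1, n // train_max)
    train = xy[::stride]
    try:
        kde = gaussian_kde(train.T, bw_method="silverman")
    except np.linalg.LinAlgError:
        _warnings.warn(
            "singular scatter covariance; keeping all events", stacklevel=2
        )
        return GateResult(np.ones(n, dtype=bool), 1.0)

    dens = kde(xy.T)
    level = np.quantile(dens, 1.0 - q)

    # grid the density to find the connected component holding the mode
    pad_x = 0.05 * max(np.ptp(xy[:, 0]), 0.1)
    pad_y = 0.05 * max(np.ptp(xy[:, 1]), 0.1)
    gx = np.linspace(xy[:, 0].min() - pad_x, xy[:, 0].max() + pad_x, grid_size)
    gy = np.linspace(xy[:, 1].min() - pad_y, xy[:, 1].max() + pad_y, grid_size)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    gdens = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(grid_size, grid_size)
    labels, _ = ndimage.label(gdens >= level, structure=np.ones((3, 3)))
    mode_label = labels[np.unravel_index(np.argmax(gdens), gdens.shape)]
    ix = np.clip(np.searchsorted(gx, xy[:, 0]) - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(gy, xy[:, 1]) - 1, 0, grid_size - 1)
    in_mode = labels[ix, iy] == mode_label if mode_label > 0 else np.ones(
        n, dtype=bool
    )
    keep = (dens >= level) & in_mode
    if not keep.any():  # pragma: no cover - mode events always pass
        keep = dens >= level
    return GateResult(keep, float(keep.mean()))


# ---------------------------------------------------------------------------
# Classification and composition
# ---------------------------------------------------------------------------

CORE_LABELS = ("nondiff", "diff")
GAUDI_LABELS = ("nondiff", "diff", "dead")
MULTICASSETTE_LABELS = ("CN", "CbarN", "CNbar", "CbarNbar")


def classify_events(
    events: pd.DataFrame,
    thresholds: ThresholdSet | None = None,
    scheme: str = "core",
) -> pd.Series:
    """Per-event labels from fluorescence thresholds (strict ">").

    * ``core`` — differentiated iff mNeonGreen exceeds its threshold.
    * ``gaudi`` — dead iff both live markers (mCerulean for non-differentiated
      cells, mScarlet-I for differentiated cells) are at or below threshold;
      otherwise differentiated iff mScarlet-I exceeds its threshold; the
      remainder are non-differentiated (this includes escapers, which regain
      the non-differentiated phenotype on cassette loss).
    * ``multicassette`` — 2x2 logic on (mNeonGreen, mScarlet-I) marking the
      C and N cassettes respectively.
    """
    thr = thresholds or ThresholdSet()
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown classification scheme {scheme!r}")
    ng = events["ch_neongreen"].to_numpy(dtype=float)
    sc = events["ch_scarlet"].to_numpy(dtype=float)
    ce = events["ch_cerulean"].to_numpy(dtype=float)
    if scheme == "core":
        labels = np.where(ng > thr.neongreen, "diff", "nondiff")
    elif scheme == "gaudi":
        labels = np.where(sc > thr.scarlet, "diff", "nondiff")
        dead = (sc <= thr.scarlet) & (ce <= thr.cerulean)
        labels = np.where(dead, "dead", labels)
    else:
        c_rec = ng > thr.neongreen
        n_rec = sc > thr.scarlet
        labels = np.select(
            [
                c_rec & n_rec,
                c_rec & ~n_rec,
                ~c_rec & n_rec,
            ],
            ["CbarNbar", "CbarN", "CNbar"],
            default="CN",
        )
    return pd.Series(labels, index=events.index, name="label")


@dataclass
class CompositionEstimate:
    fractions: dict[str, float]
    n_events: int
    live_fractions: dict[str, float] | None = None

    @property
    def live_diff_fraction(self) -> float:
        if self.live_fractions is None:
            raise ValidationError("live fractions only defined for gaudi")
        return self.live_fractions["diff"]


def estimate_composition(
    labels: pd.Series, scheme: str = "core"
) -> CompositionEstimate:
    """Label counts normalised to fractions (plus live-only for gaudi)."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown classification scheme {scheme!r}")
    n = len(labels)
    if n == 0:
        raise ValidationError("need at least one labelled event")
    names = {
        "core": CORE_LABELS,
        "gaudi": GAUDI_LABELS,
        "multicassette": MULTICASSETTE_LABELS,
    }[scheme]
    counts = labels.value_counts()
    fractions = {name: float(counts.get(name, 0)) / n for name in names}
    live = None
    if scheme == "gaudi":
        n_live = n - int(counts.get("dead", 0))
        if n_live == 0:
            raise ValidationError("zero live events; cannot form live fractions")
        live = {
            name: float(counts.get(name, 0)) / n_live
            for name in ("nondiff", "diff")
        }
    return CompositionEstimate(fractions, n, live)
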