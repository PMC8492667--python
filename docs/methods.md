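# Methods

`optoconsort` is a closed-loop, in-silico reconstruction of an optogenetic
differentiation platform in budding yeast: a blue-light-driven Cre
recombinase excises a cassette and irreversibly switches a cell from a
non-differentiated to a differentiated state. The package simulates the
culture hardware (turbidostat), the measurement chain (flow cytometry with
spillover, gating and maturation delays), parameter estimation, and
receding-horizon control of the consortium composition. This note records
the models, the defaults and why they were chosen, and the known
limitations.

## Models

All dynamics live in `optoconsort.models`; time is in hours, light
`u(t) ∈ [0, 1]` is piecewise constant, rates are in h⁻¹, delays are
configured in minutes.

**Core differentiation.** The differentiated fraction f obeys

    df/dt = (k·u(t) + λ)(1 − f),

with k the differentiation rate under full light and λ a basal (dark) leak.
The solution depends only on the cumulative weighted ON time E(t) = ∫u dt:
f = 1 − (1−f0)·e^(−k·E−λt). This memorylessness — pulses interchangeable
with continuous light of the same total duration, and each identical pulse
converting the same share 1 − e^(−kΔ) of the remaining pool — is asserted
as a property of the simulator against the closed form, which is kept as an
independent code path.

**Two-reactor variant.** A dark reservoir feeds non-differentiated cells
into the control reactor at dilution rate φ (volumes/h), giving

    df/dt = (k·u + λ)(1 − f) − φ·f,

with steady state k·u/(k·u+φ) under constant light and exponential washout
at rate φ in the dark. The control reactor is held at constant density; the
reservoir inflow is part of the total dilution.

**Growth arrest upon differentiation (GAuDi).** Four species — n
(non-differentiated), d (differentiated, arrested), e (escaped: cassette
lost, growth restored), x (dead) — at constant total density:

    dn/dt = (μ − k·u − λ − δ)·n
    dd/dt = (k·u + λ)·n + (μ_d − γ_x − γ_e − δ)·d
    de/dt = γ_e·d + (μ − δ)·e
    dx/dt = γ_x·d − δ·x
    δ = (μ·n + μ_d·d + μ·e) / (n + d + e + x)

δ is the dilution rate; at constant density it equals the
population-weighted growth rate, which is the growth-rate observable of the
platform. Dead cells scatter like live ones, contribute to OD, and are
diluted like everything else. Escapers grow at full μ and cannot be
re-differentiated.

**Multi-cassette programmes.** Two independently recombining cassettes with
rates k_C and k_N: dp_C/dt = k_C·u·(1−p_C) and likewise for p_N. The four
species fractions are the products (1−p_C)(1−p_N), p_C(1−p_N), (1−p_C)p_N,
p_C·p_N; marginals coincide with the single-cassette model by construction
(and are verified numerically). Equal rates give the asynchronous
programme; a 5× slower second cassette gives the sequential programme in
which the "slow-only" species never becomes appreciable.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| k | 1.2 h⁻¹ | differentiation rate at full light (>99% after a 4 h pulse) |
| λ | 0 (core), 1e-3 (GAuDi) | dark leak; the GAuDi strain is leakier |
| φ | 0.2 h⁻¹ | reservoir inflow dilution |
| μ | 0.4 h⁻¹ | growth rate of non-differentiated and escaped cells |
| μ_d | 0.005 h⁻¹ | residual growth of arrested cells |
| γ_x | 0.01 h⁻¹ | death rate of arrested cells |
| γ_e | 2e-4 h⁻¹ | escape rate (see below) |
| τ_obs | 60 min | observation delay, core reporter |
| τ_frac / τ_dead / τ_mu | 120 / 360 / 300 min | GAuDi observable delays |

**Escape-rate calibration.** γ_e is the one default with a non-obvious
choice. Escapers compound at μ − δ with no differentiation penalty, so
under continuous light they overtake the live population at a time set
almost entirely by γ_e. γ_e = 2e-4 h⁻¹ puts that takeover at ≈ 20 h after
differentiation and keeps the mean culture growth rate over hours 8–12 of
continuous light at ≈ 0.012 h⁻¹ — matching both reported behaviours of the
strain (takeover 15–20 h post differentiation; arrested-phase growth
< 0.04 h⁻¹). A 10× larger escape rate would put takeover at ~13 h and the
8–12 h growth rate at 0.066 h⁻¹, inconsistent with both.

**Light intensity** is not modelled; u is normalised to [0, 1] and
intensity effects are absorbed into k.

## Numerical choices

Reference simulations use `scipy.integrate.solve_ivp` (RK45,
rtol 1e-10/atol 1e-12), integrating knot-to-knot so the solver never steps
across a light discontinuity. GAuDi trajectories are rejected if the total
concentration drifts by more than 1e-6 relative or any state goes below
−1e-7 of the total (small negative round-off is clipped). Fractions are
clipped to [0, 1] only within 1e-8; larger excursions raise.

The controller and the GAuDi fitter use separate fast predictors: an exact
piecewise closed form for the scalar models and fixed-step RK4
(dt ≤ 2 min) for GAuDi. These are deterministic and smooth in their
parameters, which finite-difference optimisation needs; their agreement
with the reference solver is tested.

## Turbidostat

Three modes: `batch` (no dilution), `grow_dilute` (grow to OD 0.6, dilute
instantaneously to OD 0.4, composition preserved), `constant_od` (dilution
continuously equals the culture growth rate; a non-growing culture gets
zero dilution and a logged warning). OD is total (live + dead)
concentration times 1.0. Pump kinetics are not modelled. Growth rates are
recovered per inter-dilution segment as the least-squares slope of log OD
versus time; segments with fewer than three points are skipped and
reported.

## Synthetic cytometry

The generator emulates the study's sampling conditions: 5000 events per
sample, species drawn multinomially from the (delayed) true composition,
log-normal fluorophore signals per species with the "on" level ~10× above
the 200 a.u. classification threshold and the "off" level ~10× below,
measured channels mixed by a symmetric 8% spillover matrix, a 10% debris
cluster displaced low in (FSC, SSC), and additive Gaussian reactor noise
(sd 0.02) on steady-state fraction tables. Maturation is a per-species
observation delay: a sample at time t reports composition at t − τ_s
(renormalised), so the dead class (τ = 360 min) lags the differentiated
class (τ = 120 min). Seeds are explicit everywhere (`numpy` SeedSequence
spawning per sample); identical seeds reproduce tables byte-for-byte.

What the generator does *not* emulate: instrument-accurate FCS binaries
(CSV stands in), autofluorescence spectra, signal-dependent spillover,
doublets, or day effects. Passing the end-to-end recovery tests therefore
shows the analysis chain is self-consistent under the stated measurement
model, not that it would be unbiased on any real cytometer.

## Cytometry analysis

Unmixing left-multiplies measured channels by the inverse spillover matrix
(singular matrices rejected). Gating fits a Gaussian KDE (Silverman
bandwidth, deterministic training subsample) on (log FSC, log SSC) and
keeps events whose density reaches the level enclosing 90% of the density
mass *and* which fall in the grid-connected density region containing the
global mode; the connectivity condition is what rejects a displaced debris
cluster regardless of its mass. Degenerate scatter keeps everything with a
warning. Classification is strict-greater-than thresholding at 200 a.u.:
mNeonGreen for the core scheme; for GAuDi, dead = below both live markers,
else differentiated by mScarlet-I; for the two-cassette scheme a 2×2 logic
on (mNeonGreen, mScarlet-I). GAuDi compositions are also reported
live-only (dead excluded, renormalised). Escapers look non-differentiated
(cassette loss removes the marker) — they are counted in the live
non-differentiated pool, which is also what the controller assumes.

## Fitting

Bounded least squares (scipy `least_squares`, trust-region reflective) in
log10 parameter space, bounds [1e-10, 10] per rate, multistart from
log-spaced (single rate) or seeded log-uniform (GAuDi) initial guesses;
the best start wins and all starts are reported. Delays are pure time
shifts of model predictions before residuals are formed — not delay ODEs.
μ is fixed from the pre-induction OD slope rather than co-fitted
(identifiability); all observables carry equal weight. Parameters whose
near-optimal starts disagree by more than 50% are flagged unidentifiable
(e.g. k on dark-only data).

## Control

Receding horizon of 10 duty cycles of 30 min (5 h); duties realised as ON
at the start of each cycle; squared set-point error summed on a 5-min
prediction grid; L-BFGS-B under box bounds with warm starts shifted by one
sampling interval; on optimiser failure the warm start is kept and a
warning logged. The state estimate takes the measured fraction as the
model state at t_now − τ (τ = sampling delay, default 20 min, plus the
observation delay) and integrates forward over the applied light. For
GAuDi the controller tracks a full four-species internal state, re-balances
its live differentiated split to each measurement at the measurement's
effective time, and integrates forward. All optimised segments covering
the inter-sample interval are applied (sampling every 1 h two-reactor,
2 h single-reactor).

Two behaviours worth knowing:

* **Duty-cycle ripple.** ON-at-start-of-cycle realisation makes the held
  fraction oscillate with trough depth ≈ f*(1 − e^(−φ(1−d)P)) — about 1.7
  points at the 40% set point — around a correctly-held mean. Samples
  taken at cycle boundaries read the trough; the settling tests use bands
  that accommodate this.
* **Finite control horizon of the GAuDi loop.** Because escapers are
  immune to differentiation, holding a set point consumes the convertible
  pool: the required light grows until it saturates and the composition
  collapses. At defaults the 40% single-reactor loop holds its band from
  the first post-delay sample (t = 4 h) until ≈ t = 48 h — a 44 h hold —
  for every seed tried. No light policy can extend this indefinitely; it
  is the in-model analogue of the genetic-stability limit of growth-arrest
  circuits, and the reason the corresponding acceptance test of a full
  48 h hold fails by one 2-h sample.

## Problem sizes

Default analyses run at the study's scale: 5000 events/sample, 12 h
(settling) to 100 h (hold) closed-loop runs, 60 h GAuDi runs, 20-replicate
recovery suites. Reference grids use 201–2601 points as noted in the
tests; all quantities reported by `scripts/acceptance.py` are recomputed
from scratch at these sizes.

## Limitations

* The measurement model is a stand-in; its fluorescence levels and
  spillover are configuration, not science.
* No stochastic single-cell (CME) dynamics, no spatial patterning, no
  hardware (pump/LED driver) modelling, no Bayesian uncertainty on fits.
* The GAuDi fitter assumes the light programme excites all four rates;
  weakly excited datasets are flagged rather than regularised.
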