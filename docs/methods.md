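# Methods

## Scope and model chain

`celldose` models the dosimetry of a radiolabelled compound internalized by
a single average cell, and the radiobiological statistics built on top of
it. The chain is:

1. gamma-counter counts → activity (counter efficiency ε),
2. activity at measurement time → initial activity A₀ (inverse decay law),
3. A₀ → cumulated activity Ã over the incubation interval (closed-form
   integral of exponential decay),
4. Ã split nucleus/cytoplasm by the measured nuclear fraction of
   internalized activity,
5. compartment doses via the 2×2 cellular S-value bilinear form, or via
   Monte Carlo electron transport in a sphere phantom,
6. survival-curve fitting, IC₅₀ and RBE on the resulting doses.

## Kinetic assumptions

The uptake model is *instant uptake, physical decay only*: the entire
internalized activity is assumed present from t = 0 and to change only by
radioactive decay until the measurement at t (default 24 h). No uptake
ramp, no biological washout, no compartmental exchange. Under this
assumption back-extrapolation is exact inversion of the decay law, and the
cumulated activity has the closed form

    Ã = (T_p/ln2) · A₀ · (1 − exp(−ln2·Δt/T_p)).

The prefactor 1/ln2 = 1.4427 is the quantity conventionally printed as
1.44; the package uses ln 2 to machine precision throughout, and the
upper bound Ã ≤ A₀·T_p/ln2 enforced on `CumulatedActivity` uses the same
constant so the infinite-time limit is admissible.

cpm → Bq assumes a 1-minute counting window: activity = (cpm/60)/ε. The
counting window is not part of the record format; if a different window
was used, the cpm column must be pre-normalized to counts per minute.

Counts are taken as the activity of the *average cell*. Well-level counts
(the raw gamma-counter output for ~50 000 cells) must be divided by the
cell number before absolute per-cell doses are meaningful; all dose
*shares* are invariant under this rescaling, which is why the share
quantities are the ones anchored to published values.

Surface-bound activity is carried in the record but never enters the dose
chain: electrons emitted at the membrane or in the medium are taken to
deposit nothing in the nucleus, consistent with the nanometre-to-micron
ranges involved.

## MIRD compartment dosimetry

Doses are the standard bilinear form over (Ã_N, Ã_Cy) with a 2×2 S-value
matrix. The shipped default `Tc99m_MIRD` is the published cellular
S-value set for the ⁹⁹ᵐTc Auger + internal-conversion electron emission in
a 4 μm cell with a 2 μm nucleus (β and photon contributions excluded;
their yield/local deposit is negligible at this scale):

| entry | Gy/(Bq·s) |
|---|---|
| S(N←N) | 1.19×10⁻² |
| S(Cy←N) = S(N←Cy) | 1.82×10⁻⁴ |
| S(Cy←Cy) | 1.74×10⁻³ |

**Total-dose convention.** "Total cell dose" defaults to the *sum* of the
two compartment doses, D_cell = D_N + D_Cy. This is not the physical
energy-per-total-mass dose (available as `convention="mass_weighted"`),
but it is the convention under which the nuclear dose shares computed from
the mean nuclear uptake fractions (45% → ~84%, 22% → ~66%) reproduce the
published per-compound shares (≈85%, ≈65%); the nuclear *share*
D_N/(D_N+D_Cy) is identical under both conventions.

**Nuclear-fraction pooling.** Dose tables default to the per-compound
*mean* nuclear fraction applied to every activity level
(`nuclear_fraction_mode="mean"`), mirroring how per-compound shares are
quoted; `"per_record"` uses each row's own measured fraction. The nuclear
fraction is empirically near-constant across applied activities, so the
two modes differ little.

## Monte Carlo transport

**Geometry.** Concentric spheres of liquid water (density 1 g/cm³):
optional central source sphere of 0.7 μm radius (a condensed-chromatin
stand-in for DNA-bound decays), nucleus 2 μm, cell 4 μm. Source positions
are uniform in the chosen volume (inverse-CDF on r³), emission isotropic.

**Physics.** Straight-ray continuous slowing-down approximation: each
electron travels along a fixed direction, losing energy at the
stopping-power rate; deposits are split between nucleus and cytoplasm by
exact ray–sphere chord geometry; kinetic energy remaining at the cell
boundary is scored as escaped; residual energy below the 10 eV floor
deposits locally. No angular scattering, no secondary electrons, no
photons, no straggling. The rationale: the target quantity is the energy
partition between two regions micrometres across. Sub-keV Auger electrons
(nanometre ranges) deposit where they are born regardless of scattering;
~120 keV conversion electrons cross the whole cell at near-constant LET,
so their partition is governed by chord lengths, which straight rays
score exactly. What this engine cannot do is nanodosimetry (DNA-scale
damage clustering) or backscatter-mediated dose redistribution — a
few-percent effect on compartment doses that is part of the engine's
stated ~10% accuracy envelope rather than its model.

**Stopping power.** The packaged table (`data/water_estopping.csv`,
10 eV – 200 keV, 240 log-spaced points) is computed from the
low-energy-corrected Bethe parameterization
S(E) = 785·(ρZ/AE)·ln[1.166(E+0.85J)/J] eV/Å with J = 75 eV for water.
Spot checks against reference collision stopping powers: ~2–3% at
1–10 keV, ~30% low at 120 keV (the formula is non-relativistic). The
high-energy bias rescales deposits that are small and nearly equal per
unit chord in both compartments, so dose *shares* are robust to it;
absolute S-values for conversion-electron-dominated sources inherit part
of it. The table path is configurable, so an evaluated table can be
substituted without code changes.

**Numerics.** The CSDA range R(E) is the trapezoid integral of 1/S on the
table grid; energy after a path s is R⁻¹(R(E)−s). Both directions
interpolate log-log through the same nodes, so they are exact mutual
inverses and per-history energy conservation holds to round-off (asserted
at ≤10⁻⁹ relative). Segment deposits are clamped to [0, total] against
round-off. A zero path returns the energy unchanged, exactly.

**Statistics.** Each spectrum line is simulated with `n_histories`
independent tracks (default 10⁵); per-decay means are yield-weighted sums
of per-line means, and standard errors combine per-line history-level
variances in quadrature with the yields. All sampling flows from one
`numpy` PCG64 generator seeded by the caller; identical seed + inputs give
bit-identical results.

**Spectrum input.** Two-column text (energy_keV, yield_per_decay), `#`
comments, comma or whitespace separated. The packaged `tc99m_like` fixture
mimics the *structure* of the ⁹⁹ᵐTc electron emission — a sub-keV Auger
cascade (~0.7 keV/decay), heavily-converted ~1.6–1.9 keV electrons from
the low-lying 2.17 keV transition (~1.5 keV/decay), and sparse
119–140 keV conversion electrons (~12 keV/decay) — with round synthetic
numbers. It is explicitly **not** evaluated nuclear data; quantitative
S-value validation against the published ⁹⁹ᵐTc values should use a
user-supplied evaluated (e.g. ICRP-107) electron spectrum through the same
entry points. With the synthetic fixture, the homogeneous-nucleus
configuration lands within ~5% of the published S(N←N), and the test
suite asserts the engine-level 10% bound while reporting the achieved
deviation.

## Survival model and RBE

The survival model is the single-parameter exponential ("single-hit
linear") SF = exp(−κD). This is the only one-parameter curve consistent
with a κ-only uncertainty budget, and the RBE definitions close under it:
RBE₀.₅ = κ_test/κ_ref exactly, RBE₂Gy = exp(2Δκ). Fitting is least squares
on ln SF with no intercept (SF(0) ≡ 1 by construction); per-point SF
standard errors, when given, enter as 1/se² weights on the log scale.
Zero-SF points cannot enter a log fit and are dropped with a warning
rather than pseudo-counted. κ's standard error uses the residual variance
on n−1 degrees of freedom, and `SurvivalFit.ci95()` uses the Student-t
quantile at those degrees of freedom — with the typical 6-dose design the
normal quantile would undercover noticeably.

RBE uncertainties are first-order delta-method propagation treating the
two κ estimates as independent; `rbe_sampling` provides a Monte Carlo
propagation used in tests to validate the formulas (agreement within 5%
at typical κ/se ratios).

IC₅₀ is computed by the same exponential fit with applied activity as the
covariate: IC₅₀ = ln2/λ̂. Data whose fitted slope is non-positive (survival
not decreasing with activity) raise instead of extrapolating a crossing.

γ-H2AX foci and micronucleus summaries are descriptive: mean ± SD of foci
per nucleus normalized to control both as a ratio and as a difference
(both conventions are in use, so both are emitted), and micronuclei per
1000 binucleated cells with optional control normalization.

## Synthetic data generator

The generator emulates the statistical structure of the uptake and
clonogenic experiments, not any specific dataset:

- internalized fraction f(A) = f_max/(1+A/k_sat): saturable uptake,
  maximal in percent terms at the lowest applied activities. Defaults
  f_max = 0.08, k_sat = 2 MBq give percent-internalized values falling
  from ~8% to ~2% over 7.4 kBq–7.4 MBq, the observed range for the
  less-internalizing compound. This hyperbola is a phenomenological
  choice; no mechanistic claim (passive diffusion is the likely mechanism)
  is attached.
- counts: Poisson around f(A)·A·60·ε with a 1-minute window at ε = 0.54,
  i.e. pure counting statistics; surface counts are a fixed multiple
  (default 4) of internalized counts.
- nuclear fraction: truncated normal on [0, 1] around the compound mean
  (defaults 0.45 ± 0.05), reproducing the near-constancy of the nuclear
  fraction across activities.
- survival: SF = exp(−κD) times median-1 lognormal noise with log-SD
  √ln(1+cv²); default cv = 5% matching few-percent replicate scatter.

What the generator does *not* emulate: cell-to-cell activity
heterogeneity (the dose model is a MIRD-style average cell), uptake
kinetics during incubation, dose-rate effects on survival, and any
correlation between uptake and survival noise. Passing tests on synthetic
data therefore demonstrate correctness of the estimators and the dose
arithmetic under the stated model, not robustness to those real-data
features.

## Problem sizes and tolerances

Default problem sizes were chosen so each statistical check is decisively
powered: 10⁵ histories per spectrum line (Monte Carlo standard errors
~0.1% of the nuclear S-value), 500-replicate κ-recovery studies (bias
resolution well under the 2% band), 10⁵-draw sampling validation of the
error propagation. The full test suite runs in a few seconds.

Key tolerances: closed-form Ã vs numerical quadrature 0.5%; per-history
and aggregate energy conservation 10⁻⁹ relative; κ-recovery bias < 2% with
95% CI coverage required in [90%, 98%]; MC S(N←N) vs the published value
within 10% (engine-level bound; see the spectrum caveat above).

## Known limitations

- Absolute doses inherit the instant-uptake assumption and the per-cell
  normalization of the input counts; only dose shares are anchored to
  published values.
- The straight-ray CSDA engine is not a track-structure code: no
  nanometre-scale clustering, no scattering-induced path lengthening
  (real low-keV electron tracks are ~2× shorter in radial extent than
  their path length), no secondaries.
- The Bethe-parameterized stopping table is non-relativistic; above
  ~50 keV it underestimates stopping power by tens of percent.
- The exponential survival model cannot represent shouldered survival
  curves (linear-quadratic behaviour); it is appropriate for the
  high-LET-like, shoulderless response of DNA-incorporated Auger emitters.
- RBE propagation treats the reference and test κ as independent and
  their estimates as approximately normal.
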