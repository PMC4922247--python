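# Methods

`scopetrack` implements a lab-to-field analysis for individual ecophysiology:
metabolic phenotypes are extracted from intermittent-flow respirometry traces,
in-situ activity metrics are computed from high-resolution acoustic-telemetry
tracks, and the two are linked by random-intercept linear mixed models with
fish-specific residual variances. Because studies of this design rarely
deposit raw traces or position fixes, the package ships a first-class
synthetic-data module that emulates the study structure with known ground
truth; every estimator is validated by parameter recovery against that truth.

## Respirometry

Intermittent-flow respirometry alternates sealed *measure* phases, during
which oxygen partial pressure declines linearly, with *flush* phases that
re-oxygenate the chamber (kept above 80% air saturation). Oxygen uptake for
one cycle is

    MO2 = K · V · β / M        [mg O2 kg⁻¹ h⁻¹]

with K the background-corrected slope of the O2 decline (kPa h⁻¹), V the
chamber volume corrected for fish volume (litres), β the oxygen solubility
(0.4755 mg O2 l⁻¹ kPa⁻¹ at 16 °C) and M body mass (kg). Fish volume is taken
to displace water at tissue density 1 g ml⁻¹, so V_eff = V − M; this is
standard respirometry practice. Slopes come from ordinary least squares per
measure phase after clipping the first 30 s (mixing transient); cycles with
r² < 0.90 are dropped as QC failures, not re-fitted. Background (microbial)
respiration is a constant blank slope subtracted from every cycle;
time-varying microbial growth is out of scope.

From the ~22 h post-chase cycle series, ten traits are derived:

| trait | definition | default window |
|---|---|---|
| SMR | mean of cycles at/below the 10th percentile of MO2 | all 22 h |
| MMR | max of the first three post-chase cycles | start of trace |
| AMS | MMR − SMR | — |
| recovery rate | OLS slope of the first five cycles vs time | start of trace |
| average MO2 | mean | last 19 h |
| metabolic variability | SD | last 19 h |
| routine MO2 | mean | last 4 h |
| spontaneous min / max | extremes | last 4 h |
| spontaneous AMS | max − min | last 4 h |

Percentiles use linear interpolation of the empirical distribution, and
membership in the "lowest decile" is `mo2 ≤ percentile`; this set always
contains at least the smallest cycle. "Highest of three consecutive
measurements" is read as the maximum of the *first three* cycles after the
chase (measurement begins within seconds of exhaustion); a sliding
three-cycle-mean alternative is available via `TraitConfig(mmr_mode=
"sliding")`. All trailing windows are anchored at the trace end. Traits that
cannot be computed (too few cycles) are NaN, never imputed.

## Morphology and phenotype reduction

Fineness ratio FR = fork length / maximal body depth is the sole shape
metric (hydrodynamically efficient fish fall roughly in 4.5–8). Metabolic
rates scale allometrically with mass, so SMR, MMR, AMS and the five
mass-dependent secondary traits are replaced by residuals of
log10(trait) on log10(mass); recovery rate and metabolic variability are
used raw. The seven secondary traits are reduced by PCA on their
correlation matrix (centred, unit sample variance, n−1). Axes are ordered
by eigenvalue; each loading vector is signed so its largest-magnitude
element is positive (raw-data loading signs are not otherwise identifiable).
Fish with any missing trait are excluded listwise.

## Activity metrics

Positions arrive as time-stamped planar coordinates at a nominal 30 s
transmitter burst interval with ~0.2 m error. The first 7 days after
release are discarded (re-acclimatisation) and metrics are computed over
the following 12 days. Days are calendar days (midnight anchored;
`day_anchor="release_time"` is available).

* `a_day`: sum of consecutive Euclidean distances within the day. On noisy
  fixes this is positively biased (each step adds noise in quadrature);
  the bias is documented, not corrected.
* `u_inst`: distance/time for consecutive pairs whose gap is within ±1 s of
  the burst interval (real systems jitter; the tolerance is configurable).
  A pair is retained only when its activity probability — that of the
  earlier fix — is ≥ 0.75.
* `u_max`: daily maximum of retained `u_inst`; pairs straddling midnight
  belong to the day of their first fix.
* `ar_day`: area of the union of 0.5 m dilations of the day's polyline
  segments (a lone fix gives a disc), overlaps merged within the day;
  merging across days is behind `merge_across_days`. Buffers are
  polygonalised with 32 segments per quarter arc (< 0.05% area error for a
  disc); a Monte-Carlo point-in-buffer oracle bounds the approximation in
  the tests.

## Activity-state HMM

A stationary fish still yields apparent steps because both fixes carry
isotropic Gaussian error: the inter-fix distance is then Rayleigh with
scale σ_noise·√2. A moving fish yields gamma-distributed steps. A two-state
Markov chain (inactive/active) switches between the regimes; Baum–Welch
(EM with scaled forward–backward) estimates σ_noise, the gamma shape/scale
and the transition matrix, and the forward–backward posterior of the active
state is `p_active`. Emission is on step length only — the smallest model
that produces the posterior the speed filter needs; location and turning
angle are deliberately not modelled. Chains are split into independent
segments at detection gaps longer than twice the burst interval, with no
imputation. Five seeded random restarts guard against local optima; states
are canonicalised so "active" has the larger mean step. Steps are floored
at 1 nm to keep log-densities finite for coincident fixes. The recursions
are JIT-compiled when numba is importable and fall back to pure numpy.

## Mixed models

Each activity measure y (with `u_inst` transformed to log(y + 0.1) for
normality) is modelled per observation i in fish j as

    y_ij = α + β_FL·FL_j + β_X·X_j + a_j + ε_ij,
    a_j ~ N(0, σ_a²),   ε_ij ~ N(0, σ_j²)

with one residual variance per fish. Repeatability is therefore
fish-specific: ICC_j = σ_a²/(σ_a² + σ_j²). The marginal covariance per fish,
V_j = σ_j²I + σ_a²J, has closed-form inverse and determinant, so each
likelihood evaluation is O(N); fixed effects are profiled out by GLS and the
log-SDs are optimised by multi-start L-BFGS-B (3 seeded starts). Every SD is
bounded below at 10⁻³ of the total residual SD: fish observed a handful of
times can otherwise drive their σ_j to zero, making the heteroscedastic
likelihood unbounded and the GLS weights singular. A σ_a at this floor is
reported as a boundary fit, not an error. Fixed-effect SEs come from the
inverse GLS information matrix.

Model selection per measure fits M0 (intercept), M1 (+FL) and M1a–g (one
phenotype covariate each: FR, SMR, MMR, AMS, MET1–3; one at a time to avoid
collinearity) under ML, compares them by AIC and by χ²(1) likelihood-ratio
tests (variance structure held fixed across nested pairs), and refits the
AIC-best model under REML for reported estimates. AIC counts all parameters
including the J per-fish SDs; this convention is stated because ΔAIC values
depend on it. Fish contributing fewer than 3 observations to a measure are
excluded from that measure's model.

**Known calibration property.** With ~16 fish, the χ²(1) LRT for a
fish-level covariate is anticonservative: simulation at the default design
(J = 16, 12 observations per fish, σ_a = 100, σ_j ∈ {50, 200}) shows a
~9–11% rejection rate at nominal 5%, for heteroscedastic and equal-variance
fits alike. This is the familiar small-group-count behaviour of fixed-effect
LRTs in mixed models, not a numerical defect; confidence-interval coverage
for β_FL is near nominal (about 94–95%) and per-fish ICCs are recovered
essentially unbiased. Users testing fish-level covariates on few fish should
treat p-values near 0.05 with caution.

## Synthetic data

The generator emulates the study conditions: ~23 perch (body mass
54.2 ± 15.3 g, fork length 16.4 ± 1.4 cm, FR 5.9 ± 0.3), SMR 79.0 ± 9.9 and
aerobic scope 313.8 ± 58.9 mg O2 kg⁻¹ h⁻¹ at 16 °C, 22 h traces, 19-day
tracks in a 1 ha lake at a 30 s burst interval with 0.2 m positional noise.
Body mass is coupled to length as mass ∝ FL³ with lognormal scatter
(σ = 0.08), the prefactor chosen analytically so the expected mass equals
the configured mean — this gives the log10–log10 mass correction realistic
structure. Per-cycle oxygen uptake follows smr + (mmr − smr)·e^(−t/τ)
(recovery half-life ~0.7 h) plus lognormal spontaneous excursions, optionally
modulated by a diel cycle (quieter in the dark hours); the measure-phase
slope is obtained by inverting the uptake equation, so noise-free traces
invert exactly through the respirometry module (a round-trip identity the
tests assert). Ground truth for the round trip is the trait set computed
from the generator's recorded per-cycle uptake values. Flush/measure
cadence defaults to 300 s/600 s and the O2 series is sampled every 5 s
(1 Hz is the instrument-realistic setting; both are config values, and the
suite's scaled problem sizes are stated in each test). Tracks follow a
two-state switching correlated random walk: inactive fish do not move,
active fish draw gamma step lengths (mean speed ~0.15 m s⁻¹) with
persistent headings, reflected at the lake boundary; fixes get Gaussian
noise and 3% random dropout.

What the generator does **not** emulate: multilateration error structure
(position noise is i.i.d. isotropic, real systems have geometry-dependent
error), tag-detection correlation, temperature drift, social interactions,
predator encounters (predation enters only as a cohort-exclusion count),
and non-gamma burst swimming. Passing recovery tests therefore demonstrates
internal consistency of the estimators under the stated model, not
robustness to every field pathology.

## Numerical choices and degenerate inputs

* OLS slopes and r² via centred sums; an exactly flat phase has r² = 1 only
  if variance is zero (guarded).
* MO2 is clamped at zero with a warning when the blank slope exceeds the
  cycle slope.
* EM convergence: relative log-likelihood change < 1e-8, max 500
  iterations; forward–backward uses per-step scaling (no log-sum-exp
  needed); gamma weighted MLE solves the digamma equation by Brent
  bracketing with a moment fallback.
* All generators and fits are pure functions of (config, seed); reruns are
  bit-identical, which the pipeline manifest (config hash + seed) records.

## Scaled problem sizes

The test suite and the acceptance script run scaled-down studies chosen to
exercise every code path while keeping recovery estimates stable: cohorts
of 4–50 fish, tracks of 1–4 days, 200 replicates for coverage, 100 for the
LRT rejection rate, 10 for ICC recovery (medians over 160 fish), 10⁶ points
for the Monte-Carlo geometry oracle. These sizes are the package's own
defaults for its validation experiments.
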