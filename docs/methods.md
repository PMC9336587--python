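# Methods

This note documents the models and procedures implemented in `brainthermo`,
the defaults chosen where the design was genuinely open, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## MRS thermometry (`thermometry`)

Temperature is a linear function of the NAA-minus-water chemical-shift
difference, `T = 100·(f_NAA − f_H2O + 2.665) + 37` (shifts in ppm, T in °C),
i.e. a water-shift sensitivity of −0.01 ppm/°C and 37 °C at a difference of
exactly −2.665 ppm. Conversion is exact and invertible
(`temperature_to_shift`); temperatures are carried at full float precision
and rounded only at map export (0.1 °C).

Shift differences outside a plausibility band (default 2.55–2.75 ppm,
≈ 28–48 °C) are *flagged* rather than rejected, because clinical inputs
contain artefacts the pipeline must survive; a strict mode raises instead.

QC filtering is config-driven: any named metric can carry lower/upper
bounds. Defaults: relative fit uncertainty ≤ 20 %, linewidth 1–15 Hz.
Excluded rows keep every violated bound as a reason code; the partition is
exhaustive, disjoint, and order-independent.

The default voxel layout has 82 voxels: 80 superficial voxels in four
medial→lateral column groups of 20 (Sup1–Sup4) plus one thalamic (id 81)
and one hypothalamic (id 82) voxel. The true row/column geometry of the
multivoxel grid is not recoverable from available descriptions; only the
medial→lateral grouping is meaningful, and the layout is replaceable.

## Sleep scoring and chronotype (`chronotype`)

Device-proprietary sleep scoring is replaced by a transparent detector:
activity is smoothed with an 11-min rolling median; epochs below a rest
threshold (default 10 counts) form candidate rest blocks; blocks separated
by less than 90 min of wake merge; blocks shorter than 3 h are discarded.
Episode boundaries are then refined on *raw* activity — the first/last
sustained (≥10 min) immobility run fixes sleep onset/offset — and raw
within-episode activity runs ≥ 5 min are wake bouts (they never split an
episode). On generator output, onsets and offsets are recovered at epoch
resolution.

Formulas (all clock arithmetic mod 24, clock-time averages circular):

- sleep duration = offset − onset; WASO = Σ wake-bout durations;
  total sleep time = duration − WASO;
  efficiency = time asleep / time in bed × 100.
- MSF_sc = mean free-day onset + (mean weekly duration)/2. MSW_sc likewise
  with scheduled-day onsets. PCSM = onset + TST/2 of the single night
  before measurement.
- SJL_sc: when free-day sleep is on average longer than work-day sleep,
  |free onset − work onset| (equivalently |MSF_sc − MSW_sc|); otherwise
  |free offset − work offset|. Requires at least one day of each type.
- `normalize_time(t, MSF_sc) = ((t − MSF_sc) mod 24)/24`, the proportion of
  a linearized unit circle with 0 = MSF_sc.

Whether MSF_sc should average free-day onsets arithmetically or circularly
is ambiguous; the circular mean is used (it equals the arithmetic mean
whenever onsets do not straddle midnight, and behaves correctly when they
do).

## Rhythm detection (`rhythm`)

**Preprocessing** (idempotent, reason-coded): drop the first 2 h (probe
stabilization); remove samples outside plausibility bounds (30–43 °C brain,
30–42 °C body — this removes impossible negative values, including those
flanking gaps); flag samples adjacent to gaps (spacing > 3× median
interval); drop TTM-masked spans and post-TTM samples until the rewarming
trend first inflects; start the analysis window at the first sample
exceeding the retained minimum. Eligibility: ≥ 24 h window span for
summaries, ≥ 36 h of continuous (gap-free summed) coverage for rhythm
analysis. Series are never resampled to a uniform grid; all fits use the
irregular timestamps directly.

**Cosinor fit.** Least squares of `mesor + b·t + A·cos(2π(t−φ)/τ)` at fixed
period τ. Significance is the extra-sum-of-squares F test against the
straight line (intercept + trend) — not against a flat constant — so slow
drift alone is never called a rhythm. The mesor is the fitted value at the
mean sample time.

**Autocorrelation correction.** Minute-resolution physiological noise is
strongly autocorrelated, which makes iid F tests wildly anticonservative.
Residuals are modelled as AR(1) plus white measurement noise; from the
lag-1 and lag-2 residual autocorrelations (r1 = φλ, r2 = φ²λ) the
low-frequency variance-inflation factor `VIF = λ(1+φ)/(1−φ) + (1−λ)` is
estimated. The F statistic is divided by the VIF and the residual degrees
of freedom replaced by n/VIF (an effective-sample-size correction). Under
white noise VIF ≈ 1 and the standard test is recovered; the correction is
skipped when residuals sit at numerical-noise level.

**Period estimation** over a period grid (default 16–32 h, 0.1 h step):

- `cosinor_scan`: argmin-SSE period via batched 4×4 normal equations; its
  p-value carries a false-alarm correction `1 − (1−p)^M` with
  `M = span·(1/τ_min − 1/τ_max)` independent frequencies, because the
  period was selected by search.
- `lomb_scargle`: classic Lomb–Scargle periodogram (vectorized,
  verified against `scipy.signal.lombscargle` to 1e-13) on linearly
  detrended data; peak power is normalized by the post-fit residual
  variance (the total-variance normalization saturates at n/2 and cannot
  express strong signals), deflated by the VIF, and converted to the
  analytic false-alarm probability `1 − (1 − e^(−z))^M`.
- `harmonic_regression`: the cosinor fit with τ fixed at 24 h; always
  reports period 24 with the trend-line comparison p-value.

**Classification.** `is_rhythmic` = criterion (i) AND criterion (ii).
(i): a 36 h sliding window (6 h step) scan finds ≥ 1 window whose best
period lies in [22, 26] h with scan-corrected p < α (this operationalizes
"a ~22–26 h period in at least part of the series"; the window/step sizes
are config-driven and replace non-reproducible visual inspection).
(ii): ≥ 1 whole-series method is significant with period in [22, 26] h
("at least one of" replaces an and/or across three software packages; all
method outputs are retained so stricter consensus rules can be applied).
α = 0.05 throughout, no multiplicity correction across methods, band slack
0 by default. Ineligible series get `is_rhythmic = None` — not
classifiable, distinct from not rhythmic.

Measured operating characteristics at the generator's defaults (96 h,
minute sampling): false-rhythmic rate 5/200 on white noise and 9/200 on
AR(1) noise with drift; detection 200/200 for a 0.8 °C rhythm over 0.2 °C
noise; 30 h rhythms are classified rhythmic in 0/20 runs. These are
computed by the test suite, not assumed.

**Extrema and summaries.** Daily extrema use consecutive 24 h blocks
anchored at the window start (calendar anchoring available by flag since
either convention is defensible); ties resolve to the earliest occurrence;
days with < 50 % expected coverage are flagged and withheld. Summaries
(mean/min/max/range) use all retained in-window samples.

## Circular statistics (`circstats`)

Clock hours map to angles by t·2π/24, midnight at 0. Circular mean/SD via
the resultant vector (SD = √(−2 ln R̄), infinite at R̄ = 0 where the mean is
undefined). Rayleigh Z = nR̄² with the standard series approximation
`exp(−Z)[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)]`, clipped to
[0, 1]; validated against `pingouin.circ_rayleigh` and calibrated against
uniform simulation. Watson's two-sample U² is computed from the ranked
combined sample (tied blocks take the block-end CDF difference); its
p-value is by label permutation (default 9999, seeded; samples are
canonically ordered so swapping groups is a no-op), with the classical
critical-value bracket (0.152/0.187/0.268 for P 0.10/0.05/0.01) reported
alongside, matching the "P > 0.1" reporting convention.

## Temperature and outcome models (`models`)

Gaussian mixed models are fitted by REML (`statsmodels MixedLM`) with a
random intercept and, when every subject has ≥ 2 distinct time values, a
random time-slope per subject. Categorical codings: sex reference = luteal
female; region reference = Sup1 (Thalamus in the deep-only variant, which
restricts rows to thalamus + hypothalamus); in-scanner sleep coded
yes/maybe/no with reference no. Missing values are handled by complete-case
filtering only (no imputation). Wald CIs use t quantiles with
between-subject degrees of freedom (n_subjects − 1), since subject-level
effects carry roughly that many df and z intervals undercover at cohort
sizes in the tens. A singular random-effects covariance triggers an
intercept-only refit; a fully collapsed structure falls back to OLS. All
fallbacks are flagged in the result's notes.

The mortality model is a binomial logit (death = 1) on age, sex, mean
brain temperature, brain temperature range and daily-rhythm status. A
per-patient random intercept is stated in the full specification but is
unidentifiable with one observation per patient, so the default fit is the
plain fixed-effects logit (identical likelihood maximum). Complete
separation (detected by exploding slopes/SEs) falls back to Firth's
Jeffreys-prior penalized fit, flagged. Estimates and CIs are exponentiated
to odds ratios; transformed CIs are asymmetric.

Power for detecting a diurnal mean-temperature difference is estimated by
Monte-Carlo: subjects with a random intercept (default SD 0.3 °C) measured
at three normalized times (0.21, 0.52, 0.81), within-subject SD 0.35 °C —
these variance components are package defaults, not published values. The
time effect is tested on within-subject centred data, which for this
balanced design is exactly the random-intercept mixed-model test; this
keeps each replicate at closed form.

## 24 h map extrapolation (`heatwave`)

Per (group, voxel) cell, a fixed-24 h sinusoid `M + a·cos(ωt) + b·sin(ωt)`
is least-squares fitted to the three time-point means duplicated one cycle
later (six points). Duplication leaves the solution unchanged and with
three parameters and three distinct times the fit interpolates the means
exactly (< 1e-9 °C). The fitted minimum is `mesor − amplitude` at
acrophase + 12 h; a zero-amplitude cell has an undefined minimum time. The
time axis is clock hours by default (group curves are deliberately not
chronotype-corrected), with a normalized-time option. Group means are
assumed computed per voxel across subjects before fitting. Hourly export
rounds to 0.1 °C; fits are kept at full precision, so re-importing
full-precision output reproduces them bit-for-bit.

## Synthetic data (`synthdata`)

One global seed expands into independent per-generator substreams
(`SeedSequence` spawn keys), so adding a generator never perturbs existing
output, and every generator is a pure function of its config.

- **Patient series**: 96 h at 1-min sampling; mesor 38.5 °C; amplitude
  0.8 °C when rhythmic (the plausible clinical range is ~0.3–1.5 °C);
  AR(1) noise (φ = 0.9 per minute, stationary SD 0.2 °C — white noise alone
  would overstate detector power) plus 0.05 °C white sensor noise and a
  random linear drift (SD 0.1 °C/day); two gaps of 0.5–2 h; a 30 %
  chance per gap of an impossible −99 value at the gap edge; optional TTM
  plateau at 34 °C.
- **MRS tables**: 40 subjects (14 luteal female, 6 non-luteal female, 20
  male) × 3 sessions (09:30, 16:30, 23:30) × 82 voxels. Additive truth:
  region offsets (Sup1 0, Sup2 0.3, Sup3 0.4, Sup4 0.5, Thalamus 1.64,
  Hypothalamus 1.08 °C), luteal-female effect +0.36 °C over both other
  groups, diurnal effect 0.57 °C per unit normalized time, ageing
  0.03 °C/yr deep vs 0.01 °C/yr superficial, subject intercept/slope SDs
  0.3/0.2 °C, residual SD 0.35 °C. Temperatures are back-converted to
  (NAA = 2.035 ppm, water) shift pairs; 24 QC violations (high fit
  uncertainty) are seeded per dataset.
- **Actigraphy**: 7 days of 1-min epochs; bed ~23:15 (±20 min/night),
  onset latency 15 min, offset ~07:30; wake activity gamma with mean 150
  counts, in-bed wakefulness 25, sleep exponential mean 1; wrist
  temperature rises 2.5 °C during sleep; ~2 wake bouts of 5–20 min per
  night; two free days per week; optional social-jetlag nights delayed
  2.5 h.
- **Outcome cohorts**: n = 500; age ~ N(47, 17) truncated to [16, 95];
  mean T_Br ~ N(38.5, 0.8); range ~ N(3.2, 1.1); daily rhythm
  Bernoulli(0.25); female Bernoulli(0.18). Death is drawn from the logit
  model with ORs 0.05 (rhythm), 1.10 (per year), 0.42 (per °C of mean),
  1.0 (range, sex), anchored at a 30 % baseline death rate at the
  reference covariates.

Default effect sizes equal the magnitudes the pipeline is designed to
detect, so recovery tests double as plausibility checks; all are
configurable.

**What the generators do not emulate**: non-sinusoidal or phase-drifting
rhythms, realistic TTM cooling/rewarming ramps (stylized as plateaus),
state-dependent artefact structure, menstrual-phase dynamics within a
session, naps and split sleep, and any spatial correlation between voxels
beyond the region offsets. Passing tests therefore demonstrate internal
consistency and statistical calibration under these stylized conditions,
not performance on real recordings.

## Numerical choices and degenerate inputs

- Cosinor designs are rank-checked; all-one-phase sampling raises a
  degenerate-fit error. Scan grids use batched normal equations (periods
  vectorized).
- The VIF correction clips r1, r2 to [0, 0.99], φ to ≤ 0.98, and floors
  the effective sample size at 10.
- The Rayleigh p is clipped to [0, 1]; R̄ < 1e-12 is treated as zero
  resultant (undefined mean, p = 1 region).
- `normalize_time` guards the float round-up at the wrap point so its
  range is exactly [0, 1).
- Permutation p-values use the add-one estimator (k+1)/(B+1).

## Known limitations

- Dedicated rhythm-analysis suites ship larger batteries of period
  algorithms (FFT-NLLS, MESA, spectrum resampling, ...); this package
  represents the family with three estimators (cosinor scan, Lomb–Scargle,
  fixed-24 h harmonic regression) rather than reproducing any of them
  bit-for-bit.
- The sliding-window scan is a reproducible surrogate for visual rhythm
  assessment; its window/step defaults (36 h/6 h) are judgement calls.
- Supplementary-only QC thresholds are configurable defaults, not the
  original values.
- Environmental temperature enters the oral model raw (unsmoothed), and
  time enters the temperature models as a single linear term in normalized
  time; an optional harmonic basis can be added where curvature is
  suspected.
- Wald/REML inference is approximate at small subject counts even with
  the t-df correction; profile likelihood is not implemented.
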