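# brainthermo

Tools for analysing human brain temperature and its daily rhythm: MRS
chemical-shift thermometry, actigraphy-based chronotype normalization,
rhythm detection in intensive-care temperature traces, circular statistics
on event timings, mixed-effects temperature models, a logistic mortality
model, and 24 h sinusoidal brain-temperature maps. It is aimed at
researchers working with clinical temperature monitoring data (e.g.
intracranial probes in traumatic brain injury) and healthy-volunteer MRS
thermometry cohorts.

## The science in brief

**Thermometry.** The chemical-shift difference between the water and
N-acetylaspartate (NAA) resonances is temperature dependent (water moves
−0.01 ppm/°C; NAA is stable), so brain temperature follows from one
spectrum per voxel:

    T_Br = 100 · (f_NAA − f_H2O + 2.665) + 37          [°C, shifts in ppm]

**Chronotype.** Clock time is a poor circadian coordinate because people
differ in phase. Each subject's chronotype is summarized by MSF_sc — the
sleep-corrected midpoint of sleep on free days (mean free-day sleep onset
plus half the average weekly sleep duration) — and event times enter the
models as the proportion of a linearized unit circle where 0 = MSF_sc and
1 = 24 h.

**Rhythm detection.** A patient temperature series has a *daily rhythm*
when (i) a sliding-window cosinor scan finds a significant local period of
~22–26 h in at least part of the series, and (ii) at least one whole-series
period analysis (cosinor grid scan, Lomb–Scargle, or fixed-24 h harmonic
regression) reports a significant period inside 22–26 h. Every
significance test compares the sinusoid against a straight line and
corrects for residual autocorrelation; scanned periods additionally carry
a false-alarm correction for the search.

**Models.** Oral/brain temperature is modelled with Gaussian linear mixed
models (fixed effects: normalized time, sex, region or environmental
temperature, age, BMI or in-scanner sleep; random intercept and time-slope
per subject). Mortality in intensive care is a binomial-logit model on
age, sex, mean brain temperature, temperature range, and daily-rhythm
status, reported as odds ratios. The HEATWAVE-style map fits a fixed-24 h
sinusoid through per-voxel group mean temperatures measured at three time
points (an exact interpolation) and emits an hourly 82-voxel grid at
0.1 °C export resolution.

Because the underlying patient data are access-restricted, the
`synthdata` module generates every input with known ground truth (minute
resolution AR(1)-noise temperature traces with gaps/artefacts/TTM spans,
MRS voxel tables back-converted to shift pairs, week-long actigraphy with
planted sleep windows, and logistic outcome cohorts), so every stage is
testable end to end.

## Worked example

```python
import brainthermo as bt

cfg = bt.GeneratorConfig(seed=7)

# a rhythmic 96 h patient trace, preprocessed and classified
series, truth = bt.gen_patient_series(cfg, rhythmic=True)
series, window = bt.preprocess_series(series)
call = bt.classify_daily_rhythm(series, window)
print(call.is_rhythmic, call.method_periods)

# outcome model on a synthetic 500-patient cohort
cohort, _ = bt.gen_cohort_outcomes(cfg)
result = bt.fit_outcome_model(cohort)
print(result.term("daily_rhythm").or_)
```

prints (seed 7):

```
rhythmic: True
  cosinor_scan: period 23.9 h, p = 0
  lomb_scargle: period 23.9 h, p = 0
  harmonic_regression: period 24.0 h, p = 1.8e-135
daily_rhythm: OR 0.067 (95% CI 0.027-0.169)
age: OR 1.099 (95% CI 1.077-1.121)
brain_mean_c: OR 0.296 (95% CI 0.207-0.423)
```

The trace was generated with a 24 h, 0.8 °C-amplitude rhythm — all three
period methods find it. The cohort was generated with odds ratios 0.05
(daily rhythm), 1.10 (per year of age) and 0.42 (per °C of mean brain
temperature); the fitted ORs recover these within their confidence
intervals: a daily brain-temperature rhythm is strongly protective, age
increases the odds of death, and a warmer mean brain temperature is
associated with survival.

A `thermo` console script exposes the same pipeline from the shell
(`thermo simulate`, `thermo convert`, `thermo chronotype`, `thermo rhythm`,
`thermo circ`, `thermo fit`, `thermo heatwave`, `thermo power`).

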