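"""Synthetic data generators with known ground truth.

Every pipeline stage in this package is exercised against data whose
generative parameters are known exactly, so recovery can be verified.  The
generators emulate the structure of the study data the pipeline targets:

* patient temperature traces: minute-resolution, ~96 h, sinusoidal daily
  rhythm (mesor ~38.5 degC, amplitude 0.3-1.5 degC) over AR(1)
  physiological noise plus white measurement noise, with gaps, impossible
  negative artefacts flanking gaps, and optional TTM cooling spans;
* healthy MRS voxel tables: per subject x session x voxel temperatures
  built from region, sex, age and time-of-day effects plus subject random
  intercept/slope and residual noise, back-converted to NAA/water
  chemical-shift pairs (NAA fixed at 2.035 ppm) with seeded QC violations;
* week-long actigraphy traces with planted sleep windows, day types and
  optional social-jetlag nights;
* patient outcome cohorts drawn from a logistic mortality model on age,
  sex, mean brain temperature, temperature range and daily-rhythm status.

Default effect sizes are the magnitudes the pipeline is designed to detect
(sex effect 0.36 degC, diurnal effect 0.57 degC over the normalized cycle,
deep-region ageing 0.6 degC / 20 yr, mortality odds ratios 0.05 for a
daily rhythm, 1.10 per year of age, 0.42 per degC of mean temperature).
Each generator is a pure function of its config; a single global seed
expands into independent per-generator substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from .rhythm import TemperatureSeries
from .thermometry import VoxelLayout, temperature_to_shift

__all__ = [
    "GeneratorConfig",
    "PatientSeriesParams",
    "MRSParams",
    "ActigraphyParams",
    "CohortParams",
    "gen_patient_series",
    "gen_mrs_dataset",
    "gen_actigraphy",
    "gen_cohort_outcomes",
]

_STREAMS = {"patient": 1, "mrs": 2, "actigraphy": 3, "cohort": 4}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Independent substream: adding a generator never perturbs the others."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], index))
    )


@dataclass(frozen=True)
class PatientSeriesParams:
    length_h: float = 96.0
    sample_interval_min: float = 1.0
    mesor: float = 38.5
    amplitude: float = 0.8
    period_h: float = 24.0
    ar1_coef: float = 0.9
    noise_sd: float = 0.2          # stationary SD of the AR(1) component
    measurement_sd: float = 0.05   # white sensor noise
    drift_per_day: float = 0.1     # SD of a random linear drift, degC/day
    n_gaps: int = 2
    gap_length_h: tuple[float, float] = (0.5, 2.0)
    artefact_rate: float = 0.3     # probability a gap edge carries a -99 artefact
    ttm_span_h: float = 0.0        # >0 inserts one TTM plateau of this length


@dataclass(frozen=True)
class MRSParams:
    n_subjects: int = 40
    n_female: int = 20
    n_luteal: int = 14
    session_clock_times: tuple[float, ...] = (9.5, 16.5, 23.5)
    n_voxels: int = 82
    base_temp: float = 38.0
    region_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "Sup1": 0.0, "Sup2": 0.3, "Sup3": 0.4, "Sup4": 0.5,
            "Thalamus": 1.64, "Hypothalamus": 1.08,
        }
    )
    sex_effect: float = 0.36       # luteal female above male / non-luteal
    time_effect: float = 0.57      # degC per unit of normalized cycle time
    deep_age_slope: float = 0.03   # degC/yr in thalamus+hypothalamus (0.6/20 yr)
    sup_age_slope: float = 0.01    # degC/yr superficially
    age_range: tuple[float, float] = (20.0, 40.0)
    age_center: float = 30.0
    msf_mean: float = 3.93         # clock hours (~03:56)
    msf_sd: float = 1.0
    subject_intercept_sd: float = 0.3
    subject_slope_sd: float = 0.2
    residual_sd: float = 0.35
    naa_ppm: float = 2.035
    n_qc_violations: int = 24


@dataclass(frozen=True)
class ActigraphyParams:
    n_days: int = 7
    epoch_min: float = 1.0
    start_clock: float = 12.0
    bed_time: float = 23.25
    onset_latency_min: float = 15.0
    sleep_offset: float = 7.5
    night_jitter_min: float = 20.0
    waso_bouts_per_night: float = 2.0
    waso_bout_min: tuple[float, float] = (5.0, 20.0)
    wake_activity: float = 150.0
    inbed_wake_activity: float = 25.0
    sleep_activity: float = 1.0
    wrist_temp_wake: float = 31.5
    wrist_temp_sleep_rise: float = 2.5
    free_days: tuple[int, ...] = (5, 6)   # day indices treated as free
    social_jetlag_nights: tuple[int, ...] = ()
    social_jetlag_delay_h: float = 2.5


@dataclass(frozen=True)
class CohortParams:
    n_patients: int = 500
    age_mean: float = 47.0
    age_sd: float = 17.0
    age_bounds: tuple[float, float] = (16.0, 95.0)
    brain_mean_mu: float = 38.5
    brain_mean_sd: float = 0.8
    brain_range_mu: float = 3.2
    brain_range_sd: float = 1.1
    p_rhythm: float = 0.25
    p_female: float = 0.18
    baseline_death_rate: float = 0.30   # at reference covariates, no rhythm
    or_rhythm: float = 0.05
    or_age_per_yr: float = 1.10
    or_mean_per_c: float = 0.42
    or_range_per_c: float = 1.0
    or_female: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    patient: PatientSeriesParams = field(default_factory=PatientSeriesParams)
    mrs: MRSParams = field(default_factory=MRSParams)
    actigraphy: ActigraphyParams = field(default_factory=ActigraphyParams)
    cohort: CohortParams = field(default_factory=CohortParams)


# ---------------------------------------------------------------------------
# Patient temperature series
# ---------------------------------------------------------------------------

def gen_patient_series(
    config: GeneratorConfig, rhythmic: bool, index: int = 0
) -> tuple[TemperatureSeries, dict]:
    """Minute-level patient trace plus its ground-truth record.

    ``index`` selects an independent replicate substream under the same
    seed.  Non-rhythmic series keep the same noise model with zero
    amplitude.
    """
    p = config.patient
    import warnings as _w
    if rhythmic and p.length_h < 36.0:
        _w.warn("series shorter than 36 h cannot be classified for rhythm")
    rng = _rng(config.seed, "patient", index)
    dt_h = p.sample_interval_min / 60.0
    n = int(round(p.length_h / dt_h)) + 1
    t = np.arange(n) * dt_h
    phase = rng.uniform(0.0, p.period_h)
    clock_anchor = rng.uniform(0.0, 24.0)

    signal = np.zeros(n)
    if rhythmic:
        signal = p.amplitude * np.cos(2 * np.pi * (t - phase) / p.period_h)
    ar = np.zeros(n)
    if p.noise_sd > 0:
        innov_sd = p.noise_sd * np.sqrt(1.0 - p.ar1_coef**2)
        innov = rng.normal(0.0, innov_sd, n)
        innov[0] = rng.normal(0.0, p.noise_sd)
        ar = lfilter([1.0], [1.0, -p.ar1_coef], innov)
    white = rng.normal(0.0, p.measurement_sd, n) if p.measurement_sd > 0 else 0.0
    drift = rng.normal(0.0, p.drift_per_day) * (t / 24.0)
    values = p.mesor + signal + ar + white + drift

    ttm_mask = np.zeros(n, dtype=bool)
    if p.ttm_span_h > 0:
        start = rng.uniform(4.0, max(p.length_h - p.ttm_span_h - 4.0, 5.0))
        span = (t >= start) & (t < start + p.ttm_span_h)
        ttm_mask |= span
        values[span] = 34.0 + rng.normal(0.0, 0.1, int(span.sum()))

    keep = np.ones(n, dtype=bool)
    gap_edges = []
    for _ in range(p.n_gaps):
        glen = rng.uniform(*p.gap_length_h)
        gstart = rng.uniform(4.0, p.length_h - glen - 1.0)
        inside = (t > gstart) & (t < gstart + glen)
        keep &= ~inside
        gap_edges.append(gstart)
    for gstart in gap_edges:
        if rng.uniform() < p.artefact_rate:
            before = np.flatnonzero(keep & (t <= gstart))
            if before.size:
                values[before[-1]] = -99.0

    series = TemperatureSeries(
        times=t[keep], values=values[keep], clock_anchor=clock_anchor,
        source="brain", ttm_mask=ttm_mask[keep],
    )
    truth = {
        "rhythmic": rhythmic, "mesor": p.mesor,
        "amplitude": p.amplitude if rhythmic else 0.0,
        "period_h": p.period_h, "phase_h": phase,
        "clock_anchor": clock_anchor, "noise_sd": p.noise_sd,
        "ar1_coef": p.ar1_coef, "n_samples": int(keep.sum()),
    }
    return series, truth


# ---------------------------------------------------------------------------
# MRS voxel tables
# ---------------------------------------------------------------------------

def gen_mrs_dataset(
    config: GeneratorConfig, index: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Healthy-cohort voxel table (subject x session x voxel) with truth.

    Temperatures follow the additive structure the brain-temperature mixed
    model fits — region, sex, age, normalized-time fixed effects plus
    subject random intercept/slope and residual noise — and are
    back-converted to chemical-shift pairs so the thermometry stage can be
    tested end to end.  QC violations (high fit uncertainty) are seeded
    into randomly chosen rows.
    """
    m = config.mrs
    rng = _rng(config.seed, "mrs", index)
    layout = VoxelLayout(n_voxels=m.n_voxels)

    sexes = (
        ["luteal_female"] * m.n_luteal
        + ["nonluteal_female"] * (m.n_female - m.n_luteal)
        + ["male"] * (m.n_subjects - m.n_female)
    )
    ages = rng.uniform(*m.age_range, m.n_subjects)
    msf = rng.normal(m.msf_mean, m.msf_sd, m.n_subjects) % 24.0
    u0 = rng.normal(0.0, m.subject_intercept_sd, m.n_subjects)
    u1 = rng.normal(0.0, m.subject_slope_sd, m.n_subjects)
    sleep_levels = np.array(["no", "maybe", "yes"])

    rows = []
    for i in range(m.n_subjects):
        sid = f"S{i + 1:03d}"
        sex = sexes[i]
        sex_term = 0.0 if sex == "luteal_female" else -m.sex_effect
        for clock in m.session_clock_times:
            tnorm = ((clock - msf[i]) % 24.0) / 24.0
            sleep = str(rng.choice(sleep_levels, p=[0.6, 0.2, 0.2]))
            resid = rng.normal(0.0, m.residual_sd, m.n_voxels)
            for j, vid in enumerate(layout.voxel_ids):
                region = layout.region_of[vid]
                deep = region in ("Thalamus", "Hypothalamus")
                age_slope = m.deep_age_slope if deep else m.sup_age_slope
                temp = (
                    m.base_temp
                    + m.region_offsets[region]
                    + sex_term
                    + age_slope * (ages[i] - m.age_center)
                    + m.time_effect * tnorm
                    + u0[i]
                    + u1[i] * tnorm
                    + resid[j]
                )
                rows.append(
                    {"subject_id": sid, "sex": sex, "age": float(ages[i]),
                     "msf_sc": float(msf[i]), "session_clock_time": float(clock),
                     "time_norm": float(tnorm), "sleep": sleep,
                     "voxel_id": int(vid), "region": region,
                     "temperature_true": float(temp)}
                )
    df = pd.DataFrame(rows)
    df["naa_ppm"] = m.naa_ppm
    df["water_ppm"] = m.naa_ppm + temperature_to_shift(df["temperature_true"].to_numpy())
    df["fit_uncertainty_pct"] = rng.uniform(2.0, 15.0, len(df))
    df["linewidth_hz"] = np.clip(rng.normal(6.0, 1.5, len(df)), 1.5, 14.0)
    n_bad = min(m.n_qc_violations, len(df))
    bad_idx = rng.choice(len(df), size=n_bad, replace=False)
    df.loc[df.index[bad_idx], "fit_uncertainty_pct"] = rng.uniform(25.0, 60.0, n_bad)

    truth = {
        "sex_effect": m.sex_effect, "time_effect": m.time_effect,
        "deep_age_slope": m.deep_age_slope, "sup_age_slope": m.sup_age_slope,
        "region_offsets": dict(m.region_offsets), "base_temp": m.base_temp,
        "residual_sd": m.residual_sd,
        "subject_intercept_sd": m.subject_intercept_sd,
        "subject_slope_sd": m.subject_slope_sd,
        "n_qc_violations": n_bad,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Actigraphy
# ---------------------------------------------------------------------------

def gen_actigraphy(
    config: GeneratorConfig, index: int = 0
) -> tuple[pd.DataFrame, list[dict]]:
    """Week-long minute-epoch actigraphy trace with planted sleep windows.

    Returns the epoch table (timestamp, activity, wrist_temp_c, light_lux,
    day_type) and the list of planted episode truth records (clock-hour
    bed time, onset, offset and WASO bouts per night).
    """
    a = config.actigraphy
    rng = _rng(config.seed, "actigraphy", index)
    epochs_per_day = int(round(24 * 60 / a.epoch_min))
    n = a.n_days * epochs_per_day
    start = pd.Timestamp("2024-01-01") + pd.Timedelta(hours=a.start_clock)
    ts = pd.date_range(start, periods=n, freq=f"{int(a.epoch_min * 60)}s")
    hours_abs = a.start_clock + np.arange(n) * a.epoch_min / 60.0

    activity = rng.gamma(2.0, a.wake_activity / 2.0, n)
    wrist = a.wrist_temp_wake + rng.normal(0.0, 0.3, n)
    clock = hours_abs % 24.0
    light = np.where((clock > 7.0) & (clock < 22.0), rng.gamma(2.0, 150.0, n), 0.0)

    truths: list[dict] = []
    for d in range(a.n_days):
        jitter = rng.normal(0.0, a.night_jitter_min) / 60.0
        bed = a.bed_time + jitter
        if d in a.social_jetlag_nights:
            bed += a.social_jetlag_delay_h
        onset = bed + a.onset_latency_min / 60.0
        offset = 24.0 + a.sleep_offset + rng.normal(0.0, a.night_jitter_min) / 60.0
        if d in a.social_jetlag_nights:
            offset += a.social_jetlag_delay_h
        bed_abs = d * 24.0 + bed
        onset_abs = d * 24.0 + onset
        offset_abs = d * 24.0 + offset

        inbed_wake = (hours_abs >= bed_abs) & (hours_abs < onset_abs)
        asleep = (hours_abs >= onset_abs) & (hours_abs < offset_abs)
        activity[inbed_wake] = rng.gamma(2.0, a.inbed_wake_activity / 2.0, int(inbed_wake.sum()))
        activity[asleep] = rng.exponential(a.sleep_activity, int(asleep.sum()))
        wrist[asleep] += a.wrist_temp_sleep_rise
        light[asleep | inbed_wake] = 0.0

        bouts = []
        n_bouts = rng.poisson(a.waso_bouts_per_night)
        for _ in range(n_bouts):
            blen = rng.uniform(*a.waso_bout_min) / 60.0
            bstart = rng.uniform(onset_abs + 1.0, offset_abs - 1.0 - blen)
            bmask = (hours_abs >= bstart) & (hours_abs < bstart + blen)
            activity[bmask] = rng.gamma(2.0, a.wake_activity / 3.0, int(bmask.sum()))
            bouts.append((bstart % 24.0, (bstart + blen) % 24.0))
        day_type = "free" if (d + 1) % 7 in a.free_days else "scheduled"
        truths.append(
            {"night": d, "day_type": day_type, "bed_time": bed % 24.0,
             "sleep_onset": onset % 24.0, "sleep_offset": offset % 24.0,
             "onset_latency_min": a.onset_latency_min, "waso_bouts": bouts}
        )

    day_idx = (np.arange(n) * a.epoch_min / 60.0 + a.start_clock) // 24.0
    day_type_col = np.where(
        np.isin((day_idx.astype(int) + 1) % 7, a.free_days), "free", "scheduled"
    )
    df = pd.DataFrame(
        {"timestamp": ts, "activity": activity, "wrist_temp_c": wrist,
         "light_lux": light, "day_type": day_type_col}
    )
    return df, truths


# ---------------------------------------------------------------------------
# Outcome cohorts
# ---------------------------------------------------------------------------

def gen_cohort_outcomes(
    config: GeneratorConfig, index: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Patient outcome cohort drawn from a logistic mortality model.

    The linear predictor is anchored at reference covariate values (age at
    its mean, mean brain temperature 38.5 degC, range 3.2 degC, male, no
    rhythm) so that the configured baseline death rate is the death
    probability at the reference point.
    """
    c = config.cohort
    rng = _rng(config.seed, "cohort", index)
    n = c.n_patients
    age = np.clip(rng.normal(c.age_mean, c.age_sd, n), *c.age_bounds)
    brain_mean = rng.normal(c.brain_mean_mu, c.brain_mean_sd, n)
    brain_range = np.clip(rng.normal(c.brain_range_mu, c.brain_range_sd, n), 0.1, None)
    rhythm = rng.uniform(size=n) < c.p_rhythm
    female = rng.uniform(size=n) < c.p_female

    beta = {
        "intercept": float(logit(c.baseline_death_rate)),
        "age": float(np.log(c.or_age_per_yr)),
        "sex_female": float(np.log(c.or_female)),
        "brain_mean_c": float(np.log(c.or_mean_per_c)),
        "brain_range_c": float(np.log(c.or_range_per_c)),
        "daily_rhythm": float(np.log(c.or_rhythm)),
    }
    lp = (
        beta["intercept"]
        + beta["age"] * (age - c.age_mean)
        + beta["sex_female"] * female
        + beta["brain_mean_c"] * (brain_mean - c.brain_mean_mu)
        + beta["brain_range_c"] * (brain_range - c.brain_range_mu)
        + beta["daily_rhythm"] * rhythm
    )
    p = expit(lp)
    if np.any(p <= 0) or np.any(p >= 1):
        import warnings as _w
        _w.warn("death probabilities clipped to (0, 1)")
        p = np.clip(p, 1e-9, 1 - 1e-9)
    died = (rng.uniform(size=n) < p).astype(int)

    df = pd.DataFrame(
        {"subject_id": [f"P{i + 1:04d}" for i in range(n)],
         "age": age, "sex": np.where(female, "female", "male"),
         "brain_mean_c": brain_mean, "brain_range_c": brain_range,
         "daily_rhythm": rhythm.astype(int), "died": died}
    )
    truth = {"beta": beta, "centering": {"age": c.age_mean,
             "brain_mean_c": c.brain_mean_mu, "brain_range_c": c.brain_range_mu},
             "death_rate": float(died.mean())}
    return df, truth
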