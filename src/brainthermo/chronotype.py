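"""Actigraphy-derived sleep metrics and chronotype quantities.

Chronotype — an individual's circadian phase preference — is operationalized
as MSF_sc, the sleep-corrected midpoint of sleep on free (non-work) days:
mean free-day sleep onset plus half of the average weekly sleep duration.
Companion quantities follow the same convention: MSW_sc (work days), PCSM
(the night before an intervention), and sleep-corrected social jetlag SJL_sc.
Event clock times are normalized to circadian phase as the proportion of a
linearized unit circle where 0 = MSF_sc and 1 = 24 h, so that downstream
models compare subjects at equivalent internal times rather than equal wall
clock times.

All clock arithmetic is modulo 24 h; averages of clock times use the
circular mean so that onsets straddling midnight are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SleepEpisode",
    "ChronotypeProfile",
    "SleepDetectionParams",
    "detect_sleep_windows",
    "sleep_metrics",
    "msf_sc",
    "msw_sc",
    "sjl_sc",
    "pcsm",
    "normalize_time",
    "build_profile",
    "circular_mean_hours",
]


@dataclass
class SleepEpisode:
    """One scored night of sleep, all clock fields in decimal hours [0, 24)."""

    date: object
    bed_time: float
    onset_latency_min: float
    sleep_onset: float
    sleep_offset: float
    wake_bouts: list[tuple[float, float]] = field(default_factory=list)
    day_type: str = "free"  # free | scheduled

    def __post_init__(self):
        expected = (self.bed_time + self.onset_latency_min / 60.0) % 24.0
        if abs((expected - self.sleep_onset) % 24.0) > 1e-6 and abs(
            (self.sleep_onset - expected) % 24.0
        ) > 1e-6:
            raise ValueError("sleep_onset must equal bed_time + latency (mod 24)")

    @property
    def sleep_duration_min(self) -> float:
        """Minutes from sleep onset to offset (mod-24 aware)."""
        return ((self.sleep_offset - self.sleep_onset) % 24.0) * 60.0

    @property
    def waso_min(self) -> float:
        """Wake after sleep onset: summed wake-bout minutes inside the episode."""
        return sum(((e - s) % 24.0) * 60.0 for s, e in self.wake_bouts)

    @property
    def total_sleep_time_min(self) -> float:
        return self.sleep_duration_min - self.waso_min

    @property
    def time_in_bed_min(self) -> float:
        return ((self.sleep_offset - self.bed_time) % 24.0) * 60.0


@dataclass
class ChronotypeProfile:
    msf_sc: float | None
    msw_sc: float | None
    pcsm: float | None
    sjl_sc_min: float | None
    sleep_duration_min: float
    total_sleep_time_min: float
    waso_min: float
    sleep_efficiency_pct: float


def circular_mean_hours(hours) -> float:
    """Circular mean of clock times (hours), result in [0, 24)."""
    h = np.asarray(hours, dtype=float)
    ang = h * 2 * np.pi / 24.0
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * 24.0 / (2 * np.pi)) % 24.0)


# ---------------------------------------------------------------------------
# Sleep-window detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SleepDetectionParams:
    """Transparent threshold-based sleep scorer.

    rest_threshold: activity (counts/epoch, after rolling-median smoothing)
    below which an epoch counts as rest; immobility onset/offset require
    ``onset_run_min`` consecutive rest minutes; within-episode activity runs
    of at least ``min_bout_min`` count as wake bouts without splitting the
    episode unless they exceed ``max_bout_min``.
    """

    rest_threshold: float = 10.0
    smooth_min: int = 11
    onset_run_min: int = 10
    min_bout_min: int = 5
    max_bout_min: int = 90
    min_episode_h: float = 3.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(idx[::2], idx[1::2]))


def detect_sleep_windows(
    epochs: pd.DataFrame, params: SleepDetectionParams | None = None
) -> list[SleepEpisode]:
    """Score sleep episodes from an epoch-level actigraphy table.

    ``epochs`` needs columns ``timestamp`` (datetime-like, time-ordered,
    uniform spacing), ``activity`` and optionally ``day_type``.  Returns
    non-overlapping episodes of at least ``min_episode_h`` hours.
    """
    params = params or SleepDetectionParams()
    ts = pd.to_datetime(epochs["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("actigraphy timestamps must be time-ordered")
    activity = epochs["activity"].to_numpy(float)
    epoch_min = (ts.iloc[1] - ts.iloc[0]).total_seconds() / 60.0 if len(ts) > 1 else 1.0

    smooth_n = max(1, int(round(params.smooth_min / epoch_min)))
    smoothed = (
        pd.Series(activity).rolling(smooth_n, center=True, min_periods=1).median().to_numpy()
    )
    rest = smoothed < params.rest_threshold

    min_len = int(round(params.min_episode_h * 60 / epoch_min))
    onset_run = max(1, int(round(params.onset_run_min / epoch_min)))
    max_gap = int(round(params.max_bout_min / epoch_min))

    # merge rest runs separated by short wake gaps
    runs = _runs(rest)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    raw_rest = activity < params.rest_threshold
    episodes: list[SleepEpisode] = []
    for s, e in merged:
        if e - s < min_len:
            continue
        # boundaries refined on raw activity: smoothing finds the block,
        # the first/last sustained raw-immobility run fixes onset/offset
        seg_raw = raw_rest[s:e]
        onset_idx, offset_idx = s, e
        sustained = [(rs, re_) for rs, re_ in _runs(seg_raw) if re_ - rs >= onset_run]
        if sustained:
            onset_idx = s + sustained[0][0]
            offset_idx = s + sustained[-1][1]
        t_bed = ts.iloc[s]
        t_on = ts.iloc[onset_idx]
        t_off = ts.iloc[min(offset_idx, len(ts) - 1)]
        clock = lambda t: (t.hour + t.minute / 60.0 + t.second / 3600.0) % 24.0
        bouts = []
        min_bout = max(1, int(round(params.min_bout_min / epoch_min)))
        for ws, we in _runs(~raw_rest[onset_idx:offset_idx]):
            if we - ws >= min_bout:
                bouts.append(
                    (clock(ts.iloc[onset_idx + ws]), clock(ts.iloc[min(onset_idx + we, len(ts) - 1)]))
                )
        day_type = "free"
        if "day_type" in epochs.columns:
            day_type = str(epochs["day_type"].iloc[onset_idx])
        episodes.append(
            SleepEpisode(
                date=t_bed.date(),
                bed_time=clock(t_bed),
                onset_latency_min=(t_on - t_bed).total_seconds() / 60.0,
                sleep_onset=clock(t_on),
                sleep_offset=clock(t_off),
                wake_bouts=bouts,
                day_type=day_type,
            )
        )
    return episodes


# ---------------------------------------------------------------------------
# Sleep metrics and chronotype formulas
# ---------------------------------------------------------------------------

def sleep_metrics(episodes: list[SleepEpisode]) -> pd.DataFrame:
    """Per-night sleep metrics.

    sleep_duration = offset - onset; WASO = summed wake-bout minutes;
    total_sleep_time = duration - WASO; efficiency = time asleep / time in
    bed x 100.
    """
    if not episodes:
        raise ValueError("at least one sleep episode required")
    rows = []
    for ep in episodes:
        dur = ep.sleep_duration_min
        if dur <= 0:
            raise ValueError("sleep offset precedes onset after mod-24 correction")
        tib = ep.time_in_bed_min
        tst = ep.total_sleep_time_min
        rows.append(
            {
                "date": ep.date,
                "day_type": ep.day_type,
                "bed_time": ep.bed_time,
                "sleep_onset": ep.sleep_onset,
                "sleep_offset": ep.sleep_offset,
                "sleep_duration_min": dur,
                "waso_min": ep.waso_min,
                "total_sleep_time_min": tst,
                "time_in_bed_min": tib,
                "sleep_efficiency_pct": 100.0 * tst / tib if tib > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _mean_weekly_duration_min(episodes: list[SleepEpisode]) -> float:
    return float(np.mean([ep.sleep_duration_min for ep in episodes]))


def msf_sc(episodes: list[SleepEpisode]) -> float | None:
    """Sleep-corrected midpoint of sleep on free days (clock hours).

    Mean free-day sleep onset plus half the average weekly (all-day) sleep
    duration, mod 24.  None when no free days are present.
    """
    free = [ep for ep in episodes if ep.day_type == "free"]
    if not free:
        return None
    onset = circular_mean_hours([ep.sleep_onset for ep in free])
    half = _mean_weekly_duration_min(episodes) / 60.0 / 2.0
    return (onset + half) % 24.0


def msw_sc(episodes: list[SleepEpisode]) -> float | None:
    """Sleep-corrected midpoint of sleep on work (scheduled) days."""
    work = [ep for ep in episodes if ep.day_type == "scheduled"]
    if not work:
        return None
    onset = circular_mean_hours([ep.sleep_onset for ep in work])
    half = _mean_weekly_duration_min(episodes) / 60.0 / 2.0
    return (onset + half) % 24.0


def _circ_diff_hours(a: float, b: float) -> float:
    """Signed shortest circular difference a - b in hours, in (-12, 12]."""
    d = (a - b) % 24.0
    return d - 24.0 if d > 12.0 else d


def sjl_sc(episodes: list[SleepEpisode]) -> float | None:
    """Sleep-corrected social jetlag (minutes, non-negative).

    When average sleep duration is longer on free days than work days,
    SJL_sc is |MSF_sc - MSW_sc|, equal to the absolute difference between
    free- and work-day sleep onsets; when work-day sleep is longer, it is
    the absolute difference between free- and work-day sleep offsets.
    Requires at least one day of each type.
    """
    free = [ep for ep in episodes if ep.day_type == "free"]
    work = [ep for ep in episodes if ep.day_type == "scheduled"]
    if not free or not work:
        return None
    dur_free = float(np.mean([ep.sleep_duration_min for ep in free]))
    dur_work = float(np.mean([ep.sleep_duration_min for ep in work]))
    if dur_free >= dur_work:
        a = circular_mean_hours([ep.sleep_onset for ep in free])
        b = circular_mean_hours([ep.sleep_onset for ep in work])
    else:
        a = circular_mean_hours([ep.sleep_offset for ep in free])
        b = circular_mean_hours([ep.sleep_offset for ep in work])
    return abs(_circ_diff_hours(a, b)) * 60.0


def pcsm(last_night: SleepEpisode) -> float:
    """Previous corrected sleep midpoint: onset + total sleep time / 2 of the
    single night before the measurement, clock hours."""
    return (last_night.sleep_onset + last_night.total_sleep_time_min / 60.0 / 2.0) % 24.0


def normalize_time(event_clock_time: float, msf: float) -> float:
    """Chronotype-normalized time: proportion of a linearized unit circle
    where 0 = MSF_sc and 1 = 24 h."""
    if not (0.0 <= event_clock_time < 24.0 and 0.0 <= msf < 24.0):
        raise ValueError("clock times must lie in [0, 24)")
    p = ((event_clock_time - msf) % 24.0) / 24.0
    return p if p < 1.0 else 0.0  # guard float round-up at the wrap point


def build_profile(episodes: list[SleepEpisode]) -> ChronotypeProfile:
    """Assemble a per-subject chronotype profile from scored nights."""
    metrics = sleep_metrics(episodes)
    return ChronotypeProfile(
        msf_sc=msf_sc(episodes),
        msw_sc=msw_sc(episodes),
        pcsm=pcsm(episodes[-1]),
        sjl_sc_min=sjl_sc(episodes),
        sleep_duration_min=float(metrics["sleep_duration_min"].mean()),
        total_sleep_time_min=float(metrics["total_sleep_time_min"].mean()),
        waso_min=float(metrics["waso_min"].mean()),
        sleep_efficiency_pct=float(metrics["sleep_efficiency_pct"].mean()),
    )
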