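"""24 h sinusoidal brain-temperature maps from sparse time-point means.

Given per-group, per-voxel mean temperatures at three clock times, a fixed
24 h sinusoid M + a*cos(2*pi*t/24) + b*sin(2*pi*t/24) is fitted by least
squares to the three means duplicated across two cycles (six points).  With
three free parameters and three distinct times the fit interpolates the
means exactly, yielding a continuous diurnal temperature curve per voxel.
Assembling all voxels gives an hourly brain-temperature map; the hourly
export is rounded to 0.1 degC, full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermometry import VoxelLayout

__all__ = [
    "TimepointMeans",
    "SinusoidFit",
    "HeatwaveMap",
    "extrapolate_sinusoid",
    "build_map",
    "predicted_minimum",
]

PERIOD_H = 24.0


@dataclass(frozen=True)
class TimepointMeans:
    """Three (clock hour, mean temperature) pairs for one (group, voxel) cell."""

    group: str
    voxel_id: int
    times: tuple[float, float, float]
    temps: tuple[float, float, float]

    def __post_init__(self):
        t = np.asarray(self.times, float) % PERIOD_H
        if np.unique(np.round(t, 9)).size != 3:
            raise ValueError("the three time points must be distinct mod 24 h")
        if not np.all(np.isfinite(self.temps)):
            raise ValueError("non-finite mean temperature")


@dataclass(frozen=True)
class SinusoidFit:
    mesor: float
    amplitude: float
    acrophase: float  # clock hour of the fitted peak, in [0, 24)

    def curve(self, hours) -> np.ndarray:
        h = np.asarray(hours, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (h - self.acrophase) / PERIOD_H
        )


@dataclass
class HeatwaveMap:
    fits: dict[tuple[str, int], SinusoidFit] = field(default_factory=dict)
    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    def hourly_frame(self, *, round_export: bool = True) -> pd.DataFrame:
        """Hourly grid (group, voxel_id, hour 0..23, temperature)."""
        hours = np.arange(24)
        rows = []
        for (group, vid), fit in sorted(self.fits.items()):
            temps = fit.curve(hours)
            if round_export:
                temps = np.round(temps, 1)
            for h, temp in zip(hours, temps):
                rows.append({"group": group, "voxel_id": vid, "hour": int(h),
                             "temperature_c": float(temp)})
        return pd.DataFrame(rows)

    def fit_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "voxel_id": v, "mesor": f.mesor,
             "amplitude": f.amplitude, "acrophase_h": f.acrophase}
            for (g, v), f in sorted(self.fits.items())
        ]
        return pd.DataFrame(rows)


def extrapolate_sinusoid(tp: TimepointMeans) -> SinusoidFit:
    """Fit the fixed-period 24 h sinusoid through three time-point means.

    The three points are duplicated one cycle later (six points) before the
    least-squares fit — which leaves the solution unchanged — and the fit
    interpolates all three means exactly.  A warning-grade conditioning note
    is attached when the times span under 1 h.
    """
    t = np.asarray(tp.times, float)
    y = np.asarray(tp.temps, float)
    t6 = np.concatenate([t, t + PERIOD_H])
    y6 = np.concatenate([y, y])
    w = 2 * np.pi / PERIOD_H
    X = np.column_stack([np.ones_like(t6), np.cos(w * t6), np.sin(w * t6)])
    beta, *_ = np.linalg.lstsq(X, y6, rcond=None)
    mesor, a, b = beta
    amplitude = float(np.hypot(a, b))
    acrophase = float((np.arctan2(b, a) / w) % PERIOD_H)
    return SinusoidFit(mesor=float(mesor), amplitude=amplitude, acrophase=acrophase)


def build_map(
    means: pd.DataFrame, layout: VoxelLayout | None = None
) -> HeatwaveMap:
    """Assemble a map from a means table (group, voxel_id,
    session_clock_time, mean_temp_c); cells without exactly three time
    points are skipped with a report entry."""
    layout = layout or VoxelLayout()
    hw = HeatwaveMap()
    for (group, vid), cell in means.groupby(["group", "voxel_id"]):
        if len(cell) != 3:
            hw.skipped.append((str(group), int(vid), f"{len(cell)} time points (need 3)"))
            continue
        if int(vid) not in layout.region_of:
            hw.skipped.append((str(group), int(vid), "voxel not in layout"))
            continue
        tp = TimepointMeans(
            group=str(group), voxel_id=int(vid),
            times=tuple(cell["session_clock_time"].astype(float)),
            temps=tuple(cell["mean_temp_c"].astype(float)),
        )
        hw.fits[(str(group), int(vid))] = extrapolate_sinusoid(tp)
    return hw


def predicted_minimum(fit: SinusoidFit) -> tuple[float | None, float]:
    """Clock hour and value of the fitted diurnal minimum.

    minimum value = mesor - amplitude, at acrophase + 12 h (mod 24).  For a
    flat cell (zero amplitude) the time is undefined (None) and the value
    equals the mesor.
    """
    if fit.amplitude <= 1e-12:
        return None, fit.mesor
    return float((fit.acrophase + 12.0) % PERIOD_H), float(fit.mesor - fit.amplitude)
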