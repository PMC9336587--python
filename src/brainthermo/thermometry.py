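"""MRS chemical-shift thermometry.

Brain temperature is estimated from the temperature-dependent chemical-shift
difference between the water and N-acetylaspartate (NAA) resonances in a
magnetic-resonance spectrum.  The water resonance moves by about
-0.01 ppm per degree Celsius while NAA is temperature-stable, so the
NAA-minus-water difference maps linearly onto tissue temperature:

    T = 100 * (f_NAA - f_H2O + 2.665) + 37        [degC, frequencies in ppm]

This module converts frequency pairs to temperatures, applies configurable
quality-control filtering, assigns voxels of the multivoxel grid to six
brain regions (four superficial medial-to-lateral groups plus thalamus and
hypothalamus), and computes per-session spatial summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CALIBRATION_SLOPE",
    "CALIBRATION_OFFSET",
    "REFERENCE_SHIFT",
    "REGIONS",
    "VoxelLayout",
    "QCConfig",
    "shift_to_temperature",
    "assign_region",
    "qc_filter",
    "spatial_range",
    "convert_voxel_table",
]

# Calibration constants of the linear shift->temperature transform.
CALIBRATION_SLOPE = 100.0   # degC per ppm of (NAA - water + REFERENCE_SHIFT)
CALIBRATION_OFFSET = 37.0   # degC at the reference shift difference
REFERENCE_SHIFT = 2.665     # ppm water-minus-NAA difference corresponding to 37 degC

#: Region labels, superficial groups ordered medial -> lateral, then deep.
REGIONS = ("Sup1", "Sup2", "Sup3", "Sup4", "Thalamus", "Hypothalamus")

DEFAULT_SHIFT_BAND = (2.55, 2.75)  # plausible water-minus-NAA difference, ppm


class InvalidInputError(ValueError):
    """Raised for non-finite or otherwise unusable inputs."""


class InsufficientDataError(ValueError):
    """Raised when an operation needs more data than the caller supplied."""


def shift_to_temperature(
    naa_freq,
    water_freq,
    *,
    band: tuple[float, float] = DEFAULT_SHIFT_BAND,
    strict: bool = False,
):
    """Convert an NAA/water chemical-shift pair (ppm) to temperature (degC).

    Parameters
    ----------
    naa_freq, water_freq
        Scalar or array chemical shifts in ppm.  Physically water resonates
        downfield of NAA so ``water_freq > naa_freq``.
    band
        Plausibility band for the water-minus-NAA difference.  Values outside
        the band are flagged (or rejected when ``strict``).
    strict
        If True, out-of-band shift differences raise ``InvalidInputError``
        instead of being flagged.

    Returns
    -------
    temperature, flagged
        Temperature(s) in degC and a boolean out-of-band flag of matching
        shape.  Scalars in, scalars out.
    """
    naa = np.asarray(naa_freq, dtype=float)
    water = np.asarray(water_freq, dtype=float)
    if not (np.all(np.isfinite(naa)) and np.all(np.isfinite(water))):
        raise InvalidInputError("non-finite chemical shift input")
    diff = water - naa
    lo, hi = band
    flagged = (diff < lo) | (diff > hi)
    if strict and np.any(flagged):
        raise InvalidInputError(
            f"shift difference outside plausibility band [{lo}, {hi}] ppm"
        )
    temp = CALIBRATION_SLOPE * (naa - water + REFERENCE_SHIFT) + CALIBRATION_OFFSET
    if np.ndim(naa_freq) == 0 and np.ndim(water_freq) == 0:
        return float(temp), bool(flagged)
    return temp, flagged


def temperature_to_shift(temperature) -> np.ndarray | float:
    """Inverse transform: temperature (degC) -> water-minus-NAA difference (ppm)."""
    t = np.asarray(temperature, dtype=float)
    diff = REFERENCE_SHIFT - (t - CALIBRATION_OFFSET) / CALIBRATION_SLOPE
    return float(diff) if np.ndim(temperature) == 0 else diff


# ---------------------------------------------------------------------------
# Voxel layout and region assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelLayout:
    """Mapping of voxel ids to brain regions and grid coordinates.

    The default layout mirrors an 82-voxel acquisition: 80 superficial
    voxels arranged in four medial-to-lateral column groups of 20 rows each
    (Sup1..Sup4), one thalamic and one hypothalamic voxel.
    """

    n_voxels: int = 82
    region_of: dict[int, str] = field(default_factory=dict)
    grid_of: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.region_of:
            region_of: dict[int, str] = {}
            grid_of: dict[int, tuple[int, int]] = {}
            n_sup = self.n_voxels - 2
            if n_sup < 4 or n_sup % 4:
                raise ValueError("superficial voxel count must be a positive multiple of 4")
            per_col = n_sup // 4
            for vid in range(1, n_sup + 1):
                col = (vid - 1) // per_col          # 0..3, medial -> lateral
                row = (vid - 1) % per_col
                region_of[vid] = REGIONS[col]
                grid_of[vid] = (row, col)
            region_of[n_sup + 1] = "Thalamus"
            grid_of[n_sup + 1] = (per_col, 0)
            region_of[n_sup + 2] = "Hypothalamus"
            grid_of[n_sup + 2] = (per_col, 1)
            object.__setattr__(self, "region_of", region_of)
            object.__setattr__(self, "grid_of", grid_of)
        deep = [r for r in self.region_of.values() if r in ("Thalamus", "Hypothalamus")]
        if sorted(deep) != ["Hypothalamus", "Thalamus"]:
            raise ValueError("layout must contain exactly one thalamic and one hypothalamic voxel")

    @property
    def voxel_ids(self) -> list[int]:
        return sorted(self.region_of)


def assign_region(voxel_id: int, layout: VoxelLayout) -> str:
    """Region label for a voxel id under the given layout."""
    try:
        return layout.region_of[int(voxel_id)]
    except KeyError:
        raise KeyError(f"voxel_id {voxel_id} not in layout") from None


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCConfig:
    """Named QC thresholds: metric -> (lower, upper) bounds (either may be None).

    Defaults keep voxels with relative fit uncertainty (CRLB-style, percent)
    at or below 20 and linewidth inside a broad plausible band (Hz).
    """

    bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: {
            "fit_uncertainty_pct": (None, 20.0),
            "linewidth_hz": (1.0, 15.0),
        }
    )


def qc_filter(
    voxels: pd.DataFrame, qc_config: QCConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Partition a voxel table into QC passes and failures.

    ``voxels`` must carry one column per thresholded metric.  Returns
    ``(passed, excluded, exclusion_fraction)``; excluded rows gain a
    ``qc_reason`` column listing every violated bound (semicolon-joined),
    and both partitions gain a boolean ``qc_pass`` column.  The partition
    is exhaustive, disjoint and independent of row order.
    """
    qc_config = qc_config or QCConfig()
    missing = [m for m in qc_config.bounds if m not in voxels.columns]
    if missing:
        raise KeyError(f"QC thresholds reference unknown metrics: {missing}")
    n = len(voxels)
    reasons = pd.Series([""] * n, index=voxels.index, dtype=object)
    fail = pd.Series(False, index=voxels.index)
    for metric, (lo, hi) in qc_config.bounds.items():
        col = voxels[metric].astype(float)
        if lo is not None:
            bad = col < lo
            fail |= bad
            reasons[bad] += f"{metric}<{lo};"
        if hi is not None:
            bad = col > hi
            fail |= bad
            reasons[bad] += f"{metric}>{hi};"
    passed = voxels.loc[~fail].copy()
    excluded = voxels.loc[fail].copy()
    passed["qc_pass"] = True
    excluded["qc_pass"] = False
    excluded["qc_reason"] = reasons[fail].str.rstrip(";")
    fraction = len(excluded) / n if n else 0.0
    return passed, excluded, fraction


def spatial_range(session_voxels: pd.DataFrame) -> float:
    """Hottest-minus-coolest voxel temperature within one session (degC).

    Only QC-passed voxels (if a ``qc_pass`` column is present) contribute.
    """
    df = session_voxels
    if "qc_pass" in df.columns:
        df = df.loc[df["qc_pass"].astype(bool)]
    temps = df["temperature_c"].astype(float)
    if len(temps) < 2:
        raise InsufficientDataError("spatial range needs >=2 QC-passed voxels")
    return float(temps.max() - temps.min())


# ---------------------------------------------------------------------------
# Table-level conversion
# ---------------------------------------------------------------------------

def _parse_clock(value) -> float:
    """Clock time as decimal hours from ``HH:MM`` or a numeric string."""
    if isinstance(value, str) and ":" in value:
        h, m = value.split(":")[:2]
        return (int(h) + int(m) / 60.0) % 24.0
    return float(value) % 24.0


def convert_voxel_table(
    table: pd.DataFrame,
    layout: VoxelLayout | None = None,
    qc_config: QCConfig | None = None,
    *,
    strict: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Convert a raw voxel table to temperatures with region and QC annotation.

    Expects columns ``subject_id, session_clock_time, voxel_id, naa_ppm,
    water_ppm`` plus any QC metric columns named in ``qc_config``.  Returns
    the annotated table (added ``region, temperature_c, qc_pass, qc_reason``)
    and a QC report dict.
    """
    layout = layout or VoxelLayout()
    out = table.copy()
    out["session_clock_time"] = out["session_clock_time"].map(_parse_clock)
    temps, flagged = shift_to_temperature(
        out["naa_ppm"].to_numpy(float), out["water_ppm"].to_numpy(float), strict=strict
    )
    out["temperature_c"] = temps
    out["shift_out_of_band"] = flagged
    out["region"] = out["voxel_id"].map(lambda v: assign_region(v, layout))
    passed, excluded, fraction = qc_filter(out, qc_config)
    out["qc_pass"] = ~out.index.isin(excluded.index)
    out["qc_reason"] = ""
    out.loc[excluded.index, "qc_reason"] = excluded["qc_reason"]
    report = {
        "n_total": int(len(out)),
        "n_excluded": int(len(excluded)),
        "exclusion_fraction": fraction,
        "n_shift_flagged": int(np.count_nonzero(flagged)),
    }
    return out, report
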