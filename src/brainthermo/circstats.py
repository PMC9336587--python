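"""Circular statistics for timing data.

Clock times of temperature extrema and acrophases live on a 24 h circle;
the convention here is 24 h <-> 2*pi with midnight at angle 0.  Provides
the circular mean and SD, the Rayleigh test of uniformity and Watson's
two-sample U-squared test of homogeneity (permutation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleSample",
    "hours_to_angles",
    "angles_to_hours",
    "circular_mean_sd",
    "rayleigh_test",
    "watson_two_sample",
    "rose_counts",
]


@dataclass
class AngleSample:
    """Angles in radians reduced to [0, 2*pi), with optional group labels."""

    angles: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float) % (2 * np.pi)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)

    @property
    def n(self) -> int:
        return self.angles.size


def hours_to_angles(hours) -> np.ndarray:
    """Clock hours -> radians (24 h = 2*pi, midnight = 0)."""
    return (np.asarray(hours, dtype=float) % 24.0) * 2 * np.pi / 24.0


def angles_to_hours(angles) -> np.ndarray:
    return (np.asarray(angles, dtype=float) % (2 * np.pi)) * 24.0 / (2 * np.pi)


def circular_mean_sd(sample: AngleSample) -> tuple[float, float, float]:
    """Circular mean direction, mean resultant length and circular SD.

    mean = atan2(mean sin, mean cos); Rbar = resultant length / n;
    circular SD = sqrt(-2 ln Rbar) (radians).  With Rbar == 0 the mean is
    undefined (returned as nan) and the SD is infinite.
    """
    a = sample.angles
    if a.size < 1:
        raise ValueError("empty angle sample")
    c, s = np.cos(a).mean(), np.sin(a).mean()
    rbar = float(np.hypot(c, s))
    if rbar < 1e-12:
        return float("nan"), 0.0, float("inf")
    mean = float(np.arctan2(s, c) % (2 * np.pi))
    sd = float(np.sqrt(-2.0 * np.log(rbar)))
    return mean, rbar, sd


def rayleigh_test(sample: AngleSample) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Z = n * Rbar**2; p-value from the standard series approximation
    exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],
    clipped to [0, 1].
    """
    n = sample.n
    if n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    c, s = np.cos(sample.angles).mean(), np.sin(sample.angles).mean()
    rbar = float(np.hypot(c, s))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


def rbar_defined(sample: AngleSample) -> bool:
    c, s = np.cos(sample.angles).mean(), np.sin(sample.angles).mean()
    return bool(np.hypot(c, s) >= 1e-12)


def _watson_u2(a: np.ndarray, b: np.ndarray) -> float:
    """Watson two-sample U-squared from the ranked combined sample.

    U2 = n*m/N^2 * [sum(d_k^2) - (sum d_k)^2 / N] where d_k is the
    difference of the two empirical CDFs at the k-th combined order
    statistic.  Ties are handled by averaging d over tied blocks (mid-rank
    convention).
    """
    n, m = a.size, b.size
    combined = np.concatenate([a, b])
    which = np.concatenate([np.zeros(n, dtype=int), np.ones(m, dtype=int)])
    order = np.argsort(combined, kind="mergesort")
    x = combined[order]
    w = which[order]
    cdf_a = np.cumsum(w == 0) / n
    cdf_b = np.cumsum(w == 1) / m
    d = cdf_a - cdf_b
    # ties: every point of a tied block takes the d reached at the block end
    if x.size > 1 and np.any(np.diff(x) == 0):
        block_end = np.r_[np.diff(x) != 0, True]
        d = d[block_end][np.cumsum(block_end) - np.where(block_end, 1, 0)]
    N = n + m
    return float(n * m / N**2 * ((d**2).sum() - d.sum() ** 2 / N))


# classical two-sample U2 critical values (alpha: critical value), for the
# bracket report alongside the permutation p-value
_U2_CRITICAL = {0.10: 0.152, 0.05: 0.187, 0.01: 0.268}


def watson_two_sample(
    a: AngleSample,
    b: AngleSample,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> dict:
    """Watson's two-sample U-squared test of homogeneity.

    The p-value is obtained by permuting group labels (seeded); the
    classical critical-value bracket (e.g. "P > 0.1") is reported
    alongside.  Invariant to common rotation and to swapping the samples.
    """
    if a.n < 8 or b.n < 8:
        raise ValueError("Watson two-sample test needs n >= 8 per group")
    # canonical order (smaller sample first): U2 is symmetric, and this
    # makes the permutation p-value invariant to swapping the samples
    first, second = (a, b) if a.n <= b.n else (b, a)
    x, y = np.sort(first.angles), np.sort(second.angles)
    u2 = _watson_u2(x, y)
    rng = np.random.default_rng(seed)
    combined = np.concatenate([x, y])
    n = x.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(combined)
        if _watson_u2(np.sort(perm[:n]), np.sort(perm[n:])) >= u2 - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_permutations + 1)
    bracket = "P > 0.1"
    for alpha in sorted(_U2_CRITICAL):
        if u2 >= _U2_CRITICAL[alpha]:
            bracket = f"P < {alpha}"
            break
    return {"u2": u2, "p_value": p_perm, "critical_bracket": bracket,
            "n_permutations": n_permutations}


def rose_counts(sample: AngleSample, n_bins: int = 24) -> np.ndarray:
    """Bin counts for a rose plot (default 24 one-hour bins from midnight)."""
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(sample.angles, bins=edges)
    return counts
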