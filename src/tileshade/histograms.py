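"""Intensity histograms, smoothed CDFs, and CDF-based histogram matching.

The matching function ``hm`` maps each source intensity to the reference
intensity whose cumulative probability is closest; compensating a tile's
overlap stripe through ``hm`` makes its intensity distribution match the
neighboring tile's half of the same physical region.

The CDF carries a +1 pseudo-count per bin,

    cdf(i) = sum_{j<=i} (h(j) + 1)  /  sum_{j<N} (h(j) + 1),

which regularizes empty bins and makes every CDF strictly increasing, so the
matching is defined for all 256 levels even when the stripe only contains a
few distinct intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_LEVELS = 256  # 8-bit data throughout; parameterized for small-N oracle tests


@dataclass
class IntensityHistogram:
    """Per-level pixel counts ``h(i)`` for one channel of a pixel set."""

    counts: np.ndarray  # (n_levels,) int64
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.n_levels,):
            raise ValueError(f"counts must have shape ({self.n_levels},)")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def n(self) -> int:
        """Total pixel count."""
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.n == 0

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of intensities actually present."""
        return self.counts > 0


@dataclass
class CDF:
    """Smoothed cumulative distribution over intensity levels."""

    values: np.ndarray  # (n_levels,) float64, strictly increasing, last == 1
    degenerate: bool = False  # built from an empty histogram (pseudo-counts only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class MatchTable:
    """Intensity-transfer table ``hm(i1) -> i2`` with its source-support mask.

    ``values`` are float so that averaged/blended tables (iterative spreading)
    share the type; fresh tables from :func:`match_histograms` hold integers.
    """

    values: np.ndarray  # (n_levels,) float64 in [0, n_levels-1]
    support: np.ndarray  # (n_levels,) bool — intensities present in the source
    n_levels: int = N_LEVELS
    #: supported intensities whose matched value also falls on an intensity
    #: observed in the reference; matches landing in the pseudo-count-only
    #: region of the reference CDF (its tails beyond the data) are smoothing
    #: artifacts and are excluded from regression fits
    fit_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.support = np.asarray(self.support, dtype=bool)
        if self.fit_support is None:
            self.fit_support = self.support.copy()
        else:
            self.fit_support = np.asarray(self.fit_support, dtype=bool)

    @classmethod
    def identity(cls, n_levels: int = N_LEVELS, support: np.ndarray | None = None) -> "MatchTable":
        if support is None:
            support = np.zeros(n_levels, dtype=bool)
        return cls(np.arange(n_levels, dtype=np.float64), support, n_levels)

    def copy(self) -> "MatchTable":
        return MatchTable(self.values.copy(), self.support.copy(), self.n_levels,
                          self.fit_support.copy())


def compute_histogram(pixels: np.ndarray, channel: int = 0, n_levels: int = N_LEVELS) -> IntensityHistogram:
    """Histogram of one channel of a stripe/patch pixel block.

    ``pixels`` is (..., C) or a flat/2-D single-channel array.  An empty pixel
    set yields the all-zero histogram with ``n == 0`` (flagged via ``empty``).
    """
    arr = np.asarray(pixels)
    if arr.ndim >= 3:
        arr = arr[..., channel]
    arr = arr.reshape(-1)
    counts = np.bincount(arr.astype(np.int64), minlength=n_levels) if arr.size else np.zeros(n_levels, np.int64)
    if counts.shape[0] > n_levels:
        raise ValueError(f"pixel intensity exceeds n_levels={n_levels}")
    return IntensityHistogram(counts, n_levels)


def compute_cdf(hist: IntensityHistogram) -> CDF:
    """Smoothed CDF with one pseudo-count per bin (strictly increasing)."""
    smoothed = hist.counts + 1
    values = np.cumsum(smoothed) / smoothed.sum()
    return CDF(values, degenerate=hist.empty)


def match_histograms(source: IntensityHistogram, reference: IntensityHistogram) -> MatchTable:
    """Histogram-matching table from ``source`` to ``reference``.

    For each source level ``i1`` the matched level is the ``i2`` whose
    reference CDF value is nearest ``cdf_src(i1)`` (ties broken toward the
    smaller ``i2``).  Because both smoothed CDFs are strictly increasing the
    resulting table is monotone non-decreasing, and identical histograms map
    to the identity.
    """
    if source.n_levels != reference.n_levels:
        raise ValueError("histograms must share the same number of levels")
    c1 = compute_cdf(source).values
    c2 = compute_cdf(reference).values
    # first index with cdf2 >= cdf1[i]; compare with its left neighbor
    hi = np.searchsorted(c2, c1, side="left")
    hi = np.clip(hi, 0, source.n_levels - 1)
    lo = np.maximum(hi - 1, 0)
    pick_lo = np.abs(c1 - c2[lo]) <= np.abs(c2[hi] - c1)
    i2 = np.where(pick_lo, lo, hi)
    fit_support = source.support & reference.support[i2]
    return MatchTable(i2.astype(np.float64), source.support.copy(), source.n_levels,
                      fit_support)
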