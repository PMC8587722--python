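"""Patch subdivision of overlap stripes and per-patch histogram matching.

A single match table per stripe can only model a spatially uniform intensity
change.  Cutting the stripe into a few patches along its long axis (three by
default) and matching each patch against the co-located patch of the partner
stripe captures compensation that varies along the tile edge, while each
patch still holds enough pixels for a stable histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histograms import MatchTable, compute_histogram, match_histograms
from .mosaic_io import MosaicError, OverlapStripe

DEFAULT_N_PATCHES = 3
#: a patch whose histogram has fewer distinct intensities than this is flagged
#: low-confidence (typically background-only); regression then falls back to
#: the stripe-global table.
TAU_SUPPORT = 8


def _long_axis(side: str) -> int:
    """Axis index of the stripe's long dimension: x for top/bottom, y for left/right."""
    if side in ("top", "bottom"):
        return 1
    if side in ("left", "right"):
        return 0
    raise MosaicError(f"stripes of side {side!r} have no patch axis")


@dataclass
class PatchGrid:
    """Equal splits of a stripe along its long axis; remainder goes to the last patch."""

    side: str
    n_patches: int
    bounds: tuple[tuple[int, int], ...]  # half-open pixel ranges along the long axis

    def __len__(self) -> int:
        return self.n_patches


def split_stripe(stripe: OverlapStripe, n_patches: int = DEFAULT_N_PATCHES) -> PatchGrid:
    """Partition ``stripe`` into ``n_patches`` contiguous ranges along its long axis."""
    if n_patches < 1:
        raise MosaicError(f"n_patches must be >= 1, got {n_patches}")
    axis = _long_axis(stripe.side)
    length = stripe.pixels.shape[axis]
    if n_patches > length:
        raise MosaicError(f"cannot split a stripe of length {length} into {n_patches} patches")
    step = length // n_patches
    bounds = tuple(
        (p * step, (p + 1) * step if p < n_patches - 1 else length) for p in range(n_patches)
    )
    return PatchGrid(stripe.side, n_patches, bounds)


def patch_pixels(stripe: OverlapStripe, grid: PatchGrid, p: int) -> np.ndarray:
    lo, hi = grid.bounds[p]
    if _long_axis(stripe.side) == 1:
        return stripe.pixels[:, lo:hi]
    return stripe.pixels[lo:hi]


@dataclass
class PatchMatchSet:
    """Per-patch match tables for one directed stripe pair, plus the stripe-global table."""

    grid: PatchGrid
    tables: list[MatchTable]
    low_confidence: list[bool]
    global_table: MatchTable

    def __len__(self) -> int:
        return len(self.tables)


def match_patches(
    stripe_a: OverlapStripe,
    stripe_b: OverlapStripe,
    n_patches: int = DEFAULT_N_PATCHES,
    channel: int = 0,
    tau_support: int = TAU_SUPPORT,
) -> PatchMatchSet:
    """Match each patch of ``stripe_a`` against the co-located patch of ``stripe_b``.

    ``stripe_a`` is the source (the tile being compensated), ``stripe_b`` the
    reference.  With ``n_patches == 1`` this reduces exactly to whole-stripe
    histogram matching.
    """
    if stripe_a.pixels.shape != stripe_b.pixels.shape:
        raise MosaicError(
            f"stripe shapes differ: {stripe_a.pixels.shape} vs {stripe_b.pixels.shape}"
        )
    grid = split_stripe(stripe_a, n_patches)
    h_a = compute_histogram(stripe_a.pixels, channel)
    h_b = compute_histogram(stripe_b.pixels, channel)
    global_table = match_histograms(h_a, h_b)
    tables: list[MatchTable] = []
    low_conf: list[bool] = []
    for p in range(n_patches):
        ph_a = compute_histogram(patch_pixels(stripe_a, grid, p), channel)
        ph_b = compute_histogram(patch_pixels(stripe_b, grid, p), channel)
        tables.append(match_histograms(ph_a, ph_b))
        low_conf.append(int(ph_a.support.sum()) < tau_support)
    return PatchMatchSet(grid, tables, low_conf, global_table)
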