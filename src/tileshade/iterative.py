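"""Iterative neighborhood compensation.

A single pass of the regression method removes the disagreement along tile
borders, but an isolated dark or bright tile is only half-corrected and its
immediate neighbors are dragged toward it.  The iterative scheme repeats the
estimate-and-compensate cycle with geometrically decreasing strength
(a simulated-annealing-style schedule): each iteration

1. recomputes the per-patch match tables from the current, partially
   corrected mosaic,
2. averages the match tables over each tile's patches,
3. blends ("spreads") every patch table toward its tile's average with the
   iteration strength ``w_k``,
4. re-fits the patch regressions and applies the compensation field at
   strength ``w_k``.

Because the tables are re-estimated after every partial application, a
correction propagates one tile ring farther per iteration: the defective
tile climbs toward its neighborhood while the burden spreads over an ever
wider ring of tiles, so the fault disappears without spoiling the immediate
neighbors.  ``n_iterations=0`` reduces bit-exactly to the non-iterative
regression method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .histograms import MatchTable, N_LEVELS
from .mosaic_io import Position, TileMosaic
from .patches import DEFAULT_N_PATCHES, TAU_SUPPORT, PatchMatchSet
from .regression import DEFAULT_DEGREE
from .compensation import (
    DEFAULT_ALPHA,
    SIDES,
    compensate_tile,
    field_from_tables,
    run_regression,
    tile_patch_sets,
)

DEFAULT_N_ITERATIONS = 5
DEFAULT_W0 = 0.5
DEFAULT_DECAY = 0.5

#: keys of per-tile patch sets: a lateral side, or "z+:<side>"/"z-:<side>" for
#: the co-located stripe regions on the adjacent focal layers
LATERAL_KEYS = set(SIDES)


def geometric_schedule(n_iterations: int, w0: float = DEFAULT_W0,
                       decay: float = DEFAULT_DECAY) -> list[float]:
    """Strictly decreasing spreading strengths ``w_k = w0 * decay**k``."""
    if not (0 < decay < 1 and 0 < w0 <= 1):
        raise ValueError("schedule requires 0 < w0 <= 1 and 0 < decay < 1")
    return [w0 * decay**k for k in range(n_iterations)]


@dataclass
class IterationState:
    """Match-table state of one iteration: per (tile, channel) patch sets."""

    sets: dict[tuple[Position, int], dict[str, PatchMatchSet]]
    weights: list[float]
    k: int = 0
    z_weight: float = 1.0
    n_levels: int = N_LEVELS

    @property
    def n_iterations(self) -> int:
        return len(self.weights)


def build_state(mosaic: TileMosaic, n_patches: int = DEFAULT_N_PATCHES,
                tau_support: int = TAU_SUPPORT, weights: list[float] | None = None,
                z_neighbors: bool = False, z_weight: float = 1.0) -> IterationState:
    """Estimate all match tables of the mosaic (Steps 1-2 of the protocol)."""
    from .multifocal import z_patch_sets  # local import; multifocal builds on this module

    sets: dict[tuple[Position, int], dict[str, PatchMatchSet]] = {}
    for pos in mosaic.positions():
        for c in range(len(mosaic.channels)):
            entry = tile_patch_sets(mosaic, pos, c, n_patches, tau_support)
            if z_neighbors:
                entry.update(z_patch_sets(mosaic, pos, c, n_patches, tau_support))
            sets[(pos, c)] = entry
    return IterationState(sets, weights if weights is not None else [],
                          z_weight=z_weight)


def tile_average_match(tile_patches, weights=None, n_levels: int = N_LEVELS) -> MatchTable:
    """Support-masked (weighted) mean of a tile's patch match tables.

    Each intensity is averaged only over the patches whose source histogram
    supports it; an intensity supported nowhere maps to itself.  Accepts a
    sequence of :class:`MatchTable` or of :class:`PatchMatchSet` (flattened).
    """
    tables: list[MatchTable] = []
    w: list[float] = []
    items = list(tile_patches)
    if weights is None:
        weights = [1.0] * len(items)
    for item, wi in zip(items, weights):
        if isinstance(item, PatchMatchSet):
            tables.extend(item.tables)
            w.extend([wi] * len(item.tables))
        else:
            tables.append(item)
            w.append(wi)
    if not tables:
        raise ValueError("tile_average_match needs at least one patch table")
    n_levels = tables[0].n_levels
    num = np.zeros(n_levels)
    den = np.zeros(n_levels)
    for table, wi in zip(tables, w):
        num += wi * table.values * table.support
        den += wi * table.support
    supported = den > 0
    values = np.where(supported, num / np.where(supported, den, 1.0),
                      np.arange(n_levels, dtype=np.float64))
    return MatchTable(values, supported, n_levels)


def _tile_average(entry: dict[str, PatchMatchSet], z_weight: float) -> MatchTable:
    items: list[PatchMatchSet] = []
    weights: list[float] = []
    for key, pms in entry.items():
        items.append(pms)
        weights.append(1.0 if key in LATERAL_KEYS else z_weight)
    return tile_average_match(items, weights)


def spread_step(state: IterationState, w: float | None = None) -> IterationState:
    """Blend every patch table toward its tile's average with strength ``w``.

    ``w`` defaults to the state's schedule entry for the current iteration.
    The stripe-global fallback tables are blended alongside so that
    low-confidence patches stay consistent with the spread state.
    """
    if w is None:
        w = state.weights[state.k]
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"spreading strength must be in [0, 1], got {w}")
    for entry in state.sets.values():
        if not entry:
            continue
        avg = _tile_average(entry, state.z_weight)
        for pms in entry.values():
            for table in pms.tables + [pms.global_table]:
                table.values = (1.0 - w) * table.values + w * avg.values
    state.k += 1
    return state


def _apply_state(mosaic: TileMosaic, state: IterationState, n_patches: int,
                 degree: int, strength: float) -> TileMosaic:
    out = mosaic.copy()
    for pos in mosaic.positions():
        fields = []
        for c in range(len(mosaic.channels)):
            lateral = {k: v for k, v in state.sets[(pos, c)].items() if k in LATERAL_KEYS}
            fields.append(field_from_tables(mosaic, pos, c, lateral, "poly",
                                            n_patches, degree))
        out.tiles[pos] = compensate_tile(mosaic, fields, alpha=strength)
    return out


def run_iterative(mosaic: TileMosaic, n_iterations: int = DEFAULT_N_ITERATIONS,
                  n_patches: int = DEFAULT_N_PATCHES, degree: int = DEFAULT_DEGREE,
                  alpha: float = DEFAULT_ALPHA, w0: float = DEFAULT_W0,
                  decay: float = DEFAULT_DECAY, tau_support: int = TAU_SUPPORT,
                  z_neighbors: bool = False, z_weight: float = 1.0,
                  collect_trace: bool = False):
    """Iterative compensation of a mosaic.

    With ``n_iterations == 0`` this is exactly the one-shot regression method
    applied at strength ``alpha``.  Otherwise iteration ``k`` (0-based)
    spreads the tables and applies the field at ``w_k = w0 * decay**k``.

    When ``collect_trace`` is true, returns ``(mosaic, trace)`` where trace
    holds the heterogeneity of the intermediate mosaic against the input
    after each iteration (``nan`` if the metric is undefined).
    """
    from .metrics import heterogeneity
    from .mosaic_io import MosaicError

    if n_iterations == 0:
        out = run_regression(mosaic, n_patches, degree, alpha, tau_support)
        return (out, []) if collect_trace else out

    weights = geometric_schedule(n_iterations, w0, decay)
    current = mosaic.copy()
    trace: list[float] = []
    for k, w in enumerate(weights):
        state = build_state(current, n_patches, tau_support, weights,
                            z_neighbors, z_weight)
        state.k = k
        spread_step(state, w)
        current = _apply_state(current, state, n_patches, degree, strength=w)
        if collect_trace:
            try:
                trace.append(heterogeneity(mosaic, current))
            except MosaicError:
                trace.append(math.nan)
    return (current, trace) if collect_trace else current
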