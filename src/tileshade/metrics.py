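"""Validation metrics: overlap error, tile heterogeneity, focal-layer error.

- ``error``: mean absolute per-pixel intensity difference between the two
  halves of every lateral overlap pair, in gray levels — how visible the
  seams are.
- ``heterogeneity``: for every adjacent tile pair, the ratio of the
  compensated to the original absolute difference of whole-tile mean
  intensities, averaged — 1.0 means the compensation left the tile-level
  brightness pattern unchanged, below 1.0 means the mosaic became more
  homogeneous.  Pairs whose original gap is exactly zero are excluded (the
  ratio is undefined) and counted separately.
- ``zerror``: mean absolute per-pixel difference between co-located tiles on
  adjacent focal layers (stacked FOVs share their full footprint), in gray
  levels.

Each metric is computed per channel and averaged uniformly over channels;
multiple mosaics ("cases") are aggregated as the mean of per-case means,
with a pooled-pairs variant available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mosaic_io import MosaicError, Position, TileMosaic, get_overlap_pair


def _as_cases(mosaics) -> list[TileMosaic]:
    if isinstance(mosaics, TileMosaic):
        return [mosaics]
    cases = list(mosaics)
    if not cases:
        raise MosaicError("need at least one mosaic")
    return cases


def _channel_indices(mosaic: TileMosaic, channel: int | None) -> list[int]:
    if channel is None:
        return list(range(len(mosaic.channels)))
    return [channel]


def pair_error(mosaic: TileMosaic, a: Position, b: Position,
               channel: int | None = None) -> float:
    """Mean absolute intensity difference over the overlap of adjacent tiles."""
    sa, sb = get_overlap_pair(mosaic, a, b)
    diff = np.abs(sa.pixels.astype(np.int16) - sb.pixels.astype(np.int16))
    chans = _channel_indices(mosaic, channel)
    return float(np.mean([diff[..., c].mean() for c in chans]))


def _case_pair_errors(mosaic: TileMosaic, channel: int | None) -> list[float]:
    return [pair_error(mosaic, a, b, channel) for a, b in mosaic.iter_lateral_pairs()]


def mosaic_error(mosaics, channel: int | None = None, pooled: bool = False) -> float:
    """Seam error aggregated over pairs and cases (mean of per-case means)."""
    cases = _as_cases(mosaics)
    per_case, pool = [], []
    for m in cases:
        errs = _case_pair_errors(m, channel)
        if not errs:
            raise MosaicError("mosaic has no lateral overlap pairs")
        per_case.append(float(np.mean(errs)))
        pool.extend(errs)
    return float(np.mean(pool)) if pooled else float(np.mean(per_case))


def _tile_means(mosaic: TileMosaic, channel: int) -> dict[Position, float]:
    return {p: float(t.pixels[..., channel].mean()) for p, t in mosaic.tiles.items()}


def _case_het_ratios(original: TileMosaic, compensated: TileMosaic,
                     channel: int | None) -> tuple[list[float], int]:
    if original.shape != compensated.shape or set(original.tiles) != set(compensated.tiles):
        raise MosaicError("original and compensated mosaics must share geometry")
    ratios: list[float] = []
    n_degenerate = 0
    for c in _channel_indices(original, channel):
        means_o = _tile_means(original, c)
        means_c = _tile_means(compensated, c)
        for a, b in original.iter_lateral_pairs():
            diff_o = abs(means_o[a] - means_o[b])
            if diff_o == 0.0:
                n_degenerate += 1
                continue
            ratios.append(abs(means_c[a] - means_c[b]) / diff_o)
    return ratios, n_degenerate


def heterogeneity(original, compensated, channel: int | None = None,
                  pooled: bool = False) -> float:
    """Mean ratio of compensated to original neighboring-tile mean gaps.

    Evaluating a mosaic against itself yields exactly 1.0.  Raises if every
    pair is degenerate (original gap zero).
    """
    orig_cases = _as_cases(original)
    comp_cases = _as_cases(compensated)
    if len(orig_cases) != len(comp_cases):
        raise MosaicError("need one compensated mosaic per original")
    per_case, pool = [], []
    for o, c in zip(orig_cases, comp_cases):
        ratios, _ = _case_het_ratios(o, c, channel)
        if ratios:
            per_case.append(float(np.mean(ratios)))
            pool.extend(ratios)
    if not per_case:
        raise MosaicError("heterogeneity undefined: every pair has a zero original gap")
    return float(np.mean(pool)) if pooled else float(np.mean(per_case))


def _case_z_errors(mosaic: TileMosaic, channel: int | None) -> list[float]:
    return [pair_error(mosaic, a, b, channel) for a, b in mosaic.iter_z_pairs()]


def z_error(mosaics, channel: int | None = None, pooled: bool = False) -> float:
    """Focal-layer error aggregated over stacked pairs and cases."""
    cases = _as_cases(mosaics)
    per_case, pool = [], []
    for m in cases:
        if m.n_layers < 2:
            raise MosaicError("z_error needs at least 2 focal layers")
        errs = _case_z_errors(m, channel)
        per_case.append(float(np.mean(errs)))
        pool.extend(errs)
    return float(np.mean(pool)) if pooled else float(np.mean(per_case))


@dataclass
class MetricsReport:
    """Per-case metric values with mean/sd aggregation and tabular export."""

    error_cases: list[float]
    het_cases: list[float]
    zerr_cases: list[float] | None
    n_degenerate_pairs: int = 0
    pair_detail: pd.DataFrame | None = None
    method: str = ""

    @staticmethod
    def _agg(vals: list[float] | None) -> tuple[float | None, float | None]:
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def error_mean(self): return self._agg(self.error_cases)[0]
    @property
    def error_sd(self): return self._agg(self.error_cases)[1]
    @property
    def het_mean(self): return self._agg(self.het_cases)[0]
    @property
    def het_sd(self): return self._agg(self.het_cases)[1]
    @property
    def zerr_mean(self): return self._agg(self.zerr_cases)[0]
    @property
    def zerr_sd(self): return self._agg(self.zerr_cases)[1]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "error_mean": self.error_mean, "error_sd": self.error_sd,
            "het_mean": self.het_mean, "het_sd": self.het_sd,
            "zerr_mean": self.zerr_mean, "zerr_sd": self.zerr_sd,
            "n_degenerate_pairs": self.n_degenerate_pairs,
        }

    def to_frame(self) -> pd.DataFrame:
        cols = ["method", "error_mean", "error_sd", "het_mean", "het_sd",
                "zerr_mean", "zerr_sd"]
        d = self.to_dict()
        return pd.DataFrame([{k: d[k] for k in cols}])


def evaluate(original, compensated, channel: int | None = None,
             method: str = "") -> MetricsReport:
    """Full three-metric report of compensated mosaics against the originals."""
    orig_cases = _as_cases(original)
    comp_cases = _as_cases(compensated)
    if len(orig_cases) != len(comp_cases):
        raise MosaicError("need one compensated mosaic per original")
    error_cases, het_cases, zerr_cases = [], [], []
    rows = []
    n_degenerate = 0
    has_z = all(m.n_layers >= 2 for m in comp_cases)
    for idx, (o, c) in enumerate(zip(orig_cases, comp_cases)):
        errs = _case_pair_errors(c, channel)
        if not errs:
            raise MosaicError("mosaic has no lateral overlap pairs")
        error_cases.append(float(np.mean(errs)))
        for (a, b), e in zip(c.iter_lateral_pairs(), errs):
            rows.append({"case": idx, "kind": "lateral", "a": a, "b": b, "error": e})
        ratios, n_deg = _case_het_ratios(o, c, channel)
        n_degenerate += n_deg
        if ratios:
            het_cases.append(float(np.mean(ratios)))
        if has_z:
            zerrs = _case_z_errors(c, channel)
            zerr_cases.append(float(np.mean(zerrs)))
            for (a, b), e in zip(c.iter_z_pairs(), zerrs):
                rows.append({"case": idx, "kind": "z", "a": a, "b": b, "error": e})
    if not het_cases:
        raise MosaicError("heterogeneity undefined: every pair has a zero original gap")
    return MetricsReport(error_cases, het_cases, zerr_cases if has_z else None,
                         n_degenerate, pd.DataFrame(rows), method)
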