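"""Per-tile compensation fields: interpolate patch transfers and apply them.

Each tile owns one intensity-transfer model per patch on each of its four
overlap stripes (top/bottom/left/right; sides without a neighbor fall back to
the identity).  The compensated value of a pixel blends those transfers
smoothly:

- along a stripe, neighboring patch models are linearly interpolated;
- the top and bottom stripe values are blended by the pixel's vertical
  position (``comp_h``), left and right by its horizontal position
  (``comp_v``);
- ``comp_h`` and ``comp_v`` are combined with a weight that favors the
  horizontal blend near the top/bottom edges and the vertical blend near the
  left/right edges (0.5 in the center);
- finally the compensated intensity is averaged with the source at strength
  ``alpha`` (default 0.5, a half-strength application that limits the damage
  of any single bad transfer), rounded half-away-from-zero and clamped to
  [0, 255].

If every transfer is the identity the whole pipeline is a bit-exact no-op.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .histograms import MatchTable, N_LEVELS
from .mosaic_io import MosaicError, Position, Tile, TileMosaic, get_overlap_pair
from .patches import DEFAULT_N_PATCHES, TAU_SUPPORT, PatchMatchSet, match_patches
from .regression import DEFAULT_DEGREE, RegressionModel, fit_patch_regression

SIDES = ("top", "bottom", "left", "right")

#: an intensity-transfer model: maps (array of) intensities to float intensities
TransferModel = Callable[[np.ndarray], np.ndarray]

DEFAULT_ALPHA = 0.5


@dataclass
class TableTransfer:
    """Raw match-table lookup used by the histogram and patch methods."""

    table: MatchTable

    def __call__(self, i: np.ndarray | float) -> np.ndarray | float:
        levels = np.arange(self.table.n_levels)
        return np.interp(np.asarray(i, dtype=np.float64), levels, self.table.values)


@dataclass
class CompensationField:
    """All per-patch transfers of one tile/channel, ready for evaluation."""

    owner: Position
    channel: int
    sides: dict[str, list[TransferModel]]  # keys: top, bottom, left, right
    tile_width: int
    tile_height: int
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        counts = {len(v) for v in self.sides.values()}
        if set(self.sides) != set(SIDES):
            raise MosaicError(f"field must define all of {SIDES}")
        if len(counts) != 1:
            raise MosaicError("every side must carry the same number of patch models")
        self.n_patches = counts.pop()

    # vectorized per-side lookup table: value of the interpolated patch
    # transfer at every (coordinate along the stripe axis, intensity)
    def side_lut(self, side: str) -> np.ndarray:
        models = self.sides[side]
        axis_len = self.tile_width if side in ("top", "bottom") else self.tile_height
        levels = np.arange(self.n_levels, dtype=np.float64)
        vals = np.stack([np.asarray(m(levels), dtype=np.float64) for m in models])
        pos = np.arange(axis_len) * len(models) / axis_len
        p = np.floor(pos).astype(int)
        t = pos - p
        pn = np.minimum(p + 1, len(models) - 1)
        return (1.0 - t)[:, None] * vals[p] + t[:, None] * vals[pn]


def lerp(a, b, t):
    """Linear interpolation ``a*(1-t) + b*t``."""
    return a * (1.0 - t) + b * t


def interp_patches(models: Sequence[TransferModel], coord: float, i, axis_len: int):
    """Piecewise-linear blend of consecutive patch transfers along a stripe.

    ``p = floor(coord*N/axis_len)``, ``t`` its fractional part; the far-edge
    neighbor index ``p+1`` clamps to the last patch.
    """
    if not 0 <= coord < axis_len:
        raise MosaicError(f"coord {coord} outside [0, {axis_len})")
    n = len(models)
    pos = coord * n / axis_len
    p = int(np.floor(pos))
    t = pos - p
    pn = min(p + 1, n - 1)
    return lerp(models[p](i), models[pn](i), t)


def comp_h(field: CompensationField, x: float, y: float, i):
    """Horizontal compensation: top/bottom stripe transfers blended by y/H."""
    top = interp_patches(field.sides["top"], x, i, field.tile_width)
    bottom = interp_patches(field.sides["bottom"], x, i, field.tile_width)
    return lerp(top, bottom, y / field.tile_height)


def comp_v(field: CompensationField, x: float, y: float, i):
    """Vertical compensation: left/right stripe transfers blended by x/W."""
    left = interp_patches(field.sides["left"], y, i, field.tile_height)
    right = interp_patches(field.sides["right"], y, i, field.tile_height)
    return lerp(left, right, x / field.tile_width)


def blend_weight(x: float, y: float, W: int, H: int) -> float:
    """Weight of the vertical term in the final blend.

    0 on the top/bottom edges (pure ``comp_h``), 1 on the left/right edges
    (pure ``comp_v``), 0.5 at the center and wherever the two edge distances
    tie; continuous except at the exact corners, which are pinned to 0.5.
    """
    a = 0.5 - abs(0.5 - x / W)  # distance measure to the nearest left/right edge
    b = 0.5 - abs(0.5 - y / H)  # ... to the nearest top/bottom edge
    if a + b == 0:
        return 0.5
    return b / (a + b)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def compensate_pixel(field: CompensationField, x: int, y: int, i: int,
                     alpha: float = DEFAULT_ALPHA) -> int:
    """Compensated 8-bit value of one pixel (scalar reference path)."""
    w = blend_weight(x, y, field.tile_width, field.tile_height)
    comp = lerp(comp_h(field, x, y, i), comp_v(field, x, y, i), w)
    out = alpha * comp + (1.0 - alpha) * i
    return int(np.clip(_round_half_away(np.asarray(out)), 0, field.n_levels - 1))


def _weight_grid(W: int, H: int) -> np.ndarray:
    a = 0.5 - np.abs(0.5 - np.arange(W) / W)
    b = 0.5 - np.abs(0.5 - np.arange(H) / H)
    denom = a[None, :] + b[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, b[:, None] / np.where(denom > 0, denom, 1.0), 0.5)
    return w


def apply_field(field: CompensationField, channel_pixels: np.ndarray,
                alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Vectorized application of a field to one (H, W) uint8 channel."""
    src = channel_pixels.astype(np.intp)
    H, W = src.shape
    top = field.side_lut("top")        # (W, n_levels)
    bottom = field.side_lut("bottom")
    left = field.side_lut("left")      # (H, n_levels)
    right = field.side_lut("right")
    xs = np.arange(W)[None, :]
    ys = np.arange(H)[:, None]
    tv = top[xs, src]
    bv = bottom[xs, src]
    lv = left[ys, src]
    rv = right[ys, src]
    ty = (np.arange(H) / H)[:, None]
    tx = (np.arange(W) / W)[None, :]
    c_h = lerp(tv, bv, ty)
    c_v = lerp(lv, rv, tx)
    comp = lerp(c_h, c_v, _weight_grid(W, H))
    out = alpha * comp + (1.0 - alpha) * src
    return np.clip(_round_half_away(out), 0, field.n_levels - 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# building fields from a mosaic
# ---------------------------------------------------------------------------

def _models_from_patchset(pms: PatchMatchSet, transfer: str, degree: int,
                          weighted: bool = False) -> list[TransferModel]:
    models: list[TransferModel] = []
    for p, table in enumerate(pms.tables):
        if transfer == "table":
            models.append(TableTransfer(table))
        elif transfer == "poly":
            # background-only patches carry too little information for a stable
            # fit; fall back to the stripe-global table
            use = pms.global_table if pms.low_confidence[p] else table
            models.append(fit_patch_regression(use, degree))
        else:
            raise ValueError(f"unknown transfer kind {transfer!r}")
    return models


def tile_patch_sets(mosaic: TileMosaic, pos: Position, channel: int,
                    n_patches: int = DEFAULT_N_PATCHES,
                    tau_support: int = TAU_SUPPORT) -> dict[str, PatchMatchSet]:
    """Directed per-side patch match sets of one tile (absent neighbors skipped)."""
    out: dict[str, PatchMatchSet] = {}
    for side in SIDES:
        q = mosaic.neighbor(pos, side)
        if q is None:
            continue
        sa, sb = get_overlap_pair(mosaic, pos, q)
        out[side] = match_patches(sa, sb, n_patches, channel, tau_support)
    return out


def field_from_tables(mosaic: TileMosaic, pos: Position, channel: int,
                      side_sets: Mapping[str, PatchMatchSet], transfer: str,
                      n_patches: int, degree: int = DEFAULT_DEGREE) -> CompensationField:
    sides: dict[str, list[TransferModel]] = {}
    for side in SIDES:
        if side in side_sets:
            sides[side] = _models_from_patchset(side_sets[side], transfer, degree)
        else:
            sides[side] = [RegressionModel.identity()] * n_patches
    return CompensationField(pos, channel, sides, mosaic.tile_width, mosaic.tile_height)


def build_field(mosaic: TileMosaic, pos: Position, channel: int,
                n_patches: int = DEFAULT_N_PATCHES, transfer: str = "poly",
                degree: int = DEFAULT_DEGREE,
                tau_support: int = TAU_SUPPORT) -> CompensationField:
    """Compensation field of one tile/channel straight from the mosaic."""
    side_sets = tile_patch_sets(mosaic, pos, channel, n_patches, tau_support)
    return field_from_tables(mosaic, pos, channel, side_sets, transfer, n_patches, degree)


def compensate_tile(mosaic: TileMosaic, fields: Sequence[CompensationField],
                    alpha: float = DEFAULT_ALPHA) -> Tile:
    """Apply one field per channel to the fields' owner tile."""
    if len(fields) != len(mosaic.channels):
        raise MosaicError(
            f"need one field per channel: got {len(fields)} for {len(mosaic.channels)} channels"
        )
    pos = fields[0].owner
    src = mosaic.tiles[pos].pixels
    out = np.empty_like(src)
    for c, field in enumerate(fields):
        if field.owner != pos:
            raise MosaicError("all fields must share the same owner tile")
        out[:, :, c] = apply_field(field, src[:, :, c], alpha)
    return Tile(out, pos)


def compensate_mosaic(mosaic: TileMosaic, transfer: str = "poly",
                      n_patches: int = DEFAULT_N_PATCHES, degree: int = DEFAULT_DEGREE,
                      alpha: float = DEFAULT_ALPHA,
                      tau_support: int = TAU_SUPPORT) -> TileMosaic:
    """One-shot compensation of every tile (no iteration)."""
    out = mosaic.copy()
    for pos in mosaic.positions():
        fields = [build_field(mosaic, pos, c, n_patches, transfer, degree, tau_support)
                  for c in range(len(mosaic.channels))]
        out.tiles[pos] = compensate_tile(mosaic, fields, alpha)
    return out


def run_histogram(mosaic: TileMosaic, alpha: float = DEFAULT_ALPHA) -> TileMosaic:
    """Method 1: whole-stripe histogram matching (a single global patch)."""
    return compensate_mosaic(mosaic, transfer="table", n_patches=1, alpha=alpha)


def run_patch(mosaic: TileMosaic, n_patches: int = DEFAULT_N_PATCHES,
              alpha: float = DEFAULT_ALPHA) -> TileMosaic:
    """Method 2: patch-based histogram matching (raw per-patch tables)."""
    return compensate_mosaic(mosaic, transfer="table", n_patches=n_patches, alpha=alpha)


def run_regression(mosaic: TileMosaic, n_patches: int = DEFAULT_N_PATCHES,
                   degree: int = DEFAULT_DEGREE, alpha: float = DEFAULT_ALPHA,
                   tau_support: int = TAU_SUPPORT) -> TileMosaic:
    """Method 3: per-patch polynomial regression of the match tables."""
    return compensate_mosaic(mosaic, transfer="poly", n_patches=n_patches,
                             degree=degree, alpha=alpha, tau_support=tau_support)
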