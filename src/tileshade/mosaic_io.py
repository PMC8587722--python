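"""Tile-mosaic container, manifest I/O, and overlap-stripe geometry.

A mosaic is a dense rectangular grid of 8-bit tiles (fields of view) with a
fixed overlap width per axis: adjacent tiles in x share ``overlap_h`` pixel
columns, adjacent tiles in y share ``overlap_v`` pixel rows, and tiles stacked
in z (focal layers) share their full footprint.  Pixel coordinates are
0-based, ``(x=column, y=row)``, origin top-left, ranges half-open.

On disk a mosaic is a JSON manifest naming every tile image (PNG or TIFF,
8-bit grayscale or multi-channel) plus the grid geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import imageio.v3 as iio
import numpy as np
import tifffile
from pydantic import BaseModel, Field, ValidationError

Position = tuple[int, int, int]  # (col, row, z)
Side = Literal["left", "right", "top", "bottom", "z"]

#: lateral side of the partner tile that faces back at us
OPPOSITE: dict[str, str] = {"left": "right", "right": "left", "top": "bottom", "bottom": "top"}


class MosaicError(Exception):
    """Base class for mosaic domain errors."""


class MosaicIOError(MosaicError):
    """File or manifest could not be read or written."""


class MosaicValidationError(MosaicError):
    """Mosaic contents violate an invariant (shape, bit depth, geometry)."""


@dataclass
class Tile:
    """One field of view: an (H, W, C) uint8 pixel block at a grid position."""

    pixels: np.ndarray
    position: Position

    def __post_init__(self) -> None:
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise MosaicValidationError(
                f"tile {self.position}: pixels must be (H, W, C), got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise MosaicValidationError(
                f"tile {self.position}: expected 8-bit pixels, got dtype {self.pixels.dtype}"
            )


@dataclass
class OverlapStripe:
    """A view of one tile's overlap region with a specific neighbor.

    For lateral adjacency the stripe is the band of shared columns/rows; for
    z-adjacency (same col/row, adjacent focal layer) the shared region is the
    entire tile footprint.
    """

    owner: Position
    side: Side
    pixels: np.ndarray  # view into the owner tile, (h, w, C)
    partner: Position


@dataclass
class TileMosaic:
    """The grid of FOV tiles with overlap geometry; the object all methods transform."""

    tiles: dict[Position, Tile]
    n_cols: int
    n_rows: int
    n_layers: int
    overlap_h: int
    overlap_v: int
    channels: tuple[str, ...]
    tile_width: int
    tile_height: int
    background: Literal["dark", "bright"] = "dark"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not self.tiles:
            raise MosaicValidationError("mosaic has no tiles")
        W, H, C = self.tile_width, self.tile_height, len(self.channels)
        if not (0 < self.overlap_h < W / 2):
            raise MosaicValidationError(
                f"overlap_h={self.overlap_h} must satisfy 0 < overlap_h < W/2 = {W / 2}"
            )
        if not (0 < self.overlap_v < H / 2):
            raise MosaicValidationError(
                f"overlap_v={self.overlap_v} must satisfy 0 < overlap_v < H/2 = {H / 2}"
            )
        for pos, tile in self.tiles.items():
            c, r, z = pos
            if not (0 <= c < self.n_cols and 0 <= r < self.n_rows and 0 <= z < self.n_layers):
                raise MosaicValidationError(f"tile position {pos} outside grid "
                                            f"{self.n_cols}x{self.n_rows}x{self.n_layers}")
            if tile.pixels.shape != (H, W, C):
                raise MosaicValidationError(
                    f"tile {pos}: shape {tile.pixels.shape} != expected {(H, W, C)}"
                )
            if tile.pixels.dtype != np.uint8:
                raise MosaicValidationError(f"tile {pos}: bit depth must be 8 bit per channel")

    # -- convenience --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_cols, self.n_rows, self.n_layers)

    def positions(self) -> list[Position]:
        return sorted(self.tiles)

    def copy(self) -> "TileMosaic":
        tiles = {p: Tile(t.pixels.copy(), p) for p, t in self.tiles.items()}
        return TileMosaic(tiles, self.n_cols, self.n_rows, self.n_layers,
                          self.overlap_h, self.overlap_v, self.channels,
                          self.tile_width, self.tile_height, self.background)

    def neighbor(self, pos: Position, side: str) -> Position | None:
        """Grid position adjacent to ``pos`` on ``side`` ('left'/'right'/'top'/
        'bottom'/'z-'/'z+'), or None if absent/outside the grid."""
        c, r, z = pos
        delta = {"left": (-1, 0, 0), "right": (1, 0, 0), "top": (0, -1, 0),
                 "bottom": (0, 1, 0), "z-": (0, 0, -1), "z+": (0, 0, 1)}[side]
        q = (c + delta[0], r + delta[1], z + delta[2])
        return q if q in self.tiles else None

    def iter_lateral_pairs(self) -> Iterator[tuple[Position, Position]]:
        """Each horizontally/vertically adjacent present pair once, (a, b) with a < b."""
        for pos in self.positions():
            for side in ("right", "bottom"):
                q = self.neighbor(pos, side)
                if q is not None:
                    yield pos, q

    def iter_z_pairs(self) -> Iterator[tuple[Position, Position]]:
        """Each vertically stacked (adjacent focal layer) present pair once."""
        for pos in self.positions():
            q = self.neighbor(pos, "z+")
            if q is not None:
                yield pos, q

    def stripe(self, pos: Position, side: str) -> np.ndarray:
        """View of the overlap band of tile ``pos`` on a lateral side."""
        px = self.tiles[pos].pixels
        if side == "left":
            return px[:, : self.overlap_h]
        if side == "right":
            return px[:, px.shape[1] - self.overlap_h:]
        if side == "top":
            return px[: self.overlap_v]
        if side == "bottom":
            return px[px.shape[0] - self.overlap_v:]
        raise MosaicError(f"unknown lateral side {side!r}")


def get_overlap_pair(mosaic: TileMosaic, a: Position, b: Position) -> tuple[OverlapStripe, OverlapStripe]:
    """Return ``(o_ab, o_ba)``: the co-located overlap stripes of adjacent tiles.

    ``a`` and ``b`` must be grid-adjacent horizontally, vertically, or in z.
    The two stripes always have identical shape; pixel row/column order is
    aligned so index (y, x) in one corresponds to the same physical point in
    the other.
    """
    for pos in (a, b):
        if pos not in mosaic.tiles:
            raise MosaicError(f"tile {pos} not present in mosaic")
    dc, dr, dz = (b[0] - a[0], b[1] - a[1], b[2] - a[2])
    nonzero = [d for d in (dc, dr, dz) if d != 0]
    if len(nonzero) != 1 or abs(nonzero[0]) != 1:
        raise MosaicError(f"tiles {a} and {b} are not grid-adjacent")
    if dz != 0:
        # stacked FOVs share the entire footprint
        sa = OverlapStripe(a, "z", mosaic.tiles[a].pixels, b)
        sb = OverlapStripe(b, "z", mosaic.tiles[b].pixels, a)
        return sa, sb
    if dc == 1:
        side_a, side_b = "right", "left"
    elif dc == -1:
        side_a, side_b = "left", "right"
    elif dr == 1:
        side_a, side_b = "bottom", "top"
    else:
        side_a, side_b = "top", "bottom"
    sa = OverlapStripe(a, side_a, mosaic.stripe(a, side_a), b)  # type: ignore[arg-type]
    sb = OverlapStripe(b, side_b, mosaic.stripe(b, side_b), a)  # type: ignore[arg-type]
    assert sa.pixels.shape == sb.pixels.shape
    return sa, sb


# ---------------------------------------------------------------------------
# manifest schema
# ---------------------------------------------------------------------------

class TileRecord(BaseModel):
    col: int = Field(ge=0)
    row: int = Field(ge=0)
    z: int = Field(default=0, ge=0)
    path: str


class Manifest(BaseModel):
    cols: int = Field(ge=1)
    rows: int = Field(ge=1)
    layers: int = Field(default=1, ge=1)
    overlap_h: int = Field(ge=1)
    overlap_v: int = Field(ge=1)
    channels: list[str] = Field(min_length=1)
    background: Literal["dark", "bright"] = "dark"
    tiles: list[TileRecord] = Field(min_length=1)


def _read_image(path: Path, n_channels: int) -> np.ndarray:
    if not path.exists():
        raise MosaicIOError(f"tile image does not exist: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise MosaicIOError(f"could not decode tile image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    # multi-page TIFFs may come back channel-first
    if arr.ndim == 3 and arr.shape[0] == n_channels and arr.shape[2] != n_channels:
        arr = np.moveaxis(arr, 0, 2)
    if arr.dtype != np.uint8:
        raise MosaicValidationError(
            f"tile image {path} has bit depth {arr.dtype}, expected 8 bit per channel"
        )
    if arr.shape[2] != n_channels:
        raise MosaicValidationError(
            f"tile image {path} has {arr.shape[2]} channels, manifest declares {n_channels}"
        )
    return arr


def read_mosaic(manifest_path: str | Path) -> TileMosaic:
    """Load a mosaic from a JSON manifest; see :class:`Manifest` for the schema."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MosaicIOError(f"manifest does not exist: {manifest_path}")
    try:
        raw = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise MosaicIOError(f"manifest {manifest_path} is not valid JSON: {exc}") from exc
    try:
        man = Manifest.model_validate(raw)
    except ValidationError as exc:
        raise MosaicValidationError(f"manifest {manifest_path} failed schema validation:\n{exc}") from exc

    base = manifest_path.parent
    tiles: dict[Position, Tile] = {}
    shape: tuple[int, int] | None = None
    for rec in man.tiles:
        pos = (rec.col, rec.row, rec.z)
        if pos in tiles:
            raise MosaicValidationError(f"duplicate tile record for position {pos}")
        arr = _read_image(base / rec.path, len(man.channels))
        if shape is None:
            shape = arr.shape[:2]
        elif arr.shape[:2] != shape:
            raise MosaicValidationError(
                f"tile {pos}: image shape {arr.shape[:2]} differs from first tile {shape}"
            )
        tiles[pos] = Tile(arr, pos)
    assert shape is not None
    H, W = shape
    return TileMosaic(tiles, man.cols, man.rows, man.layers, man.overlap_h,
                      man.overlap_v, tuple(man.channels), W, H, man.background)


def write_mosaic(mosaic: TileMosaic, out_dir: str | Path, image_format: str = "png") -> Path:
    """Write tiles and a manifest under ``out_dir``; returns the manifest path.

    Round-trip guarantee: ``read_mosaic(write_mosaic(m, d))`` reproduces the
    pixels bit-exactly and the full grid geometry.
    """
    if image_format not in ("png", "tif", "tiff"):
        raise MosaicIOError(f"unsupported image format {image_format!r}")
    # a multi-channel count outside {1, 3} cannot be a PNG
    if len(mosaic.channels) not in (1, 3):
        image_format = "tif"
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise MosaicIOError(f"cannot create output directory {out_dir}: {exc}") from exc
    records = []
    for pos in mosaic.positions():
        c, r, z = pos
        name = f"tile_c{c}_r{r}_z{z}.{image_format}"
        arr = mosaic.tiles[pos].pixels
        out = arr[:, :, 0] if arr.shape[2] == 1 else arr
        try:
            if image_format == "png":
                iio.imwrite(out_dir / name, out)
            else:
                tifffile.imwrite(out_dir / name, out)
        except OSError as exc:
            raise MosaicIOError(f"cannot write tile image {out_dir / name}: {exc}") from exc
        records.append({"col": c, "row": r, "z": z, "path": name})
    manifest = {
        "cols": mosaic.n_cols,
        "rows": mosaic.n_rows,
        "layers": mosaic.n_layers,
        "overlap_h": mosaic.overlap_h,
        "overlap_v": mosaic.overlap_v,
        "channels": list(mosaic.channels),
        "background": mosaic.background,
        "tiles": records,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
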