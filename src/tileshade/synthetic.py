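"""Synthetic mosaic generator with controlled illumination defects.

The clean mosaic is built by cropping overlapping windows out of one seamless
latent image, so before any distortion every overlap pair is pixel-identical
and all metrics are trivially perfect — any later disagreement is caused
only by the injected distortion, which is what lets metric changes be
attributed to the compensation methods.

Distortions emulate the defect taxonomy of area-scanner acquisitions:
per-tile multiplicative gain and additive offset jitter (stochastic
illumination), a smooth radial vignette inside each tile, an optional
per-tile gamma (exponential-like nonlinearity), per-focal-layer brightness
shifts, and explicit isolated defect tiles.  Everything is driven by one
seed; identical inputs give bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .mosaic_io import MosaicError, Position, Tile, TileMosaic

Content = Literal["blobs", "gradient", "texture", "constant"]


@dataclass
class DistortionSpec:
    """Parameters of the injected illumination defects (seed-deterministic)."""

    gain_sd: float = 0.05          # sd of per-tile multiplicative jitter around 1
    offset_sd: float = 5.0         # sd of per-tile additive jitter, gray levels
    vignette_strength: float = 0.0  # radial falloff amplitude in [0, 1]
    gamma_sd: float = 0.0          # sd of log per-tile exponent (0 = linear)
    layer_offsets: Sequence[float] | None = None  # additive shift per focal layer
    defect_tiles: Sequence[tuple[Position, float]] = ()  # isolated dark/bright FOVs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vignette_strength <= 1.0:
            raise ValueError("vignette_strength must be in [0, 1]")


def _latent(content: Content, lh: int, lw: int, background: str,
            rng: np.random.Generator, constant_level: int) -> np.ndarray:
    """One seamless latent channel in [0, 255] float."""
    if content == "constant":
        return np.full((lh, lw), float(constant_level))
    if content == "gradient":
        yy, xx = np.mgrid[0:lh, 0:lw]
        ramp = (yy + xx) / max(lh + lw - 2, 1)
        img = 30.0 + 190.0 * ramp
        return img if background == "dark" else 255.0 - img
    if content == "texture":
        # smooth broadband field spanning most of the intensity range
        noise = rng.standard_normal((lh, lw))
        smooth = ndimage.gaussian_filter(noise, sigma=6.0, mode="reflect")
        lo, hi = smooth.min(), smooth.max()
        f = (smooth - lo) / max(hi - lo, 1e-12)
        # skew toward the background level so the polarity is unambiguous
        img = 25.0 + 215.0 * f**1.6
        return img if background == "dark" else 255.0 - img
    if content == "blobs":
        # sparse bright signal on a dark floor (fluorescent-like); inverted
        # for bright-background (brightfield-like) content
        img = np.zeros((lh, lw))
        yy, xx = np.mgrid[0:lh, 0:lw]
        n_blobs = max(4, (lh * lw) // 2500)
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, lh), rng.uniform(0, lw)
            sig = rng.uniform(3.0, max(4.0, min(lh, lw) / 8))
            amp = rng.uniform(80.0, 220.0)
            img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)))
        img = np.clip(img, 0, 235) + 15.0
        img = np.clip(img, 0, 255)
        return img if background == "dark" else 255.0 - img
    raise ValueError(f"unknown content kind {content!r}")


def make_clean_mosaic(n_cols: int, n_rows: int, n_layers: int = 1,
                      tile_width: int = 128, tile_height: int = 128,
                      overlap_h: int = 16, overlap_v: int = 16,
                      content: Content = "blobs",
                      background: Literal["dark", "bright"] = "dark",
                      channels: Sequence[str] = ("gray",),
                      constant_level: int = 128,
                      seed: int = 0) -> TileMosaic:
    """Ground-truth mosaic: overlapping crops of one quantized latent image.

    All focal layers are identical crops, so lateral error, heterogeneity
    denominator structure, and z error all start from a perfectly consistent
    state.
    """
    if n_cols < 1 or n_rows < 1 or n_layers < 1:
        raise MosaicError("grid dimensions must be >= 1")
    if not (0 < overlap_h < tile_width / 2 and 0 < overlap_v < tile_height / 2):
        raise MosaicError("overlaps must satisfy 0 < overlap < tile size / 2")
    stride_x = tile_width - overlap_h
    stride_y = tile_height - overlap_v
    lw = n_cols * tile_width - (n_cols - 1) * overlap_h
    lh = n_rows * tile_height - (n_rows - 1) * overlap_v
    rng = np.random.default_rng(seed)
    latent = np.stack(
        [np.clip(np.round(_latent(content, lh, lw, background, rng, constant_level)),
                 0, 255).astype(np.uint8) for _ in channels],
        axis=2,
    )
    tiles: dict[Position, Tile] = {}
    for z in range(n_layers):
        for r in range(n_rows):
            for c in range(n_cols):
                y0, x0 = r * stride_y, c * stride_x
                crop = latent[y0:y0 + tile_height, x0:x0 + tile_width].copy()
                tiles[(c, r, z)] = Tile(crop, (c, r, z))
    return TileMosaic(tiles, n_cols, n_rows, n_layers, overlap_h, overlap_v,
                      tuple(channels), tile_width, tile_height, background)


def _vignette_field(h: int, w: int, strength: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    ry = (yy - (h - 1) / 2) / (h / 2)
    rx = (xx - (w - 1) / 2) / (w / 2)
    r2 = (rx**2 + ry**2) / 2.0  # normalized so corners reach ~1
    return 1.0 - strength * r2


def apply_distortion(mosaic: TileMosaic, spec: DistortionSpec) -> tuple[TileMosaic, dict]:
    """Corrupt a mosaic per ``spec``; returns (distorted copy, transform record).

    The record maps each tile position to its drawn ``gain``/``offset``/
    ``gamma`` and total additive shift, enabling parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    out = mosaic.copy()
    defects = {tuple(pos): off for pos, off in spec.defect_tiles}
    vignette = (_vignette_field(mosaic.tile_height, mosaic.tile_width,
                                spec.vignette_strength)
                if spec.vignette_strength > 0 else None)
    record: dict = {"spec": spec, "tiles": {}}
    for pos in mosaic.positions():
        gain = float(1.0 + rng.normal(0.0, spec.gain_sd)) if spec.gain_sd > 0 else 1.0
        offset = float(rng.normal(0.0, spec.offset_sd)) if spec.offset_sd > 0 else 0.0
        gamma = float(np.exp(rng.normal(0.0, spec.gamma_sd))) if spec.gamma_sd > 0 else 1.0
        z = pos[2]
        layer_off = float(spec.layer_offsets[z]) if spec.layer_offsets is not None else 0.0
        defect_off = float(defects.get(pos, 0.0))
        f = mosaic.tiles[pos].pixels.astype(np.float64)
        if gamma != 1.0:
            f = 255.0 * (f / 255.0) ** gamma
        f = gain * f + offset
        if vignette is not None:
            f = f * vignette[:, :, None]
        f = f + layer_off + defect_off
        out.tiles[pos] = Tile(np.clip(np.round(f), 0, 255).astype(np.uint8), pos)
        record["tiles"][pos] = {"gain": gain, "offset": offset, "gamma": gamma,
                                "layer_offset": layer_off, "defect_offset": defect_off}
    return out, record


# ---------------------------------------------------------------------------
# canonical study fixtures
# ---------------------------------------------------------------------------

def jittered_mosaic(n_cols: int = 5, n_rows: int = 5, n_layers: int = 1,
                    seed: int = 0, content: Content = "texture",
                    gain_sd: float = 0.05, offset_sd: float = 5.0,
                    layer_offsets: Sequence[float] | None = None,
                    **kwargs) -> tuple[TileMosaic, TileMosaic, dict]:
    """Clean + distorted pair under the standard per-tile jitter conditions."""
    clean = make_clean_mosaic(n_cols, n_rows, n_layers, content=content,
                              seed=seed, **kwargs)
    spec = DistortionSpec(gain_sd=gain_sd, offset_sd=offset_sd,
                          layer_offsets=layer_offsets, seed=seed + 1)
    distorted, record = apply_distortion(clean, spec)
    return clean, distorted, record


def center_defect_mosaic(n_cols: int = 5, n_rows: int = 5, defect: float = -30.0,
                         level: int = 128, seed: int = 0, **kwargs) -> tuple[TileMosaic, TileMosaic]:
    """Constant-content mosaic with one darkened (or brightened) center tile."""
    clean = make_clean_mosaic(n_cols, n_rows, 1, content="constant",
                              constant_level=level, seed=seed, **kwargs)
    spec = DistortionSpec(gain_sd=0.0, offset_sd=0.0, seed=seed,
                          defect_tiles=[((n_cols // 2, n_rows // 2, 0), defect)])
    distorted, _ = apply_distortion(clean, spec)
    return clean, distorted
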