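"""Multi-focal (Z-stack) extension of the iterative compensation.

When a slide is scanned in Z-X-Y order every focal layer of a grid position
covers the same physical footprint, so a tile's overlap stripes have exact
co-located counterparts on the layers above and below.  Matching those
regions across layers yields Z match tables; including them in the
"spreading" average of the iterative scheme pulls the layers' intensities
toward each other while the lateral tables keep the within-layer seams
closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .histograms import MatchTable
from .mosaic_io import MosaicError, OverlapStripe, Position, TileMosaic
from .patches import DEFAULT_N_PATCHES, TAU_SUPPORT, PatchMatchSet, match_patches
from .compensation import DEFAULT_ALPHA, SIDES
from .regression import DEFAULT_DEGREE
from .iterative import (
    DEFAULT_DECAY,
    DEFAULT_N_ITERATIONS,
    DEFAULT_W0,
    run_iterative,
    tile_average_match,
)


@dataclass
class ZNeighborhood:
    """All patches feeding one tile's spreading average: lateral plus Z.

    ``lateral`` maps side -> patch set against the in-layer neighbor;
    ``z`` maps "z+:<side>"/"z-:<side>" -> patch set matching the tile's own
    stripe region against the co-located region on the adjacent layer.
    """

    pos: Position
    lateral: dict[str, PatchMatchSet]
    z: dict[str, PatchMatchSet] = field(default_factory=dict)
    z_weight: float = 1.0

    @property
    def n_patches_total(self) -> int:
        return sum(len(p) for p in self.lateral.values()) + sum(len(p) for p in self.z.values())


def z_patch_sets(mosaic: TileMosaic, pos: Position, channel: int,
                 n_patches: int = DEFAULT_N_PATCHES,
                 tau_support: int = TAU_SUPPORT) -> dict[str, PatchMatchSet]:
    """Match tables of a tile's stripe regions against the adjacent focal layers.

    The acquisition is assumed Z-aligned, so the stripe band of the tile and
    the identically placed band one layer up/down image the same (x, y)
    region and can be matched exactly like a lateral stripe pair.
    """
    out: dict[str, PatchMatchSet] = {}
    for zkey in ("z-", "z+"):
        q = mosaic.neighbor(pos, zkey)
        if q is None:
            continue
        for side in SIDES:
            own = OverlapStripe(pos, side, mosaic.stripe(pos, side), q)
            other = OverlapStripe(q, side, mosaic.stripe(q, side), pos)
            out[f"{zkey}:{side}"] = match_patches(own, other, n_patches, channel, tau_support)
    return out


def z_average_match(neighborhood: ZNeighborhood) -> MatchTable:
    """Support-masked mean over lateral and Z patches of one tile.

    Z patches are weighted by ``z_weight`` (default 1.0: every patch counts
    once).  On a single-layer mosaic (no Z patches) this is exactly the plain
    per-tile average, with a warning.
    """
    if not neighborhood.z:
        warnings.warn(
            f"tile {neighborhood.pos} has no focal-layer neighbors; "
            "falling back to the plain tile average",
            stacklevel=2,
        )
        return tile_average_match(list(neighborhood.lateral.values()))
    items = list(neighborhood.lateral.values()) + list(neighborhood.z.values())
    weights = [1.0] * len(neighborhood.lateral) + [neighborhood.z_weight] * len(neighborhood.z)
    return tile_average_match(items, weights)


def run_multifocal(mosaic: TileMosaic, n_iterations: int = DEFAULT_N_ITERATIONS,
                   n_patches: int = DEFAULT_N_PATCHES, degree: int = DEFAULT_DEGREE,
                   alpha: float = DEFAULT_ALPHA, w0: float = DEFAULT_W0,
                   decay: float = DEFAULT_DECAY, tau_support: int = TAU_SUPPORT,
                   z_weight: float = 1.0, collect_trace: bool = False):
    """Iterative compensation with focal-layer neighbors in the spreading step."""
    if mosaic.n_layers < 2:
        raise MosaicError(
            "multifocal compensation needs at least 2 focal layers; "
            "use run_iterative for single-layer mosaics"
        )
    return run_iterative(mosaic, n_iterations, n_patches, degree, alpha, w0,
                         decay, tau_support, z_neighbors=True, z_weight=z_weight,
                         collect_trace=collect_trace)
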