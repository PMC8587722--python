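import numpy as np
import pytest

from tileshade.compensation import (
    CompensationField,
    blend_weight,
    comp_h,
    comp_v,
    compensate_pixel,
    compensate_tile,
    interp_patches,
    run_histogram,
    run_patch,
    run_regression,
)
from tileshade.mosaic_io import MosaicError, Tile, TileMosaic
from tileshade.regression import RegressionModel
from tileshade.synthetic import make_clean_mosaic


def shift_model(delta):
    return RegressionModel(np.array([float(delta), 1.0]), kind="poly")


def field_with(top=0, bottom=0, left=0, right=0, W=64, H=64, n=1, channel=0):
    sides = {
        "top": [shift_model(top)] * n,
        "bottom": [shift_model(bottom)] * n,
        "left": [shift_model(left)] * n,
        "right": [shift_model(right)] * n,
    }
    return CompensationField((0, 0, 0), channel, sides, W, H)


class TestInterpPatches:
    def test_single_patch_is_constant_along_axis(self):
        models = [shift_model(5)]
        assert interp_patches(models, 0, 100, 100) == 105
        assert interp_patches(models, 99, 100, 100) == 105

    def test_two_identity_models_stay_identity(self):
        models = [shift_model(0), shift_model(0)]
        for coord in (0, 25, 50, 75, 99):
            assert interp_patches(models, coord, 42, 100) == 42

    def test_two_patch_blend_and_edge_clamp(self):
        models = [shift_model(0), shift_model(10)]
        # coord=25 -> p=0, t=0.5 -> halfway between the two models
        assert interp_patches(models, 25, 100, 100) == pytest.approx(105.0)
        # coord=75 -> p=1, t=0.5, p+1 clamps to the last patch
        assert interp_patches(models, 75, 100, 100) == pytest.approx(110.0)


class TestDirectionalBlends:
    def test_comp_h_boundaries(self):
        f = field_with(top=4, bottom=8)
        assert comp_h(f, 10, 0, 100) == pytest.approx(104.0)  # top edge
        assert comp_h(f, 10, 64, 100) == pytest.approx(108.0)  # bottom limit
        assert comp_h(f, 10, 32, 100) == pytest.approx(106.0)  # midpoint

    def test_comp_v_boundaries(self):
        f = field_with(left=4, right=8)
        assert comp_v(f, 0, 10, 100) == pytest.approx(104.0)
        assert comp_v(f, 64, 10, 100) == pytest.approx(108.0)
        assert comp_v(f, 32, 10, 100) == pytest.approx(106.0)


class TestBlendWeight:
    def test_center_is_half(self):
        assert blend_weight(32, 32, 64, 64) == pytest.approx(0.5)

    def test_top_edge_prefers_horizontal(self):
        assert blend_weight(32, 0, 64, 64) == 0.0

    def test_left_edge_prefers_vertical(self):
        assert blend_weight(0, 32, 64, 64) == 1.0

    def test_corner_pinned_to_half(self):
        assert blend_weight(0, 0, 64, 64) == 0.5

    def test_continuous_in_between(self):
        w = np.array([[blend_weight(x, y, 64, 64) for x in range(64)] for y in range(64)])
        assert (w >= 0).all() and (w <= 1).all()
        interior = w[1:-1, 1:-1]
        assert np.abs(np.diff(interior, axis=0)).max() < 0.2
        assert np.abs(np.diff(interior, axis=1)).max() < 0.2


class TestCompensatePixel:
    def test_identity_field_is_noop(self):
        f = field_with()
        for x, y, i in [(0, 0, 0), (10, 20, 200), (63, 63, 255)]:
            assert compensate_pixel(f, x, y, i) == i

    def test_half_blend_of_uniform_correction(self):
        f = field_with(top=20, bottom=20, left=20, right=20)
        assert compensate_pixel(f, 30, 30, 100) == 110  # (i+20 + i)/2

    def test_no_overflow_at_255(self):
        f = field_with(top=20, bottom=20, left=20, right=20)
        assert compensate_pixel(f, 30, 30, 255) == 255

    def test_full_strength_application(self):
        f = field_with(top=20, bottom=20, left=20, right=20)
        assert compensate_pixel(f, 30, 30, 100, alpha=1.0) == 120

    def test_half_blend_contract(self):
        # |dst - src| <= max |pr(i) - i| / 2 + 1
        f = field_with(top=14, bottom=-6, left=3, right=9)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.integers(0, 64, 2)
            i = int(rng.integers(0, 256))
            assert abs(compensate_pixel(f, x, y, i) - i) <= 14 / 2 + 1


class TestCompensateTile:
    def make_mosaic(self, value=100, channels=("r", "g", "b")):
        px = np.full((64, 64, len(channels)), value, np.uint8)
        tiles = {(0, 0, 0): Tile(px, (0, 0, 0))}
        return TileMosaic(tiles, 1, 1, 1, 8, 8, channels, 64, 64)

    def test_identity_fields_leave_tile_unchanged(self):
        mosaic = self.make_mosaic()
        fields = [field_with(channel=c) for c in range(3)]
        out = compensate_tile(mosaic, fields)
        np.testing.assert_array_equal(out.pixels, mosaic.tiles[(0, 0, 0)].pixels)

    def test_uniform_correction_half_applied(self):
        mosaic = self.make_mosaic(100, channels=("gray",))
        f = field_with(top=40, bottom=40, left=40, right=40)
        out = compensate_tile(mosaic, [f])
        assert (out.pixels == 120).all()

    def test_channels_compensated_independently(self):
        mosaic = self.make_mosaic(100)
        deltas = (20, 0, -20)
        fields = [field_with(top=d, bottom=d, left=d, right=d, channel=c)
                  for c, d in enumerate(deltas)]
        out = compensate_tile(mosaic, fields)
        assert (out.pixels[..., 0] == 110).all()
        assert (out.pixels[..., 1] == 100).all()
        assert (out.pixels[..., 2] == 90).all()

    def test_channel_count_mismatch_is_domain_error(self):
        mosaic = self.make_mosaic()
        with pytest.raises(MosaicError, match="channel"):
            compensate_tile(mosaic, [field_with()])


class TestMethodRunners:
    @pytest.mark.parametrize("runner", [run_histogram, run_patch, run_regression])
    def test_clean_mosaic_is_fixed_point(self, runner, clean_3x3):
        out = runner(clean_3x3)
        for pos in clean_3x3.tiles:
            np.testing.assert_array_equal(out.tiles[pos].pixels,
                                          clean_3x3.tiles[pos].pixels)

    def test_continuity_of_compensated_surface(self):
        # smooth bounded-slope transfers must not introduce jumps between
        # adjacent pixels of a constant input
        f = field_with(top=12, bottom=-8, left=5, right=-3)
        from tileshade.compensation import apply_field
        out = apply_field(f, np.full((64, 64), 120, np.uint8)).astype(int)
        # away from the edges the surface is seam-free; within a few pixels
        # of the border the edge-distance blend weight changes faster, but
        # jumps stay within half the largest side disparity
        interior = out[4:-4, 4:-4]
        assert np.abs(np.diff(interior, axis=0)).max() <= 1
        assert np.abs(np.diff(interior, axis=1)).max() <= 1
        assert np.abs(np.diff(out, axis=0)).max() <= 10
        assert np.abs(np.diff(out, axis=1)).max() <= 10
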