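import numpy as np
import pytest

from tileshade.histograms import MatchTable
from tileshade.iterative import (
    IterationState,
    build_state,
    geometric_schedule,
    run_iterative,
    spread_step,
    tile_average_match,
)
from tileshade.metrics import heterogeneity
from tileshade.compensation import run_regression
from tileshade.synthetic import center_defect_mosaic, make_clean_mosaic


def table_shift(delta, support_lo=40, support_hi=220):
    sup = np.zeros(256, bool)
    sup[support_lo:support_hi] = True
    return MatchTable(np.arange(256, dtype=float) + delta, sup)


class TestTileAverage:
    def test_all_identity_patches_average_to_identity(self):
        avg = tile_average_match([table_shift(0), table_shift(0)])
        np.testing.assert_allclose(avg.values, np.arange(256))

    def test_arithmetic_mean_on_common_support(self):
        avg = tile_average_match([table_shift(10), table_shift(20)])
        sup = np.arange(40, 220)
        np.testing.assert_allclose(avg.values[sup], sup + 15)

    def test_support_masked_mean(self):
        # patch A supports i=50 (-> 60), patch B does not support 50
        a = MatchTable(np.arange(256, dtype=float), np.zeros(256, bool))
        a.values[50] = 60.0
        a.support[50] = True
        b = table_shift(4, 100, 200)
        avg = tile_average_match([a, b])
        assert avg.values[50] == 60.0
        assert avg.values[150] == 154.0

    def test_unsupported_everywhere_maps_to_identity(self):
        avg = tile_average_match([table_shift(9, 100, 110)])
        assert avg.values[30] == 30.0

    def test_weights_scale_contributions(self):
        avg = tile_average_match([table_shift(0), table_shift(12)], weights=[1.0, 0.5])
        assert avg.values[100] == pytest.approx(100 + 12 * 0.5 / 1.5)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            tile_average_match([])


class TestSpreadStep:
    def make_state(self, mosaic):
        return build_state(mosaic, n_patches=3)

    def test_zero_strength_is_noop(self):
        mosaic = make_clean_mosaic(2, 2, seed=1)
        state = self.make_state(mosaic)
        before = {
            k: [t.values.copy() for t in pms.tables]
            for k, entry in state.sets.items() for _, pms in entry.items()
        }
        spread_step(state, w=0.0)
        after = {
            k: [t.values for t in pms.tables]
            for k, entry in state.sets.items() for _, pms in entry.items()
        }
        for k in before:
            for x, y in zip(before[k], after[k]):
                np.testing.assert_array_equal(x, y)

    def test_full_strength_replaces_with_tile_average(self):
        mosaic = make_clean_mosaic(2, 2, seed=2)
        state = self.make_state(mosaic)
        spread_step(state, w=1.0)
        for (pos, c), entry in state.sets.items():
            tables = [t for pms in entry.values() for t in pms.tables]
            first = tables[0].values
            for t in tables[1:]:
                np.testing.assert_allclose(t.values, first)

    def test_lerp_arithmetic(self):
        # one tile, two patches at +20 and 0 -> average +10; at w=0.5 the +20
        # patch moves to +15 on the common support
        from tileshade.patches import PatchGrid, PatchMatchSet

        pms = PatchMatchSet(
            PatchGrid("right", 2, ((0, 10), (10, 20))),
            [table_shift(20), table_shift(0)],
            [False, False],
            table_shift(10),
        )
        state = IterationState({((0, 0, 0), 0): {"right": pms}}, weights=[0.5])
        spread_step(state)
        sup = np.arange(40, 220)
        np.testing.assert_allclose(pms.tables[0].values[sup], sup + 15)
        np.testing.assert_allclose(pms.tables[1].values[sup], sup + 5)
        assert state.k == 1

    def test_invalid_strength_rejected(self):
        state = IterationState({}, weights=[0.5])
        with pytest.raises(ValueError):
            spread_step(state, w=1.5)


class TestSchedule:
    def test_geometric_decay(self):
        assert geometric_schedule(3) == [0.5, 0.25, 0.125]

    def test_strictly_decreasing(self):
        w = geometric_schedule(6, w0=0.7, decay=0.6)
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            geometric_schedule(3, w0=0.0)


class TestRunIterative:
    def test_clean_mosaic_is_fixed_point(self, clean_3x3):
        out = run_iterative(clean_3x3, n_iterations=3)
        for pos in clean_3x3.tiles:
            np.testing.assert_array_equal(out.tiles[pos].pixels,
                                          clean_3x3.tiles[pos].pixels)

    def test_zero_iterations_reduces_to_regression(self):
        _, dark = center_defect_mosaic(3, 3, seed=5)
        a = run_iterative(dark, n_iterations=0)
        b = run_regression(dark)
        for pos in dark.tiles:
            np.testing.assert_array_equal(a.tiles[pos].pixels, b.tiles[pos].pixels)

    def test_center_defect_contracts_without_spoiling_neighbors(self):
        _, dark = center_defect_mosaic(5, 5)
        out = run_iterative(dark, n_iterations=5)
        center = (2, 2, 0)
        mean = lambda m, p: m.tiles[p].pixels.mean()
        center_change = abs(mean(out, center) - mean(dark, center))
        for dc, dr in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            n = (2 + dc, 2 + dr, 0)
            assert abs(mean(out, n) - mean(dark, n)) < center_change

    def test_heterogeneity_trace_non_increasing(self):
        _, dark = center_defect_mosaic(5, 5)
        out, trace = run_iterative(dark, n_iterations=5, collect_trace=True)
        assert len(trace) == 5
        assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))
        h0 = heterogeneity(dark, run_regression(dark))
        assert trace[-1] < h0
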