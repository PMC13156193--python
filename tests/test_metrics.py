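"""Configuration metrics: closed forms, undefined-value contracts, oracle parity."""

import numpy as np
import pytest

from scalescape import (
    cai_cv,
    contagion,
    delineate_patches,
    edge_density,
    metric_scan,
    pafrac,
    patch_geometry,
    proportion_uplands,
    shannon_diversity,
)
from scalescape.metrics import compute_all_metrics
from scalescape.raster import ClassTable, PatchGeometry
import pandas as pd

from conftest import make_raster
from oracles import naive_all_metrics, random_grid


class TestEdgeDensity:
    def test_uniform_grid_zero(self, uniform_raster):
        assert edge_density(uniform_raster).value == 0.0

    def test_half_split_25ha_grid_is_20_m_per_ha(self, half_split_raster):
        # one full-height boundary: 100 faces x 5 m = 500 m over 25 ha
        assert np.isclose(edge_density(half_split_raster).value, 20.0)

    def test_checkerboard_brute_force(self, checkerboard_raster):
        # every internal face separates classes: 2*100*99 faces x 5 m over 25 ha
        expected = 2 * 100 * 99 * 5 / 25.0
        assert np.isclose(edge_density(checkerboard_raster).value, expected)

    def test_recoding_a_cell_to_new_class_never_decreases(self):
        """All faces of the recoded cell become edges; none elsewhere change."""
        rng = np.random.default_rng(5)
        grid = rng.integers(1, 3, size=(30, 30)).astype(np.int32)
        base = edge_density(make_raster(grid)).value
        grid2 = grid.copy()
        grid2[12, 17] = 99  # class absent from the rest of the grid
        assert edge_density(make_raster(grid2)).value >= base - 1e-9


class TestShannonDiversity:
    def test_single_class_zero(self, uniform_raster):
        assert shannon_diversity(uniform_raster).value == 0.0

    def test_four_equal_classes_ln4(self):
        g = np.repeat(np.repeat([[1, 2], [3, 4]], 10, axis=0), 10, axis=1)
        assert np.isclose(shannon_diversity(make_raster(g)).value, np.log(4))

    def test_half_quarter_quarter(self):
        g = np.ones((20, 20))
        g[:, 10:15] = 2
        g[:, 15:] = 3  # proportions (0.5, 0.25, 0.25)
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))  # 1.0397
        assert np.isclose(shannon_diversity(make_raster(g)).value, expected)
        assert np.isclose(expected, 1.0397, atol=5e-5)

    def test_bounded_by_ln_m(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            grid = random_grid(rng)
            raster = make_raster(grid)
            m = len(raster.classes_present())
            val = shannon_diversity(raster).value
            assert 0.0 <= val <= np.log(m) + 1e-12


class TestContagion:
    def test_single_class_undefined(self, uniform_raster):
        mv = contagion(uniform_raster)
        assert not mv.defined and mv.value is None

    def test_checkerboard_interior_limit_50(self):
        # large checkerboard: boundary faces negligible; g_ii=0, P_i=0.5 -> 50%
        g = (np.indices((500, 500)).sum(axis=0) % 2) + 1
        assert abs(contagion(make_raster(g)).value - 50.0) < 0.1

    def test_aggregated_halves_exceed_random_speckle(self):
        """Aggregation raises CONTAG: a split landscape beats a random mixture
        (which has near-uniform adjacency entropy, CONTAG near 0)."""
        halves = np.ones((20, 20), dtype=int)
        halves[:, 10:] = 2
        rng = np.random.default_rng(0)
        speckle = rng.integers(1, 3, size=(20, 20))
        assert (
            contagion(make_raster(halves)).value
            > contagion(make_raster(speckle)).value
        )

    def test_two_halves_matches_naive_formula_evaluation(self):
        from oracles import naive_contag

        halves = np.ones((20, 20), dtype=np.int32)
        halves[:, 10:] = 2
        ours = contagion(make_raster(halves)).value
        np.testing.assert_allclose(ours, naive_contag(halves, -9999), rtol=1e-9)

    def test_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            raster = make_raster(random_grid(rng))
            mv = contagion(raster)
            if mv.defined:
                assert 0.0 < mv.value <= 100.0


def _square_geometry(sides_cells, cell=5.0):
    """PatchGeometry of idealised square patches with given sides (in cells)."""
    sides = np.asarray(sides_cells, dtype=float)
    area_ha = (sides * cell) ** 2 / 10_000.0
    perim_m = 4 * sides * cell
    return PatchGeometry(
        area_ha=area_ha,
        perimeter_m=perim_m,
        core_area_ha=area_ha,
        edge_depth_m=0.0,
    )


class TestPafrac:
    def test_self_similar_squares_give_one(self):
        geom = _square_geometry(np.arange(2, 14))  # 12 distinct squares
        assert np.isclose(pafrac(geom).value, 1.0)

    def test_fewer_than_ten_patches_undefined(self):
        geom = _square_geometry(np.arange(2, 11))  # 9 patches
        mv = pafrac(geom)
        assert not mv.defined
        assert "10" in mv.reason

    def test_identical_patches_undefined(self):
        geom = _square_geometry([4] * 10)
        mv = pafrac(geom)
        assert not mv.defined and "variance" in mv.reason


class TestCaiCv:
    def test_congruent_patches_zero(self):
        grid = np.full((20, 20), -9999)
        for r0, c0 in ((1, 1), (1, 8), (8, 1), (8, 8)):
            grid[r0 : r0 + 5, c0 : c0 + 5] = 1
        raster = make_raster(grid)
        geom = patch_geometry(delineate_patches(raster), edge_depth_m=5.0)
        assert cai_cv(geom).value == 0.0

    def test_two_patch_hand_computation(self):
        geom = PatchGeometry(
            area_ha=np.array([1.0, 1.0]),
            perimeter_m=np.array([400.0, 400.0]),
            core_area_ha=np.array([0.5, 1.0]),  # CAI 50 and 100
            edge_depth_m=5.0,
        )
        assert np.isclose(cai_cv(geom).value, 100.0 * 25.0 / 75.0)

    def test_all_edge_patches_undefined(self):
        geom = PatchGeometry(
            area_ha=np.array([0.01, 0.01]),
            perimeter_m=np.array([20.0, 20.0]),
            core_area_ha=np.array([0.0, 0.0]),
            edge_depth_m=5.0,
        )
        mv = cai_cv(geom)
        assert not mv.defined and mv.value is None


class TestProportionUplands:
    @staticmethod
    def _table():
        return ClassTable(
            pd.DataFrame(
                {
                    "class_code": [1, 2],
                    "vegetation": ["aspen", "fen"],
                    "age_class": ["120+", None],
                    "upland": [True, False],
                    "vegetated": [True, True],
                }
            )
        )

    def test_all_upland(self):
        assert proportion_uplands(make_raster(np.ones((5, 5))), self._table()) == 1.0

    def test_half_and_half(self):
        g = np.ones((4, 4))
        g[:2] = 2
        assert proportion_uplands(make_raster(g), self._table()) == 0.5

    def test_nodata_excluded_from_denominator(self):
        g = np.ones((4, 4))
        g[:2] = -9999
        assert proportion_uplands(make_raster(g), self._table()) == 1.0


class TestMetricScan:
    def test_single_radius_consistent_with_direct_calls(self, landscape_bundle):
        from scalescape import CircularExtent, clip_circular

        raster, table = landscape_bundle
        center = (3000.0, 3000.0)
        df = metric_scan(raster, center, [200.0], table=table)
        clipped = clip_circular(raster, CircularExtent(center, 200.0))
        direct = compute_all_metrics(clipped, table)
        for name, mv in direct.items():
            row = df[df.metric == name].iloc[0]
            if mv.defined:
                assert np.isclose(row.value, mv.value)
            else:
                assert not row.defined

    def test_row_count_is_metrics_times_radii(self, landscape_bundle):
        raster, table = landscape_bundle
        radii = [100.0, 150.0, 200.0]
        df = metric_scan(raster, (3000.0, 3000.0), radii, table=table)
        assert len(df) == 6 * len(radii)  # 5 metrics + prop_upland

    def test_pafrac_undefined_small_defined_large(self, landscape_bundle, sites40):
        """Sparse fine buffers lack the 10 patches PAFRAC needs; broad ones don't."""
        raster, table = landscape_bundle
        rows = []
        for row in sites40.head(15).itertuples(index=False):
            rows.append(
                metric_scan(raster, (row.x, row.y), [50.0, 500.0], metrics=("pafrac",))
            )
        df = pd.concat(rows)
        fine = df[df.radius_m == 50.0].defined.mean()
        broad = df[df.radius_m == 500.0].defined.mean()
        assert fine < broad
        assert broad == 1.0

    def test_empty_schedule_raises(self, uniform_raster):
        with pytest.raises(ValueError, match="empty"):
            metric_scan(uniform_raster, (50.0, 50.0), [])


class TestRelabellingInvariance:
    @pytest.mark.parametrize("seed", range(4))
    def test_metrics_invariant_under_bijective_recoding(self, seed):
        rng = np.random.default_rng(seed)
        grid = random_grid(rng)
        raster = make_raster(grid)
        codes = raster.classes_present()
        perm = {int(c): int(p) for c, p in zip(codes, rng.permutation(codes) + 100)}
        regrid = grid.copy()
        for old, new in perm.items():
            regrid[grid == old] = new
        re_raster = make_raster(regrid)
        a = compute_all_metrics(raster)
        b = compute_all_metrics(re_raster)
        for name in a:
            assert a[name].defined == b[name].defined
            if a[name].defined:
                np.testing.assert_allclose(a[name].value, b[name].value, rtol=1e-9)


class TestOracleParity:
    @pytest.mark.parametrize("seed", range(25))
    def test_all_metrics_match_naive_implementation(self, seed):
        rng = np.random.default_rng(1000 + seed)
        grid = random_grid(rng)
        raster = make_raster(grid)
        ours = compute_all_metrics(raster)
        theirs = naive_all_metrics(grid, -9999, 5.0, depth_cells=1)
        for name, expected in theirs.items():
            mv = ours[name]
            if expected is None:
                assert not mv.defined, f"{name}: expected undefined"
            else:
                assert mv.defined, f"{name}: expected {expected}, got undefined"
                np.testing.assert_allclose(mv.value, expected, rtol=1e-9)
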