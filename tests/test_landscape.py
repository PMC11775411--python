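"""Patch delineation, the six class metrics, and the median-rank classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from scatscape import landscape as L
from scatscape import synthetic as synth
from scatscape.raster import CategoricalRaster


def _raster(data, cell=30.0):
    return CategoricalRaster(np.asarray(data), cell_size=cell,
                             legend={"forest": 1})


class TestDelineation:
    def test_diagonal_touch_is_one_patch(self):
        r = _raster([[1, 0], [0, 1]])
        assert L.delineate_patches(r, 1).n_patches == 1

    def test_full_raster_single_patch_perimeter(self):
        r = _raster(np.ones((4, 6), dtype=int))
        ps = L.delineate_patches(r, 1)
        assert ps.n_patches == 1
        assert ps.table.at[1, "perimeter_m"] == pytest.approx(2 * (4 + 6) * 30)

    def test_absent_class_empty_patchset(self):
        r = _raster(np.zeros((3, 3), dtype=int))
        assert L.delineate_patches(r, 1).n_patches == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_grid_matches_flood_fill(self, seed):
        r = synth.random_raster(15, 15, n_classes=2, seed=seed)
        ps = L.delineate_patches(r, 1)
        oracle = oracles.flood_fill_patches(r.data.tolist(), 1)
        assert ps.n_patches == len(oracle)
        impl = {frozenset(map(tuple, np.argwhere(ps.labels == pid)))
                for pid in ps.table.index}
        assert impl == {frozenset(p) for p in oracle}


class TestClassMetrics:
    def test_square_patch_closed_forms(self):
        # 3x3-cell square, 30 m cells: perimeter 360 m, area 8100 m^2
        data = np.zeros((10, 10), dtype=int)
        data[2:5, 2:5] = 1
        ps = L.delineate_patches(_raster(data), 1)
        m = L.class_metrics(ps, landscape_area_ha=9.0)
        assert m["MSI"] == pytest.approx(1.0)

    def test_pd_one_patch_in_100_ha(self):
        # 100 ha = 1,000,000 m^2; a lone patch gives PD = 1 per 100 ha
        data = np.zeros((10, 10), dtype=int)
        data[4, 4] = 1
        ps = L.delineate_patches(_raster(data, cell=100.0), 1)
        m = L.class_metrics(ps, landscape_area_ha=100.0)
        assert m["PD"] == pytest.approx(1.0)

    def test_core_of_10x10_at_depth_100(self):
        data = np.zeros((14, 14), dtype=int)
        data[2:12, 2:12] = 1
        ps = L.delineate_patches(_raster(data), 1)
        assert L.core_cell_count(ps, 1, 100.0) == 16  # inner 4x4
        m = L.class_metrics(ps, landscape_area_ha=17.64)
        assert m["MCA"] == pytest.approx(1.44)

    def test_zero_depth_makes_core_equal_patch(self):
        r = synth.random_raster(12, 12, n_classes=2, seed=3)
        ps = L.delineate_patches(r, 1)
        m0 = L.class_metrics(ps, 10.0, edge_depth=0.0)
        assert m0["MCA"] == pytest.approx(m0["MPA"])

    def test_mca_never_exceeds_mpa(self):
        for seed in range(8):
            r = synth.random_raster(15, 15, n_classes=3, seed=seed)
            ps = L.delineate_patches(r, 1)
            m = L.class_metrics(ps, 20.25)
            assert m["MCA"] <= m["MPA"] + 1e-12

    def test_enn_missing_for_single_patch(self):
        data = np.zeros((6, 6), dtype=int)
        data[2:4, 2:4] = 1
        ps = L.delineate_patches(_raster(data), 1)
        assert np.isnan(L.class_metrics(ps, 3.24)["ENN"])

    def test_empty_patchset_all_missing(self):
        ps = L.delineate_patches(_raster(np.zeros((3, 3), dtype=int)), 1)
        assert L.class_metrics(ps, 1.0).isna().all()

    def test_scale_invariance_of_cell_doubling(self):
        data = synth.random_raster(12, 12, n_classes=2, seed=9).data
        ps30 = L.delineate_patches(_raster(data, cell=30.0), 1)
        ps60 = L.delineate_patches(_raster(data, cell=60.0), 1)
        assert np.allclose(ps60.table["area_m2"], 4 * ps30.table["area_m2"])
        assert np.allclose(ps60.table["perimeter_m"],
                           2 * ps30.table["perimeter_m"])
        m30 = L.class_metrics(ps30, 10.0)
        m60 = L.class_metrics(ps60, 40.0)
        assert m60["MSI"] == pytest.approx(m30["MSI"])

    @given(h=st.integers(1, 12), w=st.integers(1, 12))
    @settings(max_examples=40, deadline=None)
    def test_msi_one_only_for_squares(self, h, w):
        data = np.zeros((14, 14), dtype=int)
        data[1:1 + h, 1:1 + w] = 1
        ps = L.delineate_patches(_raster(data), 1)
        msi = L.class_metrics(ps, 17.64)["MSI"]
        if h == w:
            assert msi == pytest.approx(1.0)
        else:
            assert msi > 1.0


class TestScales:
    def test_whole_unit_equals_direct_metrics(self):
        r = synth.random_raster(15, 15, n_classes=2, seed=4)
        direct = L.class_metrics(L.delineate_patches(r, 1),
                                 15 * 15 * 900 / 1e4)
        scaled = L.metrics_at_scales(r, 1).loc["whole"]
        pd.testing.assert_series_equal(direct, scaled, check_names=False)

    def test_buffer_in_uniform_forest(self):
        r = CategoricalRaster(np.ones((40, 40), dtype=int), cell_size=30.0,
                              legend={"forest": 1})
        pts = pd.DataFrame({"x": [600.0], "y": [600.0]}, index=["p"])
        rows = L.metrics_at_scales(r, "forest", points=pts,
                                   buffer_radius=300.0)
        n_cells = oracles.circle_cells(40, 40, 30.0, 0, 0, 600, 600, 300.0)
        area_ha = len(n_cells) * 900 / 1e4
        assert rows.at["p", "PD"] == pytest.approx(100.0 / area_ha)

    def test_disjoint_units_are_local(self):
        r = synth.random_raster(20, 20, n_classes=2, seed=5)
        m1 = np.zeros((20, 20), dtype=bool)
        m1[:10] = True
        m2 = ~m1
        both = L.metrics_at_scales(r, 1, units={"a": m1, "b": m2})
        # scrambling the other unit's content must not change a unit's row
        data2 = r.data.copy()
        data2[10:] = synth.random_raster(10, 20, n_classes=2, seed=99).data
        r2 = CategoricalRaster(data2, cell_size=30.0, legend=r.legend)
        again = L.metrics_at_scales(r2, 1, units={"a": m1, "b": m2})
        pd.testing.assert_series_equal(both.loc["a"], again.loc["a"])


class TestClassifier:
    def test_dominating_unit_is_high(self):
        rows = pd.DataFrame({
            "PD": [1, 2, 9], "ED": [10, 20, 90], "MPA": [50, 40, 2],
            "MSI": [1.1, 1.2, 2.0], "MCA": [30, 20, 0.5],
            "ENN": [50, 60, 500]}, index=["A", "B", "C"])
        out = L.classify_fragmentation(rows)
        assert out.at["C", "frag_class"] == "high"
        assert out.at["A", "frag_class"] == "low"

    def test_identical_units_all_moderate(self):
        rows = pd.DataFrame({m: [3.0, 3.0, 3.0] for m in L.METRICS},
                            index=list("abc"))
        out = L.classify_fragmentation(rows)
        assert (out["frag_class"] == "moderate").all()

    def test_too_few_units_rejected(self):
        rows = pd.DataFrame({m: [1.0, 2.0] for m in L.METRICS})
        with pytest.raises(ValueError):
            L.classify_fragmentation(rows)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_ranking(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        rows = pd.DataFrame(
            {m: np.round(rng.uniform(0, 10, n), 1) for m in L.METRICS},
            index=[f"u{i}" for i in range(n)])
        out = L.classify_fragmentation(rows)
        _, medians, classes = oracles.median_rank_classes(
            rows.to_dict("records"))
        assert out["median_rank"].tolist() == pytest.approx(medians)
        assert out["frag_class"].tolist() == classes

    def test_fragmented_geometry_ranks_high(self):
        """Small dispersed patches rank as highly fragmented; large compact
        blocks as low — the qualitative pattern of the study's forests."""
        compact = [synth.Placement("forest", "rect", 5, 5, 30, 30)]
        medium = [synth.Placement("forest", "rect", 5, 5, 12, 12),
                  synth.Placement("forest", "rect", 25, 22, 10, 10)]
        dispersed = [synth.Placement("forest", "rect",
                                     4 + 9 * (k // 3), 4 + 11 * (k % 3), 3, 3)
                     for k in range(9)]
        rows = {}
        for name, placements in (("compact", compact), ("medium", medium),
                                 ("dispersed", dispersed)):
            spec = synth.LandscapeSpec(40, 40, cell_size=30.0,
                                       placements=placements)
            raster, _ = synth.simulate_landscape(spec)
            ps = L.delineate_patches(raster, "forest")
            rows[name] = L.class_metrics(ps, 144.0)
        out = L.classify_fragmentation(pd.DataFrame(rows).T)
        assert out.at["dispersed", "frag_class"] == "high"
        assert out.at["compact", "frag_class"] == "low"
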