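"""Background estimation, planar polarity, TCJ enrichment, profiles,
mitotic index and cohort aggregation."""

import numpy as np
import pandas as pd
import pytest

from junctionscope.geometry import RegionSpec
from junctionscope.graph import skeleton_mask
from junctionscope.intensity import (cohort_summary, edge_mean_intensity,
                                     estimate_background, line_profile,
                                     mitotic_index, planar_polarity,
                                     tcj_ratio)
from junctionscope.synth import generate_field, preset


class TestBackground:
    def test_constant_image(self, small_graph):
        img = np.full(small_graph.label_image.shape, 42.0)
        est = estimate_background(img, small_graph, seed=1)
        assert est.value == pytest.approx(42.0)
        assert 20 <= est.n_rois <= 40

    def test_recovers_render_background(self, quiet_field):
        est = estimate_background(quiet_field.channels["aj"],
                                  quiet_field.graph, seed=2)
        assert est.value == pytest.approx(
            quiet_field.config.background_level, abs=1e-9)

    def test_deterministic_for_seed(self, quiet_field):
        a = estimate_background(quiet_field.channels["aj"],
                                quiet_field.graph, seed=5)
        b = estimate_background(quiet_field.channels["aj"],
                                quiet_field.graph, seed=5)
        assert a.value == b.value


class TestEdgeMean:
    def test_uniform_image(self, small_graph):
        img = np.full(small_graph.label_image.shape, 7.0)
        eid = int(small_graph.edges["id"].iloc[0])
        poly = small_graph.edge_polylines[eid]
        m = edge_mean_intensity(img, poly, small_graph.pixel_size_um)
        assert m == pytest.approx(7.0)

    def test_invariant_to_point_order(self, quiet_field):
        g = quiet_field.graph
        img = quiet_field.channels["aj"]
        sk = skeleton_mask(g.label_image)
        eid = int(g.edges.sort_values("length_um").iloc[-1]["id"])
        poly = g.edge_polylines[eid]
        m1 = edge_mean_intensity(img, poly, g.pixel_size_um, skeleton=sk)
        m2 = edge_mean_intensity(img, poly[::-1], g.pixel_size_um, skeleton=sk)
        assert m1 == pytest.approx(m2)

    def test_outside_image_errors(self, small_graph):
        img = np.zeros(small_graph.label_image.shape)
        with pytest.raises(ValueError):
            edge_mean_intensity(img, np.array([[1e5, 1e5], [1e5 + 1, 1e5]]),
                                small_graph.pixel_size_um)


class TestPlanarPolarity:
    def test_uniform_intensity_ratio_one(self):
        cfg = preset("zero_polarity", noise_sd=0.0, gap_prob_by_order={})
        f = generate_field(cfg, seed=31)
        pol = planar_polarity(f.channels["aj"], f.graph, None,
                              cfg.background_level)
        assert pol.ratio == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_of_polarity_factor(self, quiet_field):
        pol = planar_polarity(quiet_field.channels["aj"], quiet_field.graph,
                              None, quiet_field.config.background_level)
        assert pol.ratio == pytest.approx(3.0, abs=1e-9)
        assert pol.n_ml >= 1 and pol.n_ap >= 1

    def test_recovery_under_noise(self):
        ratios = []
        for s in range(3):
            cfg = preset("control_late", gap_prob_by_order={})
            f = generate_field(cfg, seed=600 + s)
            bg = estimate_background(f.channels["aj"], f.graph, seed=s)
            ratios.append(planar_polarity(f.channels["aj"], f.graph, None,
                                          bg.value).ratio)
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.05)

    def test_scale_invariance_after_background_subtraction(self, quiet_field):
        bg = quiet_field.config.background_level
        img = quiet_field.channels["aj"]
        scaled = bg + 3.7 * (img - bg)
        p1 = planar_polarity(img, quiet_field.graph, None, bg)
        p2 = planar_polarity(scaled, quiet_field.graph, None, bg)
        assert p2.ratio == pytest.approx(p1.ratio, rel=1e-9)

    def test_empty_bin_is_an_error(self, quiet_field):
        region = RegionSpec((0, 0), (0.5, 0.5))
        with pytest.raises(ValueError, match="bin is empty"):
            planar_polarity(quiet_field.channels["aj"], quiet_field.graph,
                            region, quiet_field.config.background_level)


class TestTcjRatio:
    def test_arithmetic_identity(self):
        # disk 90, edges 40/50/60, background 10 -> (90-10)/(50-10) = 2
        tcj, edges, bg = 90.0, (40.0, 50.0, 60.0), 10.0
        ratio = (tcj - bg) / (np.mean(edges) - bg)
        assert ratio == pytest.approx(2.0)

    def _ratios(self, field, n=8):
        g = field.graph
        bg = field.config.background_level
        out = []
        for vid in g.vertices.loc[g.vertices["order"] == 3, "id"]:
            try:
                out.append(tcj_ratio(field.channels["aj"], g, int(vid), bg).ratio)
            except ValueError:
                continue
            if len(out) >= n:
                break
        return out

    def test_exact_recovery_of_enrichment(self, quiet_field):
        ratios = self._ratios(quiet_field)
        assert len(ratios) >= 5
        np.testing.assert_allclose(ratios, 1.8, atol=1e-9)

    def test_unit_enrichment(self):
        cfg = preset("zero_polarity", noise_sd=0.0, gap_prob_by_order={})
        f = generate_field(cfg, seed=33)
        ratios = self._ratios(f)
        np.testing.assert_allclose(ratios, 1.0, atol=1e-9)

    def test_rejects_higher_order_vertex(self, quiet_field):
        g = quiet_field.graph
        v4 = g.vertices[g.vertices["order"] >= 4]
        with pytest.raises(ValueError, match="order"):
            tcj_ratio(quiet_field.channels["aj"], g, int(v4["id"].iloc[0]),
                      quiet_field.config.background_level)


class TestLineProfile:
    def test_ridge_peak_normalized(self):
        img = np.zeros((40, 40))
        img[:, 20] = 100.0
        out = line_profile(img, anchor_um=(20.5, 20.0), direction=0.0,
                           length_um=10, n_samples=41, pixel_size_um=1.0)
        assert out["normalized"]
        assert out["profile"].max() == pytest.approx(1.0)
        assert out["profile"][np.argmin(np.abs(out["offset_um"]))] == pytest.approx(1.0)

    def test_symmetric_gaussian_ridge(self):
        x = np.arange(60)
        img = np.tile(np.exp(-0.5 * ((x - 30) / 3.0) ** 2), (60, 1)) * 50
        out = line_profile(img, anchor_um=(30.5, 30.0), direction=0.0,
                           length_um=20, n_samples=41, pixel_size_um=1.0)
        np.testing.assert_allclose(out["profile"], out["profile"][::-1],
                                   atol=1e-6)

    def test_matches_bilinear_oracle(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 10, (30, 30))
        out = line_profile(img, anchor_um=(15.0, 15.0), direction=(1, 1),
                           length_um=6, n_samples=13, pixel_size_um=1.0,
                           background=0.0)
        d = np.array([1, 1]) / np.sqrt(2)
        raw = []
        for off in out["offset_um"]:
            x, y = np.array([15.0, 15.0]) + off * d
            j, i = x - 0.5, y - 0.5
            j0, i0 = int(np.floor(j)), int(np.floor(i))
            fj, fi = j - j0, i - i0
            val = (img[i0, j0] * (1 - fi) * (1 - fj)
                   + img[i0, j0 + 1] * (1 - fi) * fj
                   + img[i0 + 1, j0] * fi * (1 - fj)
                   + img[i0 + 1, j0 + 1] * fi * fj)
            raw.append(val)
        raw = np.array(raw)
        np.testing.assert_allclose(out["profile"], raw / raw.max(), atol=1e-9)

    def test_flat_line_flagged(self):
        img = np.full((20, 20), 5.0)
        with pytest.warns(UserWarning):
            out = line_profile(img, (10.0, 10.0), 0.0, length_um=6,
                               n_samples=7, pixel_size_um=1.0, background=5.0)
        assert not out["normalized"]


class TestMitoticIndex:
    def test_counts(self, small_graph):
        region = RegionSpec((0, 0), (40, 40))
        n_cells = int(region.contains(
            small_graph.cells[["x_um", "y_um"]].to_numpy()).sum())
        assert mitotic_index(np.empty((0, 2)), small_graph, region) == 0.0
        all_pts = small_graph.cells[["x_um", "y_um"]].to_numpy()
        assert mitotic_index(all_pts, small_graph, region) == pytest.approx(1.0)
        some = all_pts[:4]
        assert mitotic_index(some, small_graph, region) == pytest.approx(
            4 / n_cells)

    def test_zero_cells_errors(self, small_graph):
        with pytest.raises(ValueError):
            mitotic_index(np.empty((0, 2)), small_graph,
                          RegionSpec((500, 500), (10, 10)))


class TestCohortSummary:
    def test_single_value_per_embryo(self):
        out = cohort_summary({"e1": [2.0], "e2": [4.0], "e3": [6.0]})
        assert out["cohort_mean"] == pytest.approx(4.0)

    def test_equal_groups_equal_pooled_mean(self):
        vals = {"a": [1.0, 2.0], "b": [3.0, 4.0]}
        out = cohort_summary(vals)
        assert out["cohort_mean"] == pytest.approx(2.5)

    def test_sem_matches_formula(self):
        groups = {"a": [1.0, 3.0], "b": [5.0], "c": [2.0, 2.0]}
        means = np.array([2.0, 5.0, 2.0])
        sem = means.std(ddof=1) / np.sqrt(3)
        out = cohort_summary(groups, dispersion="sem")
        assert out["dispersion"] == pytest.approx(sem)
        out_sd = cohort_summary(groups, dispersion="sd")
        assert out_sd["dispersion"] == pytest.approx(means.std(ddof=1))

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            out = cohort_summary({"a": [1.0], "b": []})
        assert out["n_embryos"] == 1
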