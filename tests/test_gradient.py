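import numpy as np
import pytest

from lesionkit.errors import ValidationError
from lesionkit import gradient as gr
from lesionkit.io_formats import GeneSet

from conftest import make_norm, make_spots


class TestTemplates:
    def test_eight_templates_length_13(self):
        lib = gr.build_templates(13)
        assert len(lib.names()) == 8
        assert all(len(lib[m]) == 13 for m in lib.names())

    def test_linear_descending_midpoint(self):
        f = gr.template_function("linear_descending")
        assert f(np.array([0.5]))[0] == pytest.approx(0.5)

    def test_ascending_descending_sum_to_one(self):
        lib = gr.build_templates(13)
        for base in ("linear", "immediate", "abrupt", "late"):
            total = lib[f"{base}_descending"] + lib[f"{base}_ascending"]
            np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_descending_non_increasing(self):
        lib = gr.build_templates(13)
        for name in lib.names():
            if name.endswith("_descending"):
                assert np.all(np.diff(lib[name]) <= 1e-12)

    def test_values_in_unit_interval(self):
        lib = gr.build_templates(20)
        for name in lib.names():
            assert lib[name].min() >= 0.0 and lib[name].max() <= 1.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValidationError):
            gr.build_templates(3)


class TestLesionAnnotation:
    def test_circle_requires_positive_radius(self):
        with pytest.raises(ValidationError):
            gr.LesionAnnotation("L", center=(0, 0), radius=0.0)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = ((0, 0), (2, 2), (2, 0), (0, 2))
        with pytest.raises(ValidationError):
            gr.LesionAnnotation("L", polygon=bowtie)

    def test_polygon_distance(self):
        square = ((0, 0), (10, 0), (10, 10), (0, 10))
        ann = gr.LesionAnnotation("L", polygon=square)
        d = ann.boundary_distance(np.array([[5.0, 5.0], [15.0, 5.0]]))
        assert d[0] == 0.0
        assert d[1] == pytest.approx(5.0)


class TestBinning:
    def test_inside_core_is_bin_zero(self):
        spots = make_spots([[50.0, 0.0]])
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)
        assert bins.bins["s0"] == 0

    def test_distance_50_is_bin_one(self):
        # spot at 100 um from center of a 50 um core: boundary distance 50
        spots = make_spots([[100.0, 0.0], [10.0, 0.0]])
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)
        assert bins.bins["s0"] == 1

    def test_beyond_window_unassigned(self):
        # 13 * 95 = 1235; d = 1236 falls outside, d = 1235 lands in bin 13
        spots = make_spots([[1286.0, 0.0], [1285.0, 0.0], [0.0, 0.0]])
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)
        assert "s0" not in bins.bins
        assert bins.bins["s1"] == 13

    def test_upper_edge_inclusive(self):
        spots = make_spots([[145.0, 0.0]])  # boundary distance exactly 95
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)
        assert bins.bins["s0"] == 1

    def test_excluded_clusters_unassigned(self):
        spots = make_spots([[100.0, 0.0], [120.0, 0.0]], clusters=["keep", "drop"])
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13,
                                         exclude_clusters={"drop"})
        assert "s1" not in bins.bins and "s0" in bins.bins

    def test_no_assignable_spot_errors(self):
        spots = make_spots([[5000.0, 0.0]])
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        with pytest.raises(ValidationError):
            gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)

    def test_matches_scalar_oracle(self, rng):
        """Vectorized binning equals a per-spot scalar scan, incl. edges."""
        coords = rng.uniform(-2000, 2000, size=(500, 2))
        spots = make_spots(coords)
        ann = gr.LesionAnnotation("L", center=(37.0, -11.0), radius=130.0)
        w, B = 95.0, 13
        bins = gr.assign_concentric_bins(spots, ann, binwidth=w, n_bins=B)
        edges = np.arange(1, B + 1) * w
        for i, bc in enumerate(spots.barcodes):
            d = max(np.hypot(coords[i, 0] - 37.0, coords[i, 1] + 11.0) - 130.0, 0.0)
            if d == 0.0:
                expect = 0
            else:
                expect = next((k for k in range(1, B + 1) if d <= edges[k - 1]), None)
            if expect is None:
                assert bc not in bins.bins
            else:
                assert bins.bins[bc] == expect

    def test_bin_monotone_in_distance(self):
        xs = np.linspace(60.0, 1400.0, 200)
        spots = make_spots(np.column_stack([xs, np.zeros_like(xs)]))
        ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=13)
        seq = [bins.bins[b] for b in spots.barcodes if b in bins.bins]
        assert seq == sorted(seq)


def _profile_fixture():
    """12 spots in rings 1..4 (3 each) around a core spot."""
    coords = [[0.0, 0.0]]
    for k in range(1, 5):
        r = 50.0 + (k - 0.5) * 95.0
        for j in range(3):
            theta = 2 * np.pi * j / 3 + k
            coords.append([r * np.cos(theta), r * np.sin(theta)])
    spots = make_spots(coords)
    ann = gr.LesionAnnotation("L", center=(0.0, 0.0), radius=50.0)
    bins = gr.assign_concentric_bins(spots, ann, binwidth=95.0, n_bins=4)
    return spots, bins


class TestProfiles:
    def test_constant_feature_flagged(self):
        spots, bins = _profile_fixture()
        norm = make_norm(np.full((1, 13), 2.5), gene_ids=["gc"],
                         obs_ids=list(spots.barcodes))
        profs = gr.compute_profiles(norm, bins, ["gc"])
        assert profs[0].is_constant and profs[0].scaled is None

    def test_single_member_set_equals_gene(self):
        spots, bins = _profile_fixture()
        vals = np.arange(13, dtype=float)[None, :]
        norm = make_norm(vals, gene_ids=["ga"], obs_ids=list(spots.barcodes))
        profs = gr.compute_profiles(
            norm, bins, ["ga", GeneSet("S", "", frozenset({"ga"}))])
        np.testing.assert_allclose(profs[0].ybar, profs[1].ybar)

    def test_planted_linear_recovers_template(self):
        spots, bins = _profile_fixture()
        lib = gr.build_templates(4)
        x = (np.arange(1, 5) - 0.5) / 4
        values = np.zeros((1, 13))
        for bc, k in bins.bins.items():
            if k >= 1:
                idx = list(spots.barcodes).index(bc)
                values[0, idx] = 1.0 - x[k - 1]
        norm = make_norm(values, gene_ids=["gl"], obs_ids=list(spots.barcodes))
        profs = gr.compute_profiles(norm, bins, ["gl"])
        tmpl = lib["linear_descending"]
        tmpl_scaled = (tmpl - tmpl.min()) / np.ptp(tmpl)
        np.testing.assert_allclose(profs[0].scaled, tmpl_scaled, atol=1e-12)
        res = gr.screen_profiles(profs, lib)
        assert res[0].best_model == "linear_descending"
        assert res[0].r == pytest.approx(1.0)


class TestScreening:
    def test_exact_linear_wins(self):
        lib = gr.build_templates(4)
        prof = gr.GradientProfile("f", "L", ybar=lib["linear_descending"].copy(),
                                  scaled=lib["linear_descending"].copy(),
                                  is_constant=False, incomplete=False)
        res = gr.screen_profiles([prof], lib)
        assert res[0].best_model == "linear_descending"
        assert res[0].r == pytest.approx(1.0)

    def test_count_filter_strictly_greater(self):
        lib = gr.build_templates(13)
        y = lib["linear_descending"].copy()
        profs = [gr.GradientProfile("g50", "L", y, y, False, False),
                 gr.GradientProfile("g51", "L", y, y, False, False)]
        res = gr.screen_profiles(profs, lib, min_total_counts=50,
                                 raw_totals={"g50": 50, "g51": 51})
        assert [r.feature_id for r in res] == ["g51"]

    def test_gene_sets_exempt_from_count_filter(self):
        lib = gr.build_templates(13)
        y = lib["linear_descending"].copy()
        profs = [gr.GradientProfile("SETX", "L", y, y, False, False)]
        res = gr.screen_profiles(profs, lib, min_total_counts=50, raw_totals={})
        assert len(res) == 1

    def test_length_mismatch_rejected(self):
        lib = gr.build_templates(13)
        y = np.linspace(1, 0, 7)
        prof = gr.GradientProfile("f", "L", y, y, False, False)
        with pytest.raises(ValidationError):
            gr.screen_profiles([prof], lib)

    def test_affine_rescaling_invariance(self, rng):
        lib = gr.build_templates(13)
        y = rng.random(13)
        p1 = gr.GradientProfile("a", "L", y, (y - y.min()) / np.ptp(y), False, False)
        y2 = 3.0 * y + 7.0
        p2 = gr.GradientProfile("b", "L", y2, (y2 - y2.min()) / np.ptp(y2),
                                False, False)
        r1, r2 = gr.screen_profiles([p1, p2], lib)
        assert r1.best_model == r2.best_model
        assert r1.r == pytest.approx(r2.r, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)


class TestNullCalibration:
    @staticmethod
    def _null_fraction(seed):
        from lesionkit import preprocess as pp
        from lesionkit import synthetic_data as syn

        # fixed depth: per-spot scale noise is shared by all genes and would
        # otherwise dominate the seed-to-seed wobble of the fraction
        cfg = syn.SpatialSimConfig(n_rows=36, n_cols=36, n_genes=2000,
                                   n_gradient_genes={}, n_housekeeping=50,
                                   cells_per_spot=(5, 5), libsize_sigma=0.0,
                                   seed=seed)
        cm, spots, _ = syn.simulate_spatial(cfg)
        norm = pp.normalize_log_cpm(cm)
        coords = spots.coords()
        center = ((coords[:, 0].min() + coords[:, 0].max()) / 2,
                  (coords[:, 1].min() + coords[:, 1].max()) / 2)
        ann = gr.LesionAnnotation("L", center=center, radius=cfg.core_radius)
        bins = gr.assign_concentric_bins(spots, ann, binwidth=cfg.binwidth_um,
                                         n_bins=cfg.n_bins)
        profs = gr.compute_profiles(norm, bins, list(norm.gene_ids))
        res = gr.screen_profiles(profs, gr.build_templates(cfg.n_bins),
                                 min_total_counts=50,
                                 raw_totals=dict(zip(cm.gene_ids,
                                                     cm.counts_per_gene())))
        ps = np.array([s.p for s in res])
        return (ps < 0.05).mean(), len(ps)

    def test_best_model_rate_stable_across_seeds(self):
        """argmax over 8 templates inflates the nominal rate, but the
        inflated fraction is reproducible: each seed within +/- 2% of the
        across-seed mean."""
        fracs = []
        for seed in (101, 202, 303):
            f, n = self._null_fraction(seed)
            assert n > 1500
            fracs.append(f)
        mean = sum(fracs) / len(fracs)
        assert mean > 0.05  # inflation above the nominal rate is expected
        assert all(abs(f - mean) <= 0.02 for f in fracs)


class TestMergeLesions:
    def _result(self, fid, lesion, p_by_model, r_by_model, ybar):
        best = min(r_by_model, key=lambda m: (-r_by_model[m], m))
        return gr.ScreeningResult(
            feature_id=fid, lesion_id=lesion, best_model=best, r=r_by_model[best],
            p=p_by_model[best], model_r=r_by_model, model_p=p_by_model,
            ybar=np.asarray(ybar, dtype=float), p_value_mean=p_by_model[best])

    def test_duplicate_lesions_equal_single(self):
        pm = {"linear_descending": 0.01, "late_descending": 0.2}
        rm = {"linear_descending": 0.9, "late_descending": 0.3}
        a = self._result("g", "l1", pm, rm, [3, 2, 1])
        b = self._result("g", "l2", pm, rm, [3, 2, 1])
        merged = gr.merge_lesions({"l1": [a], "l2": [b]})[0]
        single = gr.merge_lesions({"l1": [a]})[0]
        assert merged.best_model == single.best_model
        assert merged.p_value_mean == pytest.approx(single.p_value_mean)
        np.testing.assert_allclose(merged.ybar, single.ybar)

    def test_p_value_mean_arithmetic(self):
        rm = {"linear_descending": 0.9}
        a = self._result("g", "l1", {"linear_descending": 0.01}, rm, [1, 0])
        b = self._result("g", "l2", {"linear_descending": 0.03}, rm, [1, 0])
        merged = gr.merge_lesions({"l1": [a], "l2": [b]})[0]
        assert merged.p_value_mean == pytest.approx(0.02)

    def test_single_lesion_passthrough(self):
        rm = {"linear_descending": 0.8}
        a = self._result("g", "l1", {"linear_descending": 0.04}, rm, [1, 0])
        merged = gr.merge_lesions({"l1": [a]})[0]
        assert merged.p_value_mean == pytest.approx(0.04)
        assert merged.best_model == "linear_descending"

    def test_mismatched_bins_rejected(self):
        rm = {"m": 0.5}
        a = self._result("g", "l1", {"m": 0.1}, rm, [1, 0, 1])
        b = self._result("g", "l2", {"m": 0.1}, rm, [1, 0])
        with pytest.raises(ValidationError):
            gr.merge_lesions({"l1": [a], "l2": [b]})

    def test_sorted_by_p_value_mean(self):
        rm = {"m": 0.5}
        a = self._result("g1", "l1", {"m": 0.2}, rm, [1, 0])
        b = self._result("g2", "l1", {"m": 0.05}, rm, [1, 0])
        merged = gr.merge_lesions({"l1": [a, b]})
        assert [m.feature_id for m in merged] == ["g2", "g1"]
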