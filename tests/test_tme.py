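import numpy as np
import pytest

from digicms.cohort_io import NucleusRecord
from digicms.synthetic import generate_ihc_tile
from digicms.tme import (
    bh_adjust,
    cd8_area_fraction,
    cliffs_delta,
    compare_groups,
    correlate_scores,
    polygon_area_um2,
    polygon_perimeter_um,
    profile_region,
    profiles_to_frame,
    tumour_rich_lymphocyte_density,
)


def _nucleus(nid, label, cx, cy, r=3.0, mpp=0.5):
    contour = [[cx - r, cy - r], [cx + r, cy - r], [cx + r, cy + r], [cx - r, cy + r]]
    return NucleusRecord(nid, label, np.asarray(contour, float), (cx, cy), mpp)


def _cells(label, n, mpp=0.5, start=0):
    return [_nucleus(start + i, label, 10.0 + 6 * i, 10.0, mpp=mpp) for i in range(n)]


class TestRegionFormulas:
    def test_density_formula_worked_example(self):
        # 100 cells in a 256x256 px region at 0.5 mpp: A = 16384 um^2
        nuclei = _cells("lymphocyte", 100)
        prof = profile_region(nuclei, 256 * 256, 0.5, "V6")
        assert prof.area_um2 == 16384.0
        assert prof.density["lymphocyte"] == pytest.approx(100 / 16384)
        assert prof.ln_density["lymphocyte"] == pytest.approx(-5.099, abs=1e-3)

    def test_square_nucleus_area_perimeter(self):
        # 10x10 px square at 0.5 mpp: 25 um^2, 20 um
        contour = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert polygon_area_um2(contour, 0.5) == pytest.approx(25.0)
        assert polygon_perimeter_um(contour, 0.5) == pytest.approx(20.0)

    def test_shoelace_matches_shapely_on_random_polygons(self, rng):
        from shapely.geometry import Polygon

        for _ in range(20):
            n = int(rng.integers(3, 12))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radii = rng.uniform(2, 8, n)
            pts = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
            poly = Polygon(pts)
            assert polygon_area_um2(pts, 0.5) == pytest.approx(poly.area * 0.25, rel=1e-9)
            assert polygon_perimeter_um(pts, 0.5) == pytest.approx(poly.length * 0.5, rel=1e-9)

    def test_nlr_ratio_definition(self):
        nuclei = _cells("neutrophil", 10) + _cells("lymphocyte", 4, start=10)
        prof = profile_region(nuclei, 256 * 256, 0.5, "V6")
        assert prof.nlr == pytest.approx(2.5)
        assert prof.ratio["neutrophil"] == pytest.approx(10 / 14)

    def test_ratios_sum_to_one_and_counts_conserved(self, rng):
        labels = rng.choice(["neutrophil", "epithelial", "lymphocyte", "plasma"], 50)
        nuclei = [_nucleus(i, lab, 5.0 + 7 * i, 12.0) for i, lab in enumerate(labels)]
        prof = profile_region(nuclei, 512 * 512, 0.5, "V6")
        assert sum(prof.counts.values()) == 50
        assert sum(prof.ratio.values()) == pytest.approx(1.0)

    def test_missing_cell_type_yields_nan_not_zero(self):
        prof = profile_region(_cells("epithelial", 5), 256 * 256, 0.5, "V6")
        assert np.isnan(prof.ln_density["lymphocyte"])
        assert np.isnan(prof.nlr)  # zero lymphocytes -> NLR missing, not inf
        assert np.isnan(prof.morphology["lymphocyte"]["area_mean"])

    def test_scale_consistency_with_mpp(self):
        contour = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert polygon_area_um2(contour, 1.0) == 4 * polygon_area_um2(contour, 0.5)
        assert polygon_perimeter_um(contour, 1.0) == 2 * polygon_perimeter_um(contour, 0.5)
        # density in um^-2 invariant for fixed physical content
        a = profile_region(_cells("epithelial", 20, mpp=0.5), 256 * 256, 0.5, "V6")
        b = profile_region(_cells("epithelial", 20, mpp=1.0), 128 * 128, 1.0, "V6")
        assert a.density["epithelial"] == pytest.approx(b.density["epithelial"])

    def test_mixed_vocabulary_rejected(self):
        nuclei = _cells("lymphocyte", 2) + _cells("neoplastic", 2, start=2)
        with pytest.raises(ValueError, match="vocabular"):
            profile_region(nuclei, 256 * 256, 0.5, "V6")


class TestTumourRichDensity:
    # one 128x128 um^2 patch is 256x256 px at 0.5 mpp

    def _patch_cells(self, label, n, mpp=0.5):
        rng = np.random.default_rng(n)
        return [
            _nucleus(i, label, rng.uniform(0, 128 / mpp), rng.uniform(0, 128 / mpp), mpp=mpp)
            for i in range(n)
        ]

    def test_strictly_more_than_50_neoplastic_required(self):
        lym = self._patch_cells("lymphocyte", 30)
        at_50 = tumour_rich_lymphocyte_density(
            self._patch_cells("neoplastic", 50), lym, 0.5)
        assert np.isnan(at_50)
        at_51 = tumour_rich_lymphocyte_density(
            self._patch_cells("neoplastic", 51), lym, 0.5)
        assert at_51 == pytest.approx(np.log(30 / 128**2))

    def test_no_qualifying_patch_is_missing_not_zero(self):
        out = tumour_rich_lymphocyte_density(
            self._patch_cells("neoplastic", 10), self._patch_cells("lymphocyte", 5), 0.5)
        assert np.isnan(out)

    def test_pooled_density_over_two_patches(self):
        neo = self._patch_cells("neoplastic", 60)
        # second qualifying patch one grid cell to the right (shift by 256 px)
        neo2 = [
            NucleusRecord(100 + r.nucleus_id, r.class_label, r.contour + [256, 0],
                          (r.centroid[0] + 256, r.centroid[1]), r.mpp)
            for r in neo
        ]
        lym = self._patch_cells("lymphocyte", 40)  # all in the first patch
        out = tumour_rich_lymphocyte_density(neo + neo2, lym, 0.5)
        assert out == pytest.approx(np.log(40 / (2 * 128**2)))


class TestGroupStatistics:
    def test_cliffs_delta_complete_separation(self):
        assert cliffs_delta([1, 2, 3], [4, 5, 6]) == -1.0
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0

    def test_cliffs_delta_matches_enumeration(self, rng):
        x = rng.integers(0, 10, 23).astype(float)
        y = rng.integers(0, 10, 17).astype(float)
        delta = sum(
            (1.0 if a > b else -1.0 if a < b else 0.0) for a in x for b in y
        ) / (len(x) * len(y))
        assert cliffs_delta(x, y) == pytest.approx(delta, abs=1e-12)

    def test_bh_step_up_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_step_up_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 12))
            p = rng.random(m)
            # step-up oracle
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, p[i] * m / rank_from_top)
                adj[i] = val
                prev = val
            np.testing.assert_allclose(bh_adjust(p), adj, atol=1e-12)
            assert (bh_adjust(p) >= p - 1e-12).all()

    def test_identical_groups_null_result(self):
        import pandas as pd

        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        out = compare_groups(df, df.copy(), ["f"])
        row = out.iloc[0]
        assert row["cliffs_delta"] == 0.0
        assert abs(row["t"]) < 1e-12
        assert row["t_p"] > 0.99

    def test_untestable_feature_reported(self):
        import pandas as pd

        df1 = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        df2 = pd.DataFrame({"f": [np.nan, np.nan, 4.0]})
        out = compare_groups(df1, df2, ["f"])
        assert not out.iloc[0]["testable"]
        assert not out.iloc[0]["significant"]

    def test_spearman_trivial_orientations(self):
        inc = correlate_scores([0.1, 0.2, 0.3, 0.4], [1.0, 2.0, 3.0, 4.0])
        assert inc["rho"] == pytest.approx(1.0)
        dec = correlate_scores([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
        assert dec["rho"] == pytest.approx(-1.0)

    def test_spearman_matches_rank_then_pearson(self, rng):
        from scipy import stats

        x = rng.standard_normal(50)
        y = 0.4 * x + rng.standard_normal(50)
        out = correlate_scores(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert out["rho"] == pytest.approx(oracle, abs=1e-12)
        assert out["n"] == 50

    def test_spearman_constant_vector_undefined(self):
        out = correlate_scores([1.0, 1.0, 1.0, 1.0], [0.3, 0.2, 0.5, 0.4])
        assert np.isnan(out["rho"])
        assert out["n"] == 4

    def test_spearman_drops_missing_pairs(self):
        out = correlate_scores([0.1, 0.2, np.nan, 0.4], [1.0, 2.0, 3.0, 4.0])
        assert out["n"] == 3


class TestCD8Scoring:
    @pytest.mark.parametrize("frac", [0.0, 0.3, 1.0])
    def test_recovers_planted_fraction(self, frac):
        img, truth = generate_ihc_tile(frac, rng=np.random.default_rng(1))
        assert cd8_area_fraction(img) == pytest.approx(truth, abs=0.02)

    def test_empty_tissue_mask_rejected(self):
        img, _ = generate_ihc_tile(0.5, rng=np.random.default_rng(2))
        with pytest.raises(ValueError, match="tissue"):
            cd8_area_fraction(img, tissue_mask=np.zeros(img.shape[:2], bool))

    def test_threshold_is_configurable(self):
        img, _ = generate_ihc_tile(0.4, rng=np.random.default_rng(3))
        # absurdly high OD threshold -> nothing positive
        assert cd8_area_fraction(img, dab_threshold=5.0) == 0.0


class TestProfilesFrame:
    def test_flat_frame_has_feature_columns(self, small_spec):
        from digicms.synthetic import generate_nuclei

        rng = np.random.default_rng(6)
        profs = [
            profile_region(generate_nuclei(small_spec, 0, "V6", rng=rng),
                           256 * 256, 0.5, "V6", region_id=f"r{i}")
            for i in range(3)
        ]
        df = profiles_to_frame(profs)
        assert len(df) == 3
        assert "lymphocyte_ln_density" in df.columns
        assert "nlr" in df.columns
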