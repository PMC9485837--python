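"""Occurrence cleaning, range building, overlap, and disparity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from campion.geo import (AlbersEqualArea, OccurrenceSet, RangePolygon,
                         art_two_way, build_pairwise_table, build_range,
                         clean_and_thin, fit_albers, kruskal_wallis,
                         overlap_disparity_correlation, overlap_index,
                         pairwise_disparity, rank_ancova)


def rect_range(x0, y0, x1, y1, sid="r"):
    g = box(x0, y0, x1, y1)
    return RangePolygon(sid, g, g.area, projection=None)


class TestCleanThin:
    def test_origin_and_bounds_and_duplicates_removed(self):
        raw = OccurrenceSet("s", [[0.0, 0.0], [-100.0, 38.0], [-100.0, 38.0],
                                  [10.0, 70.0]])
        out = clean_and_thin(raw, bounds=(-130, 20, -60, 60), min_distance_km=0)
        assert len(out) == 1
        assert np.allclose(out.points[0], [-100.0, 38.0])

    def test_close_pair_thinned(self):
        # ~0.5 km apart at 38N; 1 km rule keeps only one
        raw = OccurrenceSet("s", [[-100.0, 38.0], [-100.0, 38.0045]])
        out = clean_and_thin(raw, min_distance_km=1.0)
        assert len(out) == 1

    def test_thinned_sets_respect_min_distance(self):
        from campion.geo import _haversine_km
        rng = np.random.default_rng(2)
        for _ in range(20):
            pts = np.column_stack([
                -100 + rng.uniform(0, 0.3, 60), 38 + rng.uniform(0, 0.3, 60)])
            out = clean_and_thin(OccurrenceSet("s", pts), min_distance_km=5.0)
            P = out.points
            for i in range(len(P)):
                for j in range(i + 1, len(P)):
                    assert _haversine_km(P[i], P[j]) >= 5.0 - 1e-9

    def test_empty_after_cleaning_warns(self):
        with pytest.warns(UserWarning):
            out = clean_and_thin(OccurrenceSet("s", [[0.0, 0.0]]))
        assert len(out) == 0


class TestRanges:
    def test_single_point_buffer_is_circle(self):
        rp = build_range(OccurrenceSet("s", [[-100.0, 38.0]]), buffer_km=10.0)
        assert rp.area_km2 == pytest.approx(np.pi * 100, rel=0.005)

    def test_two_distant_points_two_circles(self):
        occ = OccurrenceSet("s", [[-100.0, 38.0], [-99.0, 38.0]])  # ~88 km apart
        rp = build_range(occ, buffer_km=10.0)
        assert rp.area_km2 == pytest.approx(2 * np.pi * 100, rel=0.005)

    def test_zero_buffer_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="zero"):
            rp = build_range(OccurrenceSet("s", [[-100.0, 38.0]]), buffer_km=0.0)
        assert rp.area_km2 == 0.0 and rp.degenerate

    def test_projection_preserves_area_at_scale(self):
        # a 1-degree lon x 1-degree lat quad at 38N is ~9800 km^2; the
        # equal-area projection of its dense point grid buffered tightly
        # should land near the spherical-excess area
        proj = AlbersEqualArea(lon0=-100, lat0=38, lat1=30, lat2=46)
        lats = np.linspace(37.5, 38.5, 30)
        R = 6371.0072
        exact = (np.radians(1.0) * R**2
                 * (np.sin(np.radians(38.5)) - np.sin(np.radians(37.5))))
        xs, ys = proj.forward(np.full(30, -100.0), lats)
        # column heights in projected space must integrate to the exact area
        from shapely.geometry import Polygon
        x0, y0 = proj.forward([-100.5] * 50, np.linspace(37.5, 38.5, 50))
        x1, y1 = proj.forward([-99.5] * 50, np.linspace(38.5, 37.5, 50))
        poly = Polygon(list(zip(x0, y0)) + list(zip(x1, y1)))
        assert poly.area == pytest.approx(exact, rel=1e-4)


class TestOverlap:
    def test_disjoint_allopatric(self):
        a, b = rect_range(0, 0, 1, 1), rect_range(5, 5, 6, 6)
        ov, idx, symp = overlap_index(a, b)
        assert (ov, idx, symp) == (0.0, 0.0, False)

    def test_nested_unit_area(self):
        # areas 2 and 1, overlap 1 -> 1 / ((2-1) + (1-1)) = 1
        a, b = rect_range(0, 0, 2, 1), rect_range(0, 0, 1, 1)
        ov, idx, symp = overlap_index(a, b)
        assert ov == pytest.approx(1.0) and idx == pytest.approx(1.0) and symp

    def test_half_overlapping_unit_squares(self):
        a, b = rect_range(0, 0, 1, 1), rect_range(0.5, 0, 1.5, 1)
        ov, idx, _ = overlap_index(a, b)
        assert ov == pytest.approx(0.5) and idx == pytest.approx(0.5)

    def test_identical_ranges_inf_sentinel(self):
        a, b = rect_range(0, 0, 1, 1), rect_range(0, 0, 1, 1)
        ov, idx, symp = overlap_index(a, b)
        assert np.isinf(idx) and symp

    def test_symmetry(self):
        a, b = rect_range(0, 0, 3, 2), rect_range(1, 1, 5, 4)
        assert overlap_index(a, b) == overlap_index(b, a)


class TestDisparity:
    def test_values_and_count(self):
        scores = pd.DataFrame({"pPC1": [2.0, -1.5, 0.0], "pPC2": [0.0, 1.0, 1.0]},
                              index=["a", "b", "c"])
        out = pairwise_disparity(scores)
        assert len(out) == 3
        row = out[(out.species_a == "a") & (out.species_b == "b")].iloc[0]
        assert row.pPC1_disparity == pytest.approx(3.5)
        assert out[(out.species_a == "b") & (out.species_b == "c")].iloc[0] \
            .pPC2_disparity == pytest.approx(0.0)

    def test_pairwise_table_stable_under_reordering(self):
        ranges = {s: rect_range(i, 0, i + 2, 2, s) for i, s in enumerate("abc")}
        scores = pd.DataFrame({"pPC1": [1.0, 2.0, 4.0], "pPC2": [0.0, 0.0, 1.0]},
                              index=["a", "b", "c"])
        colors = pd.Series({"a": "red", "b": "white", "c": "pink"})
        t1 = build_pairwise_table(ranges, scores, colors)
        t2 = build_pairwise_table(ranges, scores.iloc[::-1], colors)
        pd.testing.assert_frame_equal(
            t1.sort_values(["species_a", "species_b"]).reset_index(drop=True),
            t2.sort_values(["species_a", "species_b"]).reset_index(drop=True))
        assert set(t1.color_pair) == {"red-white", "red-pink", "pink-white"}


class TestKruskalWallis:
    def test_hand_checked_ranks(self):
        H, df, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert H == pytest.approx(2.4)
        assert df == 1

    def test_identical_groups_zero(self):
        H, _, p = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert H == 0.0 and p == 1.0

    def test_matches_manual_tie_corrected_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            x = np.round(rng.standard_normal(15), 1)  # induce ties
            g = rng.choice(["a", "b", "c"], 15)
            if min((g == lv).sum() for lv in "abc") < 1 or np.ptp(x) == 0:
                continue
            H, df, p = kruskal_wallis(x, g)
            r = stats.rankdata(x)
            n = len(x)
            Hm = 12 / (n * (n + 1)) * sum(
                (g == lv).sum() * (r[g == lv].mean() - (n + 1) / 2) ** 2
                for lv in np.unique(g))
            _, counts = np.unique(x, return_counts=True)
            tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
            assert H == pytest.approx(Hm / tie, abs=1e-9)


class TestArtTwoWay:
    @staticmethod
    def simulate(rng, a_effect=0.0, b_effect=0.0, n=60):
        A = rng.choice(["p", "q", "r"], n)
        B = rng.choice(["s", "t"], n)
        y = rng.standard_normal(n)
        y += a_effect * (A == "p") - a_effect * (A == "r")
        y += b_effect * (B == "s")
        return y, A, B

    def test_detects_a_not_b(self):
        rng = np.random.default_rng(31)
        hits_a = hits_b = 0
        n_sim = 200
        for _ in range(n_sim):
            y, A, B = self.simulate(rng, a_effect=1.2)
            tab = art_two_way(y, A, B)
            hits_a += tab.loc["A", "p"] < 0.05
            hits_b += tab.loc["B", "p"] < 0.05
        assert hits_a / n_sim >= 0.9
        assert hits_b / n_sim <= 0.12

    def test_null_type_one_error(self):
        rng = np.random.default_rng(37)
        hits = {"A": 0, "B": 0, "A:B": 0}
        n_sim = 500
        for _ in range(n_sim):
            y, A, B = self.simulate(rng)
            tab = art_two_way(y, A, B)
            for eff in hits:
                hits[eff] += tab.loc[eff, "p"] < 0.05
        for eff, count in hits.items():
            assert 0.02 <= count / n_sim <= 0.10, eff

    def test_aligned_ranks_sum_identity(self):
        rng = np.random.default_rng(41)
        y, A, B = self.simulate(rng, a_effect=0.5, b_effect=0.5, n=40)
        # rank sums are n(n+1)/2 whatever the alignment subtracted
        n = len(y)
        grand = y.mean()
        df = pd.DataFrame({"y": y, "A": A, "B": B})
        mean_ab = df.groupby(["A", "B"])["y"].transform("mean").to_numpy()
        aligned = y - mean_ab + (df.groupby("A")["y"].transform("mean").to_numpy() - grand)
        assert stats.rankdata(aligned).sum() == n * (n + 1) / 2

    def test_empty_cell_rejected(self):
        y = np.arange(6.0)
        A = ["p", "p", "p", "q", "q", "q"]
        B = ["s", "s", "s", "t", "t", "t"]  # cells (p,t), (q,s) empty
        with pytest.raises(ValueError, match="empty"):
            art_two_way(y, A, B)

    def test_matches_statsmodels_on_balanced_design(self):
        # on a balanced design the drop-one-term F equals anova_lm's
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(43)
        A = np.repeat(["p", "q", "r"], 20)
        B = np.tile(np.repeat(["s", "t"], 10), 3)
        y = rng.standard_normal(60) + 0.8 * (A == "p")
        tab = art_two_way(y, A, B)
        grand = y.mean()
        df = pd.DataFrame({"y": y, "A": A, "B": B})
        mean_ab = df.groupby(["A", "B"])["y"].transform("mean").to_numpy()
        mean_a = df.groupby("A")["y"].transform("mean").to_numpy()
        aligned = stats.rankdata(y - mean_ab + mean_a - grand)
        fit = smf.ols("r ~ C(A) * C(B)", data=df.assign(r=aligned)).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert tab.loc["A", "F"] == pytest.approx(ref.loc["C(A)", "F"], rel=1e-8)


class TestRankAncova:
    def test_detects_group_effect_with_noise_covariate(self):
        rng = np.random.default_rng(47)
        hits = 0
        for _ in range(200):
            g = np.repeat(["u", "v"], 25)
            x = rng.standard_normal(50)
            y = rng.standard_normal(50) + 1.0 * (g == "u")
            F, p = rank_ancova(y, g, x)
            hits += p < 0.05
        assert hits / 200 >= 0.9

    def test_null_when_response_driven_by_covariate(self):
        rng = np.random.default_rng(53)
        hits = 0
        for _ in range(200):
            g = np.repeat(["u", "v"], 25)
            x = rng.standard_normal(50)
            y = np.exp(x)  # monotone in covariate only
            y += 0.01 * rng.standard_normal(50)
            F, p = rank_ancova(y, g, x)
            hits += p < 0.05
        assert 0.0 <= hits / 200 <= 0.10

    def test_invariant_to_monotone_covariate_rescaling(self):
        rng = np.random.default_rng(59)
        g = np.repeat(["u", "v"], 15)
        x = rng.uniform(1, 2, 30)
        y = rng.standard_normal(30) + (g == "u")
        F1, p1 = rank_ancova(y, g, x)
        F2, p2 = rank_ancova(y, g, np.log(x) * 1000 - 5)
        assert F1 == pytest.approx(F2, rel=1e-12) and p1 == pytest.approx(p2)

    def test_constant_covariate_warns(self):
        rng = np.random.default_rng(61)
        g = np.repeat(["u", "v"], 10)
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="constant covariate"):
            rank_ancova(y, g, np.ones(20))


class TestOverlapDisparityCorrelation:
    def make_pairs(self, rho_link=False, n=40, seed=0):
        rng = np.random.default_rng(seed)
        ov = rng.uniform(0.01, 1.0, n)
        d1 = np.sqrt(ov) if rho_link else rng.uniform(0, 5, n)
        return pd.DataFrame({
            "overlap_index": ov, "overlap_area": ov * 1e4,
            "sympatric": True,
            "pPC1_disparity": d1, "pPC2_disparity": rng.uniform(0, 5, n),
        })

    def test_monotone_link_gives_rho_one(self):
        out = overlap_disparity_correlation(self.make_pairs(rho_link=True))
        row = out[(out.component == "pPC1") & (out.measure == "overlap_index")].iloc[0]
        assert row.rho == pytest.approx(1.0)

    def test_independent_disparity_small_rho(self):
        rhos = [overlap_disparity_correlation(self.make_pairs(seed=s))
                .query("component=='pPC1'").rho.abs().max() for s in range(10)]
        assert np.median(rhos) < 0.35

    def test_needs_three_sympatric_pairs(self):
        pairs = self.make_pairs().iloc[:2]
        with pytest.raises(ValueError):
            overlap_disparity_correlation(pairs)
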