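"""Permutation tests on scores and the trait-range resampling loop."""

import numpy as np
import pandas as pd
import pytest

from campion.resampling import (all_pairwise_color_tests,
                                permute_group_statistic,
                                resample_trait_ranges,
                                resampled_ppca_summary, RESAMPLED_TRAITS)
from campion.trait_data import TraitRange, TraitTable


def series(vals, prefix="s"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestPermutationTest:
    def test_exhaustive_enumeration_oracle(self):
        scores = series([0.0, 0.0, -1.0, 1.0])
        colors = series(["A", "A", "B", "B"])
        res = permute_group_statistic(scores, colors, ("A", "B"),
                                      "variance_ratio", sided="less")
        assert res.exhaustive
        assert res.observed == 0.0
        # 6 distinct relabelings; only the observed one has var(A) = 0
        assert res.p_value == pytest.approx(1 / 6)
        assert len(res.null_distribution) == 6

    def test_identical_groups_mean_difference_null(self):
        scores = series([1.0, 2.0, 1.0, 2.0])
        colors = series(["A", "A", "B", "B"])
        res = permute_group_statistic(scores, colors, ("A", "B"),
                                      "mean_difference")
        assert res.observed == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_sampled_p_agrees_with_exhaustive(self):
        rng = np.random.default_rng(3)
        scores = series(rng.standard_normal(9))
        colors = series(["A"] * 4 + ["B"] * 5)
        exact = permute_group_statistic(scores, colors, ("A", "B"),
                                        "variance_ratio", sided="less")
        assert exact.exhaustive
        # force sampling by a temporarily tiny exhaustive limit
        import campion.resampling as rs
        old = rs.EXHAUSTIVE_LIMIT
        rs.EXHAUSTIVE_LIMIT = 1
        try:
            approx = permute_group_statistic(scores, colors, ("A", "B"),
                                             "variance_ratio", sided="less",
                                             n_perm=4000, seed=11)
        finally:
            rs.EXHAUSTIVE_LIMIT = old
        tol = 2 * np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert abs(approx.p_value - exact.p_value) <= tol + 1e-12

    def test_relabeling_preserves_group_sizes(self):
        rng = np.random.default_rng(5)
        scores = series(rng.standard_normal(12))
        colors = series(["A"] * 5 + ["B"] * 4 + ["C"] * 3)
        res = permute_group_statistic(scores, colors, ("A", "B"),
                                      "mean_difference", n_perm=50, seed=1)
        # null values exist and are finite: every relabeling kept 5 A's, 4 B's
        assert np.isfinite(res.null_distribution).all()

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_runs = 300
        for i in range(n_runs):
            scores = series(rng.standard_normal(20))
            colors = series(["A"] * 10 + ["B"] * 10)
            res = permute_group_statistic(scores, colors, ("A", "B"),
                                          "variance_ratio", sided="less",
                                          n_perm=199, seed=i)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_runs <= 0.10

    def test_degenerate_observed_denominator_errors(self):
        scores = series([1.0, 2.0, 3.0, 3.0])
        colors = series(["A", "A", "B", "B"])
        with pytest.raises(ZeroDivisionError):
            permute_group_statistic(scores, colors, ("A", "B"), "variance_ratio")

    def test_single_member_group_rejected(self):
        scores = series([1.0, 2.0, 3.0])
        colors = series(["A", "B", "B"])
        with pytest.raises(ValueError, match="< 2 members"):
            permute_group_statistic(scores, colors, ("A", "B"), "variance_ratio")


class TestAllPairwise:
    def test_table_combinatorics(self, study_ppca, study):
        colors = study["table"].colors.loc[study_ppca.scores.index]
        out = all_pairwise_color_tests(study_ppca, colors, n_perm=60, seed=0)
        assert len(out) == 3 * 2 * 2  # pairs x components x statistics
        assert set(out.statistic) == {"variance_ratio", "mean_difference"}
        # red is always the leading member of its pairs
        red_rows = out[(out.group_a == "red") | (out.group_b == "red")]
        assert (red_rows.group_a == "red").all()

    def test_random_colors_show_no_signal(self, study_ppca):
        rng = np.random.default_rng(13)
        hits = 0
        for i in range(20):
            colors = pd.Series(rng.permutation(["white"] * 20 + ["pink"] * 14
                                               + ["red"] * 9),
                               index=study_ppca.scores.index)
            out = all_pairwise_color_tests(study_ppca, colors, n_perm=99,
                                           seed=i)
            sub = out[out.statistic == "variance_ratio"]
            hits += (sub.p_value < 0.05).sum()
        # 20 runs x 6 variance tests at alpha .05 -> ~6 expected under null
        assert hits <= 18


class TestRangeResampling:
    def test_draws_stay_inside_ranges(self, study):
        table = study["table"]
        for X in resample_trait_ranges(table, n_datasets=5, seed=0):
            for t in RESAMPLED_TRAITS:
                r = table.ranges(t)
                assert (X[t].to_numpy() >= r["min"].to_numpy() - 1e-12).all()
                assert (X[t].to_numpy() <= r["max"].to_numpy() + 1e-12).all()

    def test_non_resampled_columns_untouched(self, study):
        table = study["table"]
        base = table.encoded_matrix()
        fixed = [c for c in base.columns if c not in RESAMPLED_TRAITS]
        for X in resample_trait_ranges(table, n_datasets=3, seed=1):
            pd.testing.assert_frame_equal(X[fixed], base[fixed])

    def test_degenerate_and_moment_checks(self):
        from campion.trait_data import CONTINUOUS_TRAITS, SpeciesRecord
        recs = []
        for i in range(4):
            traits = {t: TraitRange(7.0, 7.0, 7.0) for t in CONTINUOUS_TRAITS}
            traits["calyx_height"] = TraitRange(2.0, 5.0, 10.0)
            recs.append(SpeciesRecord(
                species_id=f"s{i}", traits=traits, inflorescence_class="few",
                tube_extension="equal", organ_exsertion="above",
                color="white", ploidy="diploid"))
        table = TraitTable(records=recs)
        draws = np.array([X["calyx_height"].to_numpy()
                          for X in resample_trait_ranges(table, n_datasets=4000,
                                                         seed=3)])
        widths = np.array([X["calyx_width"].to_numpy()
                           for X in resample_trait_ranges(table, n_datasets=50,
                                                          seed=3)])
        assert (widths == 7.0).all()  # zero-width range: every draw equals it
        se = np.sqrt((10.0 - 2.0) ** 2 / 12 / 4000)
        assert abs(draws.mean() - 6.0) <= 3 * se

    def test_resampled_summary_deterministic_and_detects_contrast(self, study):
        table, tree = study["table"], study["tree"]
        s1 = resampled_ppca_summary(table, tree, n_datasets=30, seed=5)
        s2 = resampled_ppca_summary(table, tree, n_datasets=30, seed=5)
        pd.testing.assert_frame_equal(s1.summary, s2.summary)
        per = s1.per_dataset
        wide = per[per.component == "pPC1"].pivot(index="dataset",
                                                  columns="group",
                                                  values="variance")
        frac = ((wide["red"] < wide["white"]) & (wide["red"] < wide["pink"])).mean()
        assert frac >= 0.95

    def test_zero_width_ranges_make_identical_datasets(self):
        from campion.trait_data import CONTINUOUS_TRAITS, SpeciesRecord
        recs = [SpeciesRecord(
            species_id=f"s{i}",
            traits={t: TraitRange(float(i + j + 1), float(i + j + 1), float(i + j + 1))
                    for j, t in enumerate(CONTINUOUS_TRAITS)},
            inflorescence_class="few", tube_extension="equal",
            organ_exsertion="above", color="white", ploidy="diploid")
            for i in range(5)]
        table = TraitTable(records=recs)
        mats = [X for X in resample_trait_ranges(table, n_datasets=4, seed=9)]
        for X in mats[1:]:
            pd.testing.assert_frame_equal(X, mats[0])
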