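import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from breedrisk.expression import (
    ase_test,
    compute_tpm,
    differential_expression,
    individual_zscore,
    median_of_ratios,
    ranksum_test,
    variance_stabilize,
)


def _nb_counts(rng, mu, n_samples, dispersion=0.1):
    nn = 1.0 / dispersion
    return rng.negative_binomial(nn, nn / (nn + mu[:, None]), size=(len(mu), n_samples))


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        counts = pd.DataFrame(np.full((4, 3), 7), index=list("abcd"))
        lengths = pd.Series([100] * 4, index=list("abcd"))
        tpm = compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.to_numpy(), 1e6 / 4)

    def test_doubling_length_halves_rate(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        tpm1 = compute_tpm(counts, pd.Series([100, 100], index=["a", "b"]))
        tpm2 = compute_tpm(counts, pd.Series([100, 200], index=["a", "b"]))
        # b's pre-normalisation rate halves, so its TPM share drops
        assert tpm2.loc["b", "s"] == pytest.approx(tpm1.loc["b", "s"] * (1 / 2) / (3 / 4))

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 6)))
        counts.iloc[0] += 1  # avoid all-zero columns
        lengths = pd.Series(rng.integers(200, 5000, size=50), index=counts.index)
        tpm = compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError, match="positive"):
            compute_tpm(counts, pd.Series([0], index=["a"]))


class TestDifferentialExpression:
    def test_spike_gene_recovered(self):
        rng = np.random.default_rng(5)
        mu = rng.lognormal(np.log(200), 1.2, size=2000)
        counts = _nb_counts(rng, mu, 12)
        nn = 1.0 / 0.1
        spiked = mu[0] * 10.9
        counts[0, 6:] = rng.negative_binomial(nn, nn / (nn + spiked), size=6)
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(2000)])
        res = differential_expression(df, ["a"] * 6 + ["b"] * 6)
        row = res.loc["g0"]
        assert row["significant"]
        assert row["log2FoldChange"] == pytest.approx(np.log2(10.9), abs=0.5)

    def test_null_groups_calibrated(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(np.log(200), 1.2, size=2000)
        counts = pd.DataFrame(_nb_counts(rng, mu, 12))
        res = differential_expression(counts, ["a"] * 6 + ["b"] * 6)
        frac = (res["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08
        assert res["log2FoldChange"].abs().median() < 0.35
        ks = sps.kstest(res["p"].dropna(), "uniform").statistic
        assert ks < 0.05

    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 100, size=(5, 6)))
        counts.iloc[2] = 0
        res = differential_expression(counts, ["a"] * 3 + ["b"] * 3)
        assert not res["tested"].iloc[2]
        assert np.isnan(res["p"].iloc[2])

    def test_small_group_rejected(self):
        counts = pd.DataFrame(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(counts, ["a", "a", "b"])

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(np.log(100), 1.0, size=300)
        counts = pd.DataFrame(_nb_counts(rng, mu, 8))
        res = differential_expression(counts, ["a"] * 4 + ["b"] * 4).dropna(subset=["p"])
        assert (res["padj"] >= res["p"] - 1e-12).all()
        s = res.sort_values("p")
        assert (np.diff(s["padj"]) >= -1e-12).all()


class TestIndividualZscore:
    def test_hand_computed_example(self):
        vst = pd.DataFrame(
            {"c1": [10.0], "c2": [12.0], "c3": [14.0], "q": [18.0]}, index=["g"]
        )
        res = individual_zscore(vst, ["c1", "c2", "c3"], "q")
        assert res.loc["g", "z"] == pytest.approx(3.0)  # sd is n-1 based
        assert res.loc["g", "significant"]

    def test_query_at_control_mean_is_zero(self):
        vst = pd.DataFrame(
            {"c1": [1.0], "c2": [2.0], "c3": [3.0], "q": [2.0]}, index=["g"]
        )
        assert individual_zscore(vst, ["c1", "c2", "c3"], "q").loc["g", "z"] == 0.0

    def test_constant_gene_flagged_undefined(self):
        vst = pd.DataFrame(
            {"c1": [5.0], "c2": [5.0], "c3": [5.0], "q": [9.0]}, index=["g"]
        )
        res = individual_zscore(vst, ["c1", "c2", "c3"], "q")
        assert res.loc["g", "undefined"]
        assert np.isnan(res.loc["g", "z"])

    def test_query_in_controls_rejected(self):
        vst = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="must not be in"):
            individual_zscore(vst, ["a", "b", "c"], "c")

    def test_leave_one_out_control_scores_standard_normal_like(self):
        rng = np.random.default_rng(9)
        n_ctrl = 12
        vst = pd.DataFrame(
            rng.normal(8, 1.5, size=(400, n_ctrl)),
            columns=[f"c{i}" for i in range(n_ctrl)],
        )
        zs = []
        for q in vst.columns:
            others = [c for c in vst.columns if c != q]
            zs.append(individual_zscore(vst, others, q)["z"])
        z = pd.concat(zs)
        assert abs(z.mean()) < 0.2
        assert 0.7 <= z.std() <= 1.3


class TestAse:
    def test_balanced_counts_not_significant(self):
        rec = pd.DataFrame(
            {"variant": ["v"], "sample": ["s"], "ref_count": [50], "alt_count": [50]}
        )
        res, _ = ase_test(rec)
        assert res["chi2"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_hand_computed_chi_square(self):
        rec = pd.DataFrame(
            {"variant": ["v"], "sample": ["s"], "ref_count": [30], "alt_count": [10]}
        )
        res, _ = ase_test(rec)
        assert res["chi2"].iloc[0] == pytest.approx(10.0)
        assert res["p"].iloc[0] == pytest.approx(0.001565, abs=2e-6)

    def test_recurrence_rule(self):
        rec = pd.DataFrame(
            {
                "variant": ["v"] * 7,
                "sample": [f"s{i}" for i in range(7)],
                "ref_count": [35] + [25] * 6,
                "alt_count": [10] + [25] * 6,
            }
        )
        _, summary = ase_test(rec)
        assert not summary.loc["v", "prioritized"]  # significant in only 1 of 7
        rec2 = rec.copy()
        rec2.loc[1, ["ref_count", "alt_count"]] = [40, 12]
        _, summary2 = ase_test(rec2)
        assert summary2.loc["v", "prioritized"]

    def test_zero_depth_skipped_with_warning(self):
        rec = pd.DataFrame(
            {
                "variant": ["v", "v"],
                "sample": ["a", "b"],
                "ref_count": [0, 30],
                "alt_count": [0, 10],
            }
        )
        with pytest.warns(UserWarning, match="zero-depth"):
            res, _ = ase_test(rec)
        assert len(res) == 1

    def test_low_depth_untested(self):
        rec = pd.DataFrame(
            {"variant": ["v"], "sample": ["s"], "ref_count": [4], "alt_count": [1]}
        )
        res, summary = ase_test(rec, min_depth=10)
        assert not res["tested"].iloc[0]
        assert summary.loc["v", "n_tested"] == 0

    def test_chi_square_approximates_exact_binomial_at_depth(self):
        # large-sample agreement between the chi-square and the exact
        # two-sided binomial (relative error shrinks with depth; these
        # depths/imbalances sit inside the asymptotic regime)
        for ref, alt in [(55, 45), (110, 90), (120, 80), (275, 225)]:
            rec = pd.DataFrame(
                {"variant": ["v"], "sample": ["s"], "ref_count": [ref], "alt_count": [alt]}
            )
            res, _ = ase_test(rec)
            p_exact = sps.binomtest(ref, ref + alt, 0.5).pvalue
            assert res["p"].iloc[0] == pytest.approx(p_exact, rel=0.2)


class TestRanksum:
    def test_complete_separation_4_vs_7(self):
        p = ranksum_test([1, 2, 3, 4], [5, 6, 7, 8, 9, 10, 11])
        assert p == pytest.approx(2 / 330)

    def test_identical_samples_p_one(self):
        assert ranksum_test([3.0, 3.0, 3.0], [3.0, 3.0]) == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=6)
        b = rng.normal(0.5, 1, size=8)
        p1 = ranksum_test(a, b)
        p2 = ranksum_test(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 9))
        b = rng.normal(0.3, 1, size=rng.integers(3, 9))
        ours = ranksum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=30)
        b = rng.normal(1.0, 1, size=30)
        ours = ranksum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ranksum_test([], [1.0])


class TestSizeFactorsAndVst:
    def test_size_factors_track_depth(self):
        rng = np.random.default_rng(13)
        base = rng.lognormal(np.log(100), 1, size=500)
        counts = pd.DataFrame(
            {
                "s1": rng.poisson(base),
                "s2": rng.poisson(base * 2.0),  # double depth
            }
        )
        sf = median_of_ratios(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0, rel=0.1)

    def test_vst_is_monotone_in_counts(self):
        counts = pd.DataFrame({"s": [0, 1, 10, 100]})
        v = variance_stabilize(counts, pd.Series({"s": 1.0}))
        assert (np.diff(v["s"]) > 0).all()
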