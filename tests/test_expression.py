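import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossbind.expression import (
    center_by_study,
    class_divergence_stats,
    extreme_tail_enrichment,
    normalize_and_center,
    normalize_counts,
    ratio_vs_count_difference,
    size_factors,
    welch_divergence,
    zero_center,
)
from _oracles import welch_bruteforce


def counts_frame(mat, samples=None):
    mat = np.asarray(mat)
    samples = samples or [f"s{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(mat.shape[0])],
                        columns=samples)


class TestNormalization:
    def test_identical_samples_have_unit_size_factors(self):
        df = counts_frame([[10, 10], [200, 200], [3, 3]])
        assert size_factors(df).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_gets_factor_two(self):
        df = counts_frame([[10, 20], [200, 400], [30, 60]])
        sf = size_factors(df)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)
        norm = normalize_counts(df)
        assert np.allclose(norm["s0"], norm["s1"])

    def test_planted_batch_shift_removed(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(2, 10, size=(50, 6))
        log_expr = counts_frame(base)
        studies = pd.Series(
            ["u", "u", "v", "v", "w", "w"], index=log_expr.columns
        )
        shifted = log_expr.copy()
        shifted[["s2", "s3"]] += 2.0  # +2 log2 units on study v
        centred = center_by_study(shifted, studies)
        # after centering, every study's per-gene mean equals the gene mean:
        # the planted cross-study shift is gone to numerical precision
        means = centred.T.groupby(studies).mean().T
        assert np.allclose(means.to_numpy() - means.mean(axis=1).to_numpy()[:, None],
                           0.0, atol=1e-9)

    def test_single_sample_study_skipped(self, caplog):
        log_expr = counts_frame(np.ones((5, 3)))
        studies = pd.Series(["u", "u", "v"], index=log_expr.columns)
        out = center_by_study(log_expr, studies)
        assert np.allclose(out.to_numpy(), 1.0)

    def test_zero_center_grand_mean(self):
        rng = np.random.default_rng(1)
        df = counts_frame(rng.uniform(0, 12, size=(40, 6)))
        assert abs(zero_center(df).to_numpy().mean()) < 1e-9

    def test_full_pipeline_species_grand_means_are_zero(self):
        rng = np.random.default_rng(2)
        counts_a = counts_frame(rng.poisson(100, size=(60, 6)))
        counts_b = counts_frame(rng.poisson(80, size=(60, 4)))
        meta_a = pd.DataFrame({"sample": counts_a.columns,
                               "study": ["u", "u", "v", "v", "w", "w"]})
        meta_b = pd.DataFrame({"sample": counts_b.columns,
                               "study": ["x", "x", "y", "y"]})
        log_a, log_b = normalize_and_center(counts_a, meta_a, counts_b, meta_b)
        assert abs(log_a.to_numpy().mean()) < 1e-9
        assert abs(log_b.to_numpy().mean()) < 1e-9


class TestWelch:
    def test_frozen_closed_form_example(self):
        res = welch_divergence([1, 2, 3], [2, 4, 6])
        assert res.t == pytest.approx(-1.549, abs=5e-4)
        assert res.df == pytest.approx(2.941, abs=5e-4)

    def test_matches_closed_form_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            res = welch_divergence(a, b)
            t, df = welch_bruteforce(a, b)
            assert res.t == pytest.approx(t)
            assert res.df == pytest.approx(df)
            scipy_res = stats.ttest_ind(a, b, equal_var=False)
            assert res.p == pytest.approx(scipy_res.pvalue)

    def test_identical_vectors(self):
        res = welch_divergence([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.log2_ratio == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetric_in_species_order(self):
        r1 = welch_divergence([1, 2, 3], [5, 6, 9])
        r2 = welch_divergence([5, 6, 9], [1, 2, 3])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.log2_ratio == pytest.approx(-r2.log2_ratio)

    def test_degenerate_zero_variance(self):
        assert welch_divergence([2, 2], [2, 2]).p == 1.0
        assert welch_divergence([3, 3], [2, 2]).p < 1e-300

    def test_null_calibration_false_positive_rate(self):
        # 200 simulated null matrices of 50 genes: p < 0.05 in 5% +/- 1%
        # (8 studies per species; at very small df Welch is conservative)
        rng = np.random.default_rng(99)
        hits = total = 0
        for _ in range(200):
            a = rng.normal(size=(50, 8))
            b = rng.normal(size=(50, 8))
            for g in range(50):
                total += 1
                hits += welch_divergence(a[g], b[g]).p < 0.05
        assert hits / total == pytest.approx(0.05, abs=0.01)


class TestClassStats:
    def test_identical_classes_f_is_one(self):
        vals = np.r_[np.arange(10.0), np.arange(10.0)]
        df = pd.DataFrame({
            "gene_class": ["conserved"] * 10 + ["alternative"] * 10,
            "log2_ratio": vals,
        })
        out = class_divergence_stats(df).set_index("gene_class")
        assert out.loc["alternative", "f_vs_ref"] == pytest.approx(1.0)
        assert out.loc["alternative", "p_f_vs_ref"] == pytest.approx(1.0)

    def test_small_class_gets_missing_stats(self):
        df = pd.DataFrame({
            "gene_class": ["conserved"] * 5 + ["a_specific"],
            "log2_ratio": [0.0, 1.0, -1.0, 0.5, -0.5, 3.0],
        })
        out = class_divergence_stats(df).set_index("gene_class")
        assert np.isnan(out.loc["a_specific", "sd"])
        assert np.isnan(out.loc["a_specific", "p_vs_ref"])

    def test_shifted_class_detected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "gene_class": ["conserved"] * 100 + ["a_specific"] * 50,
            "log2_ratio": np.r_[rng.normal(0, 1, 100), rng.normal(2, 1, 50)],
        })
        out = class_divergence_stats(df).set_index("gene_class")
        assert out.loc["a_specific", "p_vs_ref"] < 1e-6
        assert out.loc["a_specific", "mean"] == pytest.approx(2.0, abs=0.5)


class TestTailEnrichment:
    def test_planted_tail_enrichment_detected(self):
        rng = np.random.default_rng(4)
        records = pd.DataFrame({
            "gene_class": ["a_specific"] * 40 + ["conserved"] * 400,
            "log2_ratio": np.r_[rng.normal(5, 2, 40), rng.normal(0, 1.5, 400)],
        })
        out = extreme_tail_enrichment(records, cutoff=3.0)
        high = out.set_index("tail").loc["high"]
        assert high["p"] < 0.01
        assert high["tail_proportion"] > 0.5

    def test_matches_hand_chi_square(self):
        records = pd.DataFrame({
            "gene_class": (["a_specific"] * 49 + ["conserved"] * 551),
            "log2_ratio": np.r_[
                np.full(26, 9.0), np.full(23, 0.0),
                np.full(23, 9.0), np.full(528, 0.0),
            ],
        })
        out = extreme_tail_enrichment(records, cutoff=5.0)
        high = out.set_index("tail").loc["high"]
        table = np.array([[26, 23], [23, 528]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert high["chi2"] == pytest.approx(chi2)
        assert high["p"] == pytest.approx(p)

    def test_empty_tail_yields_missing_p(self):
        records = pd.DataFrame({
            "gene_class": ["conserved"] * 10,
            "log2_ratio": np.zeros(10),
        })
        out = extreme_tail_enrichment(records, cutoff=5.0)
        assert out["p"].isna().all()

    def test_null_p_uniform_over_seeds(self):
        # no class-tail association: p-values roughly uniform
        pvals = []
        rng = np.random.default_rng(5)
        for _ in range(100):
            records = pd.DataFrame({
                "gene_class": rng.permutation(
                    ["a_specific"] * 50 + ["conserved"] * 450
                ),
                "log2_ratio": rng.normal(0, 2.2, 500),
            })
            out = extreme_tail_enrichment(records, cutoff=3.0)
            p = out.set_index("tail").loc["high", "p"]
            if np.isfinite(p):
                pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestRegression:
    def test_noiseless_slope_recovered_exactly(self):
        dn = np.r_[np.arange(-5, 6)]
        df = pd.DataFrame({"dn": dn, "log2_ratio": 0.5 * dn})
        res = ratio_vs_count_difference(df)
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_dn_rejected(self):
        df = pd.DataFrame({"dn": np.zeros(10), "log2_ratio": np.arange(10.0)})
        with pytest.raises(ValueError):
            ratio_vs_count_difference(df)

    def test_slope_in_ci_for_planted_effect(self):
        rng = np.random.default_rng(6)
        dn = rng.integers(-5, 6, 300)
        df = pd.DataFrame({
            "dn": dn,
            "log2_ratio": 0.8 * dn + rng.normal(0, 1.5, 300),
        })
        res = ratio_vs_count_difference(df)
        assert abs(res.slope - 0.8) < 3 * res.stderr
        assert res.p_slope < 1e-10
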