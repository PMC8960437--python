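import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossbind.intervals import GenomicInterval, central_window
from crossbind.te import (
    TEClass,
    TEFeature,
    TEIndex,
    chisq_independence,
    class_by_teclass_table,
    distance_bins,
    overlap_table,
    permutation_chisq,
    read_te_bed,
    te_overlap_flag,
    tss_distance_tests,
)
from _oracles import kruskal_h_bruteforce, pearson_chi2_bruteforce, te_enclosure_bruteforce


def te(start, end, cls=TEClass.LINE1, chrom="chr1", name="te"):
    return TEFeature(GenomicInterval(chrom, start, end), cls, name)


def site(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestEnclosure:
    def test_fully_enclosing_te(self):
        idx = TEIndex([te(1050, 1150)])
        assert te_overlap_flag(site(1000, 1200), idx) is True

    def test_one_bp_short_fails(self):
        idx = TEIndex([te(1080, 1119)])
        assert te_overlap_flag(site(1000, 1200), idx) is False

    def test_two_adjacent_tes_do_not_jointly_enclose(self):
        idx = TEIndex([te(1050, 1100), te(1100, 1150)])
        assert te_overlap_flag(site(1000, 1200), idx) is False

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        tes = [
            te(int(s), int(s) + int(rng.integers(10, 120)))
            for s in rng.integers(0, 5000, size=150)
        ]
        idx = TEIndex(tes)
        for _ in range(1000):
            s = int(rng.integers(20, 4800))
            candidate = site(s, s + int(rng.integers(40, 200)))
            window = central_window(candidate, 40)
            assert te_overlap_flag(candidate, idx) == te_enclosure_bruteforce(
                window, tes
            )

    def test_longest_enclosing_te_wins(self):
        idx = TEIndex([
            te(1000, 1200, TEClass.SINE, name="short"),
            te(900, 1400, TEClass.LINE1, name="long"),
        ])
        feat = idx.enclosing(site(1080, 1120))
        assert feat.name == "long"


def test_read_te_bed_class_suffix():
    text = "chr1\t10\t500\tL1MdA#LINE1\t0\t+\nchr1\t600\t700\tAluY#SINE\nchr2\t0\t99\tfoo#weird\n"
    feats = read_te_bed(io.StringIO(text))
    assert [f.te_class for f in feats] == [TEClass.LINE1, TEClass.SINE, TEClass.OTHER]


class TestChiSquare:
    def test_frozen_r_example(self):
        # chisq.test(matrix(c(10,30,20,40),2,2), correct=FALSE): statistic,
        # p-value, and $residuals (the Pearson (O-E)/sqrt(E) residuals)
        res = chisq_independence(np.array([[10, 20], [30, 40]]))
        assert res.chi2 == pytest.approx(0.793651, abs=1e-6)
        assert res.p_analytic == pytest.approx(0.372998, abs=1e-6)
        assert res.std_residuals.iloc[0, 0] == pytest.approx(-0.57735027, abs=1e-7)
        assert res.std_residuals.iloc[0, 1] == pytest.approx(0.47140452, abs=1e-7)

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(50):
            table = rng.integers(1, 60, size=(rng.integers(2, 5), rng.integers(2, 4)))
            res = chisq_independence(table)
            chi2, expected, resid = pearson_chi2_bruteforce(table)
            assert res.chi2 == pytest.approx(chi2)
            assert np.allclose(res.expected.to_numpy(), expected)
            assert np.allclose(res.std_residuals.to_numpy(), resid)
            assert res.observed.to_numpy().sum() == pytest.approx(
                res.expected.to_numpy().sum()
            )

    def test_observed_equals_expected_gives_zero(self):
        res = chisq_independence(np.array([[10, 20], [20, 40]]))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.std_residuals.to_numpy(), 0.0, atol=1e-9)

    def test_residual_sign_above_expectation_positive(self):
        res = chisq_independence(np.array([[30, 10], [10, 30]]))
        assert res.std_residuals.iloc[0, 0] > 0
        assert res.std_residuals.iloc[0, 1] < 0

    def test_relative_residual_variant(self):
        obs = np.array([[10, 20], [30, 40]])
        res = chisq_independence(obs, residuals="relative")
        expected = pearson_chi2_bruteforce(obs)[1]
        assert np.allclose(
            res.std_residuals.to_numpy(), (obs - expected) / expected
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_independence(np.array([[0, 0], [5, 5]]))


class TestPermutation:
    def test_exact_enumeration_on_toy(self):
        """One TE-overlapping site among two classes of three.

        By symmetry every flag placement gives the same chi-square, so
        the exact permutation p is 1; the add-one estimate agrees."""
        classes = ["cons"] * 3 + ["spec"] * 3
        flags = [True, False, False, False, False, False]
        res = permutation_chisq(classes, flags, n_permutations=400, seed=0)
        chi2s = []
        for positions in itertools.combinations(range(6), 1):
            f = np.zeros(6, bool)
            f[list(positions)] = True
            tab = overlap_table(classes, f)
            chi2s.append(pearson_chi2_bruteforce(tab.to_numpy())[0])
        exact_p = np.mean(np.array(chi2s) >= res.observed_chi2 - 1e-12)
        assert exact_p == 1.0
        assert res.p_empirical == pytest.approx(1.0)

    def test_asymmetric_toy_matches_enumeration(self):
        classes = ["cons"] * 2 + ["spec"] * 4
        flags = np.array([True, True, False, False, False, False])
        chi2s = []
        for positions in itertools.combinations(range(6), 2):
            f = np.zeros(6, bool)
            f[list(positions)] = True
            tab = overlap_table(classes, f)
            chi2s.append(pearson_chi2_bruteforce(tab.to_numpy())[0])
        res = permutation_chisq(classes, flags, n_permutations=20_000, seed=1)
        exact_p = np.mean(np.array(chi2s) >= res.observed_chi2 - 1e-12)
        # add-one empirical estimate converges to the enumerated value
        assert res.p_empirical == pytest.approx(exact_p, abs=0.01)

    def test_same_seed_is_deterministic(self, rng):
        classes = rng.choice(["a", "b"], size=80)
        flags = rng.random(80) < 0.3
        r1 = permutation_chisq(classes, flags, 500, seed=9)
        r2 = permutation_chisq(classes, flags, 500, seed=9)
        assert r1 == r2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_chisq(["a"] * 5, [True] * 5, 10, seed=0)

    def test_agrees_with_analytic_p_on_large_table(self):
        # large, well-filled table: the chi-square approximation error is
        # below the Monte-Carlo resolution
        rng = np.random.default_rng(1)
        classes = np.r_[["cons"] * 2000, ["spec"] * 1500]
        flags = np.r_[rng.random(2000) < 0.25, rng.random(1500) < 0.30]
        tab = overlap_table(classes, flags)
        analytic = chisq_independence(tab)
        res = permutation_chisq(classes, flags, 10_000, seed=3)
        assert res.observed_chi2 == pytest.approx(analytic.chi2)
        mc_se = np.sqrt(analytic.p_analytic * (1 - analytic.p_analytic) / 10_000)
        assert abs(res.p_empirical - analytic.p_analytic) < 3 * mc_se + 1e-4


class TestClassByTEClass:
    def test_marginals_conserved(self):
        att = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(6)],
            "te_overlap": [True, True, False, True, False, False],
            "te_class": ["LINE1", "SINE", "none", "LINE1", "none", "none"],
        })
        classes = pd.Series(
            ["cons", "cons", "cons", "spec", "spec", "spec"],
            index=att["site_id"],
        )
        res = class_by_teclass_table(classes, att)
        assert res.observed.to_numpy().sum() == 6
        assert res.observed.loc["cons"].sum() == 3

    def test_planted_line1_excess_gives_positive_residual(self, rng):
        n = 300
        classes = pd.Series(
            ["spec" if i < 150 else "cons" for i in range(n)],
            index=[f"s{i}" for i in range(n)],
        )
        te_class = ["LINE1" if (i < 60) else "none" for i in range(150)] + [
            "LINE1" if i < 5 else "none" for i in range(150)
        ]
        att = pd.DataFrame({
            "site_id": classes.index,
            "te_overlap": [c != "none" for c in te_class],
            "te_class": te_class,
        })
        res = class_by_teclass_table(classes, att)
        assert res.std_residuals.loc["spec", "LINE1"] > 2


class TestTssDistances:
    def test_h_matches_rank_closed_form(self):
        groups = {
            "a": [1.0, 5.0, 9.0, 12.0],
            "b": [2.0, 6.0, 10.0],
            "c": [3.0, 7.0, 11.0, 15.0, 20.0],
        }
        out = tss_distance_tests(groups)
        h = kruskal_h_bruteforce([np.abs(np.array(v)) for v in groups.values()])
        assert out["H"] == pytest.approx(h)
        scipy_h, scipy_p = stats.kruskal(*[np.abs(np.array(v)) for v in groups.values()])
        assert out["H"] == pytest.approx(scipy_h)
        assert out["p"] == pytest.approx(scipy_p)

    def test_identical_groups_give_tiny_h(self, rng):
        base = rng.normal(0, 10_000, 200)
        out = tss_distance_tests({"a": base.tolist(), "b": base.tolist()})
        assert out["p"] > 0.9

    def test_shifted_group_detected(self, rng):
        near = rng.normal(0, 5_000, 200)
        far = near + np.sign(near + 1e-9) * 50_000
        out = tss_distance_tests({"near": near.tolist(), "far": far.tolist()})
        assert out["p"] < 0.01

    def test_empty_group_dropped(self):
        out = tss_distance_tests({"a": [1.0, 2.0], "b": [2.0, 3.0], "c": []})
        assert "c" not in out["groups"]
        with pytest.raises(ValueError):
            tss_distance_tests({"a": [1.0], "b": []})

    def test_distance_bins_signed(self):
        tab = distance_bins([-150_000, -5_000, -500, 500, 5_000, 50_000, 500_000])
        counts = dict(zip(tab["bin"], tab["count"]))
        assert counts["<-100kb"] == 1
        assert counts["-10kb..-1kb"] == 1
        assert counts["0..1kb"] == 1
        assert counts[">100kb"] == 1
        assert tab["count"].sum() == 7
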