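import math

import numpy as np
import pytest

from crossbind.motifs import (
    PWM,
    ScanEngine,
    benjamini_hochberg,
    bundled_tbox_pwm,
    estimate_background,
    exact_score_pvalues,
    known_motif_enrichment,
    motif_proportion,
    normalize_enrichment_matrix,
    prop_test_ci,
    scan_sites,
    _int_scores,
)
from _oracles import (
    benjamini_hochberg_bruteforce,
    hypergeom_tail_bruteforce,
    pwm_score_distribution_bruteforce,
)

RC = str.maketrans("ACGT", "TGCA")


def random_pwm(rng, w, sharp=1.0):
    mat = rng.dirichlet([sharp] * 4, size=w).T
    return PWM(f"rnd{w}", mat)


class TestPWMParsing:
    def test_bundled_matrix(self):
        pwm = bundled_tbox_pwm()
        assert pwm.width == 10
        assert np.allclose(pwm.probs.sum(axis=0), 1.0)
        assert len(pwm.consensus) == 10

    def test_meme_minimal(self):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF toy\n"
            "letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0\n"
            "0.97 0.01 0.01 0.01\n0.01 0.97 0.01 0.01\n"
            "0.01 0.01 0.97 0.01\n0.01 0.01 0.01 0.97\n"
        )
        (pwm,) = PWM.list_from_meme(text)
        assert pwm.consensus == "ACGT"

    def test_reverse_complement(self):
        pwm = bundled_tbox_pwm()
        rc = pwm.reverse_complement()
        assert rc.consensus == pwm.consensus[::-1].translate(RC)

    def test_zero_background_with_support_rejected(self):
        pwm = PWM("x", np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            exact_score_pvalues(pwm, np.array([0.5, 0.5, 0.0, 0.0]))


class TestExactScoreDistribution:
    @pytest.mark.parametrize("w", [4, 5, 6, 7, 8])
    def test_dp_matches_exhaustive_enumeration(self, w, rng):
        bg = rng.dirichlet([5, 5, 5, 5])
        pwm = random_pwm(rng, w, sharp=0.6)
        dist = exact_score_pvalues(pwm, bg)
        iscore = _int_scores(pwm.log_odds(bg), dist.bin_bits)
        brute, dead = pwm_score_distribution_bruteforce(iscore, bg)
        assert dist.dead_mass == pytest.approx(dead, abs=1e-12)
        assert dist.pmf.sum() + dist.dead_mass == pytest.approx(1.0, abs=1e-9)
        for s, p in brute.items():
            tail = sum(q for t, q in brute.items() if t >= s)
            assert dist.pvalue(int(s)) == pytest.approx(tail, abs=1e-10)

    def test_certain_pwm_max_score_probability(self):
        # one certain base per column, uniform background: the best score
        # is attained only by the consensus word, p = (1/4)^w
        probs = np.zeros((4, 4))
        for j, b in enumerate([0, 1, 2, 3]):
            probs[b, j] = 1.0
        pwm = PWM("certain", probs, pseudocount=1e-6)
        dist = exact_score_pvalues(pwm)
        max_score = dist.min_score + len(dist.pmf) - 1
        assert dist.pvalue(max_score) == pytest.approx(0.25**4, rel=1e-6)

    def test_minus_infinity_score_has_p_one(self):
        pwm = bundled_tbox_pwm()
        dist = exact_score_pvalues(pwm)
        assert dist.pvalue_bits(-math.inf) == 1.0
        assert dist.pvalue(dist.min_score - 100) == 1.0


class TestScanning:
    def test_consensus_sequence_hits_at_offset_zero(self):
        pwm = bundled_tbox_pwm()
        hits, flags = scan_sites({"s": pwm.consensus}, pwm, 0.004,
                                 background=np.full(4, 0.25))
        assert flags["s"] and hits[0].offset == 0 and hits[0].strand == "+"

    def test_reverse_complement_hit_on_minus_strand(self):
        pwm = bundled_tbox_pwm()
        rc_seq = pwm.consensus[::-1].translate(RC)
        hits, flags = scan_sites({"s": rc_seq}, pwm, 0.004,
                                 background=np.full(4, 0.25))
        assert flags["s"] and any(h.strand == "-" for h in hits)

    def test_strand_symmetry_of_hit_counts(self, rng):
        pwm = bundled_tbox_pwm()
        bg = np.full(4, 0.25)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=80))
            for i in range(40)
        }
        hits_fwd, _ = scan_sites(seqs, pwm, 0.01, background=bg)
        rc_seqs = {k: v[::-1].translate(RC) for k, v in seqs.items()}
        hits_rev, _ = scan_sites(rc_seqs, pwm, 0.01, background=bg)
        assert len(hits_fwd) == len(hits_rev)

    def test_windows_with_n_skipped(self):
        pwm = bundled_tbox_pwm()
        seq = pwm.consensus[:4] + "N" + pwm.consensus[5:]
        hits, flags = scan_sites({"s": seq}, pwm, 0.5, background=np.full(4, 0.25))
        assert not flags["s"]

    def test_short_sequence_yields_no_hits(self):
        pwm = bundled_tbox_pwm()
        _, flags = scan_sites({"s": "ACGT"}, pwm, 0.5)
        assert flags["s"] is False

    def test_background_hit_rate_matches_null_expectation(self, rng):
        """Hit count on pure background is Poisson around 2*L*p."""
        pwm = bundled_tbox_pwm()
        bg = np.full(4, 0.25)
        threshold = 1e-3
        L = 200_000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        engine = ScanEngine(pwm, bg)
        hits = engine.scan("bg", seq, threshold)
        n_win = L - pwm.width + 1
        # attainable per-window probability just below the threshold
        p_eff = sum(
            float(d.sf[d.sf < threshold].max()) for d in (engine.dist_fwd,
                                                          engine.dist_rev)
        )
        lam = n_win * p_eff
        assert lam > 5
        assert abs(len(hits) - lam) < 5 * math.sqrt(lam)


class TestProportions:
    def test_degenerate_bounds(self):
        est0 = motif_proportion([False] * 20)
        assert est0.proportion == 0.0 and est0.ci_low == 0.0
        est1 = motif_proportion([True] * 20)
        assert est1.proportion == 1.0 and est1.ci_high == 1.0
        with pytest.raises(ValueError):
            motif_proportion([])

    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            # frozen from R prop.test(k, n)$conf.int
            (19, 100, 0.1210653473, 0.2833178198),
            (0, 50, 0.0, 0.0888757589),
            (50, 50, 0.9111242411, 1.0),
            (7, 200, 0.0154222164, 0.0737144455),
            (123, 1000, 0.1036113898, 0.1453445445),
        ],
    )
    def test_matches_r_prop_test(self, k, n, lo, hi):
        got_lo, got_hi = prop_test_ci(k, n)
        assert got_lo == pytest.approx(lo, abs=1e-9)
        assert got_hi == pytest.approx(hi, abs=1e-9)

    def test_interval_ordering_invariant(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = prop_test_ci(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestEnrichment:
    def _seq_sets(self, n_hits, n_total, rng, length=30):
        """Site sequences with a deterministic number of motif carriers."""
        pwm = bundled_tbox_pwm()
        out = {}
        i = 0
        while len(out) < n_total:
            name = f"site{id(out)}_{i}"
            i += 1
            if len(out) < n_hits:
                flank = "".join(rng.choice(list("ACGT"), size=length - pwm.width))
                out[name] = flank[:10] + pwm.consensus + flank[10:]
            else:
                seq = "".join(rng.choice(list("ACGT"), size=length))
                out[name] = seq
        return out

    def test_matches_hypergeometric_tail_sum(self, rng):
        pwm = bundled_tbox_pwm()
        target = self._seq_sets(8, 20, rng)
        background = self._seq_sets(2, 80, rng)
        df = known_motif_enrichment(target, background, [pwm], p_threshold=1e-4,
                                    background=np.full(4, 0.25))
        k = int(df.loc[0, "k_target"])
        K = int(df.loc[0, "k_total"])
        want = hypergeom_tail_bruteforce(k, 100, K, 20)
        assert df.loc[0, "p"] == pytest.approx(want, rel=1e-9)
        # planted carriers dominate the counts at this strict threshold
        assert k >= 8 and K - k >= 2

    def test_planted_enrichment_detected(self, rng):
        pwm = bundled_tbox_pwm()
        target = self._seq_sets(80, 200, rng, length=40)
        background = self._seq_sets(10, 200, rng, length=40)
        df = known_motif_enrichment(target, background, [pwm], p_threshold=1e-5,
                                    background=np.full(4, 0.25))
        assert df.loc[0, "neglog10_p"] > 3

    def test_overlapping_sets_rejected(self):
        pwm = bundled_tbox_pwm()
        with pytest.raises(ValueError):
            known_motif_enrichment({"a": "ACGT" * 5}, {"a": "ACGT" * 5}, [pwm])


class TestBHAndNormalization:
    def test_bh_frozen_vector(self):
        q = benjamini_hochberg([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(q, [0.004, 0.02, 4 / 150, 0.8])

    def test_bh_matches_bruteforce(self, rng):
        p = rng.uniform(size=30)
        assert np.allclose(benjamini_hochberg(p), benjamini_hochberg_bruteforce(p))

    def test_single_significant_motif_normalises_to_one(self):
        import pandas as pd

        mat = pd.DataFrame({"setA": [5.0]}, index=["m1"])
        normed, sig = normalize_enrichment_matrix(mat)
        assert normed.loc["m1", "setA"] == 1.0
        assert bool(sig.loc["m1", "setA"]) is True

    def test_all_null_pvalues_keep_nothing(self):
        import pandas as pd

        mat = pd.DataFrame({"setA": [0.0, 0.0], "setB": [0.0, 0.0]},
                           index=["m1", "m2"])
        normed, _ = normalize_enrichment_matrix(mat)
        assert normed.empty


def test_background_estimated_from_sequences():
    bg = estimate_background({"a": "AAAA", "b": "CCGG", "c": "TTNN"})
    assert bg == pytest.approx([0.4, 0.2, 0.2, 0.2])
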