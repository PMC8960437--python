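"""PWM scanning with exact p-values and motif enrichment statistics.

The null distribution of the log-odds score is computed exactly by
dynamic programming over motif positions under an order-0 background,
after discretising per-position scores to fixed-width bins (1/100 bit
by default).  Scanned windows are scored with the same integer scores,
so p-value lookup is exact with respect to the discretisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = [3, 2, 1, 0]  # A<->T, C<->G

DEFAULT_BIN_BITS = 0.01
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Column-stochastic base-probability matrix (rows A, C, G, T)."""

    name: str
    probs: np.ndarray  # shape (4, w)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM must be 4 x w with w >= 4")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1], self.pseudocount)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """log2 odds vs background, with background-weighted pseudocount.

        A zero background frequency opposite non-zero motif probability
        is an error (infinite odds); motif probability 0 with zero
        pseudocount yields -inf, which the DP handles.
        """
        bg = np.asarray(background, dtype=float)
        adj = (self.probs + self.pseudocount * bg[:, None]) / (1.0 + self.pseudocount)
        with np.errstate(divide="ignore"):
            llr = np.log2(adj) - np.log2(bg[:, None])
        if np.isposinf(llr).any():
            raise ValueError(
                f"PWM {self.name}: zero background frequency with non-zero "
                "motif probability gives infinite log-odds"
            )
        return llr

    @classmethod
    def from_jaspar(cls, text: str, pseudocount: float = 1e-3) -> "PWM":
        """Parse one JASPAR-text matrix (counts or probabilities)."""
        name = "motif"
        rows: dict[str, list[float]] = {}
        for line in text.strip().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                continue
            base = line[0].upper()
            nums = line[1:].replace("[", " ").replace("]", " ").split()
            rows[base] = [float(x) for x in nums]
        if set(rows) != set(BASES):
            raise ValueError("JASPAR matrix must have A, C, G and T rows")
        mat = np.array([rows[b] for b in BASES])
        return cls(name, mat / mat.sum(axis=0), pseudocount)

    @classmethod
    def list_from_meme(cls, text: str, pseudocount: float = 1e-3) -> list["PWM"]:
        """Parse MEME minimal format (possibly several motifs)."""
        motifs: list[PWM] = []
        lines = iter(text.splitlines())
        for line in lines:
            if not line.startswith("MOTIF"):
                continue
            name = line.split()[1]
            w = None
            for line in lines:
                if line.strip().startswith("letter-probability matrix"):
                    for tok, nxt in zip(line.split(), line.split()[1:]):
                        if tok == "w=":
                            w = int(nxt)
                    break
            if w is None:
                raise ValueError(f"MEME motif {name}: missing matrix header")
            mat = []
            for _ in range(w):
                mat.append([float(x) for x in next(lines).split()])
            motifs.append(cls(name, np.array(mat).T, pseudocount))
        return motifs


@dataclass
class ScoreDistribution:
    """Exact null distribution of the binned integer log-odds score."""

    min_score: int
    pmf: np.ndarray  # over integer scores min_score .. min_score+len-1
    sf: np.ndarray  # P(score >= s), same indexing
    dead_mass: float  # probability of words with -inf score
    bin_bits: float

    def pvalue(self, int_score: int) -> float:
        if int_score < self.min_score:
            return 1.0
        idx = int_score - self.min_score
        if idx >= len(self.sf):
            return 0.0
        return float(self.sf[idx])

    def pvalue_bits(self, score_bits: float) -> float:
        if math.isinf(score_bits) and score_bits < 0:
            return 1.0
        return self.pvalue(int(round(score_bits / self.bin_bits)))


def _int_scores(llr: np.ndarray, bin_bits: float) -> np.ndarray:
    """Bin log-odds to integers; -inf stays -inf (handled by the DP)."""
    out = np.full(llr.shape, -np.inf)
    finite = np.isfinite(llr)
    out[finite] = np.round(llr[finite] / bin_bits)
    return out


def exact_score_pvalues(
    pwm: PWM,
    background: np.ndarray | None = None,
    bin_bits: float = DEFAULT_BIN_BITS,
) -> ScoreDistribution:
    """DP over positions: exact null distribution of the integer score."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    iscore = _int_scores(pwm.log_odds(bg), bin_bits)
    lo = int(np.where(np.isfinite(iscore), iscore, 0).min(axis=0).sum())
    # running pmf as array with explicit origin
    pmf = np.array([1.0])
    origin = 0  # integer score of pmf[0]
    dead = 0.0
    for j in range(pwm.width):
        col = iscore[:, j]
        finite = np.isfinite(col)
        dead += pmf.sum() * bg[~finite].sum()
        shifts = col[finite].astype(int)
        probs = bg[finite]
        new_lo = origin + shifts.min()
        new_hi = origin + shifts.max() + len(pmf) - 1
        new = np.zeros(new_hi - new_lo + 1)
        for s, p in zip(shifts, probs):
            off = origin + s - new_lo
            new[off : off + len(pmf)] += pmf * p
        pmf, origin = new, new_lo
    sf = np.cumsum(pmf[::-1])[::-1]
    total = pmf.sum() + dead
    if abs(total - 1.0) > 1e-9:
        logger.warning("score distribution mass %.3e != 1", total)
    return ScoreDistribution(origin, pmf, sf, dead, bin_bits)


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


@dataclass
class MotifHit:
    site_id: str
    offset: int
    strand: str
    score_bits: float
    p_value: float


class ScanEngine:
    """Both-strand scanner for one PWM at a fixed background."""

    def __init__(
        self,
        pwm: PWM,
        background: np.ndarray | None = None,
        bin_bits: float = DEFAULT_BIN_BITS,
    ):
        self.pwm = pwm
        self.bg = UNIFORM_BG if background is None else np.asarray(background, float)
        self.bin_bits = bin_bits
        rc = pwm.reverse_complement()
        self.dist_fwd = exact_score_pvalues(pwm, self.bg, bin_bits)
        self.dist_rev = exact_score_pvalues(rc, self.bg, bin_bits)
        self.iscore_fwd = _int_scores(pwm.log_odds(self.bg), bin_bits)
        self.iscore_rev = _int_scores(rc.log_odds(self.bg), bin_bits)

    def _window_scores(self, codes: np.ndarray, iscore: np.ndarray) -> np.ndarray:
        w = self.pwm.width
        n_win = len(codes) - w + 1
        if n_win <= 0:
            return np.empty(0)
        scores = np.zeros(n_win)
        valid = np.ones(n_win, dtype=bool)
        padded = np.vstack([iscore, np.full(iscore.shape[1], np.nan)])
        for j in range(w):
            col = padded[codes[j : j + n_win], j]
            scores += np.where(np.isnan(col), 0.0, col)
            valid &= ~np.isnan(col)
        scores[~valid] = np.nan  # windows containing N are skipped
        return scores

    def scan(self, site_id: str, seq: str, p_threshold: float) -> list[MotifHit]:
        seq = seq.upper()
        if len(seq) < self.pwm.width:
            logger.warning("sequence %s shorter than motif; no hits", site_id)
            return []
        codes = _encode(seq)
        hits: list[MotifHit] = []
        for strand, iscore, dist in (
            ("+", self.iscore_fwd, self.dist_fwd),
            ("-", self.iscore_rev, self.dist_rev),
        ):
            scores = self._window_scores(codes, iscore)
            for off in np.flatnonzero(~np.isnan(scores)):
                s = scores[off]
                p = dist.pvalue(int(s)) if np.isfinite(s) else 1.0
                if p < p_threshold:
                    hits.append(
                        MotifHit(site_id, int(off), strand, s * self.bin_bits, p)
                    )
        hits.sort(key=lambda h: (h.offset, h.strand))
        return hits


def estimate_background(seqs: dict[str, str]) -> np.ndarray:
    """Order-0 base frequencies over all sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in seqs.values():
        codes = _encode(seq.upper())
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BG.copy()
    return counts / counts.sum()


def scan_sites(
    seqs: dict[str, str],
    pwm: PWM,
    p_threshold: float = 0.004,
    background: np.ndarray | None = None,
    bin_bits: float = DEFAULT_BIN_BITS,
) -> tuple[list[MotifHit], dict[str, bool]]:
    """Scan every site sequence on both strands.

    Returns all hits and a per-site flag for >=1 hit.  The background
    is estimated from the scanned sequences when not supplied.
    """
    bg = estimate_background(seqs) if background is None else background
    engine = ScanEngine(pwm, bg, bin_bits)
    hits: list[MotifHit] = []
    flags: dict[str, bool] = {}
    for site_id in sorted(seqs):
        site_hits = engine.scan(site_id, seqs[site_id], p_threshold)
        hits.extend(site_hits)
        flags[site_id] = bool(site_hits)
    return hits, flags


@dataclass
class ProportionEstimate:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float


def prop_test_ci(
    k: int, n: int, conf: float = 0.95, correct: bool = True
) -> tuple[float, float]:
    """Wilson score interval with continuity correction (R prop.test)."""
    if n == 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf((1 + conf) / 2)
    p_hat = k / n
    yates = 0.5 if correct else 0.0
    z22n = z * z / (2 * n)
    pc = p_hat + yates / n
    hi = (
        1.0
        if pc >= 1
        else (pc + z22n + z * math.sqrt(pc * (1 - pc) / n + z22n / (2 * n)))
        / (1 + 2 * z22n)
    )
    pc = p_hat - yates / n
    lo = (
        0.0
        if pc <= 0
        else (pc + z22n - z * math.sqrt(pc * (1 - pc) / n + z22n / (2 * n)))
        / (1 + 2 * z22n)
    )
    return max(0.0, lo), min(1.0, hi)


def motif_proportion(flags: dict[str, bool] | list[bool]) -> ProportionEstimate:
    """Fraction of sites with >=1 significant motif match, with 95% CI."""
    values = list(flags.values()) if isinstance(flags, dict) else list(flags)
    n = len(values)
    if n == 0:
        raise ValueError("no sites")
    k = int(sum(values))
    lo, hi = prop_test_ci(k, n)
    return ProportionEstimate(k, n, k / n, lo, hi)


def known_motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
    p_threshold: float = 0.004,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-motif over-representation in target vs pooled sites.

    One-sided hypergeometric: of N = |target| + |background| sites with
    K motif-containing overall, the probability of >= k containing
    sites among the n target draws.
    """
    if not target_seqs:
        raise ValueError("empty target set")
    if set(target_seqs) & set(background_seqs):
        raise ValueError("target and background site sets must be disjoint")
    if not pwms:
        raise ValueError("need at least one PWM")
    rows = []
    for pwm in pwms:
        _, tf = scan_sites(target_seqs, pwm, p_threshold, background)
        _, bf = scan_sites(background_seqs, pwm, p_threshold, background)
        k = sum(tf.values())
        n = len(tf)
        K = k + sum(bf.values())
        N = n + len(bf)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "motif": pwm.name,
                "k_target": k,
                "n_target": n,
                "k_total": K,
                "n_total": N,
                "p": p,
                "neglog10_p": -math.log10(max(p, 1e-300)),
            }
        )
    return pd.DataFrame(rows)


def normalize_enrichment_matrix(
    neglog10_p: pd.DataFrame, q_max: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select and rescale motif enrichments across site sets.

    Input: motifs x site-sets matrix of -log10 p.  BH q-values are
    computed within each site set (column); motifs significant
    (q < q_max) in at least one set are kept, values are min-max
    normalised within each column, and a boolean mask marks the
    significant cells (non-significant cells lack enrichment).
    """
    p = np.power(10.0, -neglog10_p.to_numpy(dtype=float))
    q = np.empty_like(p)
    for j in range(p.shape[1]):
        q[:, j] = multipletests(p[:, j], method="fdr_bh")[1]
    sig = pd.DataFrame(q < q_max, index=neglog10_p.index, columns=neglog10_p.columns)
    keep = sig.any(axis=1)
    kept = neglog10_p.loc[keep]
    if kept.empty:
        return kept, sig.loc[keep]
    rng = kept.max() - kept.min()
    normed = (kept - kept.min()) / rng.replace(0, np.nan)
    normed = normed.fillna(1.0)
    return normed, sig.loc[keep]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH adjusted p-values (thin wrapper used across the package)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def load_pwm_file(path: str | Path, pseudocount: float = 1e-3) -> list[PWM]:
    """Load PWMs from a JASPAR-text or MEME-minimal file (sniffed)."""
    text = Path(path).read_text()
    if "MEME version" in text or text.lstrip().startswith("MOTIF"):
        return PWM.list_from_meme(text, pseudocount)
    motifs = []
    block: list[str] = []
    for line in text.splitlines():
        if line.startswith(">") and block:
            motifs.append(PWM.from_jaspar("\n".join(block), pseudocount))
            block = []
        if line.strip():
            block.append(line)
    if block:
        motifs.append(PWM.from_jaspar("\n".join(block), pseudocount))
    return motifs


def bundled_tbox_pwm() -> PWM:
    """The synthetic T-box-like PWM shipped for simulations and tests."""
    path = Path(__file__).parent / "data" / "tbox_synthetic.jaspar"
    return load_pwm_file(path)[0]
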