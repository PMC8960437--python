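"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes the quantity from first principles (explicit
base-pair sets, exhaustive enumeration, closed-form textbook formulas)
and never calls the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from crossbind.intervals import GenomicInterval


def bp_set(iv: GenomicInterval) -> set[tuple[str, int]]:
    return {(iv.chrom, p) for p in range(iv.start, iv.end)}


def overlaps_bruteforce(a: GenomicInterval, b: GenomicInterval) -> bool:
    return bool(bp_set(a) & bp_set(b))


def nearest_tss_bruteforce(point: int, chrom: str, genes):
    """Exhaustive scan over every TSS of every gene on the chromosome."""
    best = None
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for tss in gene.tss_positions:
            key = (abs(point - tss), gene.gene_id, tss)
            if best is None or key < best[0]:
                d = point - tss
                if gene.strand == "-":
                    d = -d
                best = (key, gene.gene_id, d)
    if best is None:
        return None
    return best[1], best[2]


def consensus_bruteforce(replicates, q_max):
    """Clique test over merged per-bp sets.

    Returns the sorted list of (chrom, start, end) regions: connected
    components of the pooled qualifying-peak bp set that contain at
    least one bp from every replicate."""
    rep_bps = []
    for peaks in replicates:
        s = set()
        for pk in peaks:
            if pk.q is not None and pk.q < q_max:
                s |= bp_set(pk.interval)
        rep_bps.append(s)
    pooled = set().union(*rep_bps)
    out = []
    for chrom in sorted({c for c, _ in pooled}):
        positions = sorted(p for c, p in pooled if c == chrom)
        runs = []
        start = prev = positions[0]
        for p in positions[1:]:
            if p == prev + 1:
                prev = p
            else:
                runs.append((start, prev + 1))
                start = prev = p
        runs.append((start, prev + 1))
        for s, e in runs:
            run_bp = {(chrom, p) for p in range(s, e)}
            if all(run_bp & rb for rb in rep_bps):
                out.append((chrom, s, e))
    return out


def lift_bruteforce(iv: GenomicInterval, chains):
    """Per-base dictionary mapping through the best-scoring chain.

    Walks the blocks of every chain on the source chromosome base by
    base; selects the highest-score (then smallest chain_id) chain with
    at least one aligned source base, and returns the spanning range of
    the forward-strand images plus the aligned fraction."""
    candidates = sorted(
        (c for c in chains if c.t_name == iv.chrom),
        key=lambda c: (-c.score, c.chain_id),
    )
    for chain in candidates:
        mapping = {}
        t, q = chain.t_start, chain.q_start
        for size, dt, dq in chain.blocks:
            for k in range(size):
                mapping[t + k] = q + k
            t += size + dt
            q += size + dq
        images = []
        for pos in range(iv.start, iv.end):
            if pos in mapping:
                img = mapping[pos]
                if chain.q_strand == "-":
                    img = chain.q_size - img - 1
                images.append(img)
        if images:
            return (
                chain.q_name,
                min(images),
                max(images) + 1,
                len(images) / iv.length,
            )
    return None


def te_enclosure_bruteforce(window: GenomicInterval, tes) -> bool:
    return any(
        te.interval.chrom == window.chrom
        and bp_set(window) <= bp_set(te.interval)
        for te in tes
    )


def pearson_chi2_bruteforce(table: np.ndarray):
    """Textbook Pearson chi-square with (O-E)/sqrt(E) residuals."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    expected = np.outer(rows, cols) / table.sum()
    chi2 = ((table - expected) ** 2 / expected).sum()
    resid = (table - expected) / np.sqrt(expected)
    return chi2, expected, resid


def welch_bruteforce(a, b):
    """Closed-form Welch t and Welch-Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def kruskal_h_bruteforce(groups):
    """Rank-based closed form of the Kruskal-Wallis H (tie-corrected)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    pos = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def hypergeom_tail_bruteforce(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


def benjamini_hochberg_bruteforce(pvalues):
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def pwm_score_distribution_bruteforce(int_scores: np.ndarray, background):
    """Exhaustive enumeration over all 4^w words.

    ``int_scores`` is the 4 x w integer score matrix (-inf allowed);
    returns {score: probability} over finite scores plus the -inf mass."""
    w = int_scores.shape[1]
    dist: dict[float, float] = {}
    dead = 0.0
    for word in itertools.product(range(4), repeat=w):
        p = 1.0
        s = 0.0
        for j, b in enumerate(word):
            p *= background[b]
            s += int_scores[b, j]
        if math.isinf(s):
            dead += p
        else:
            dist[s] = dist.get(s, 0.0) + p
    return dist, dead
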