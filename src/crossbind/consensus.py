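"""Per-species consensus binding sites from replicate peak calls.

The high-confidence set keeps genomic regions supported by a
significant (q < 0.01) peak in every replicate; the low-confidence set
is the merged union of any q < 0.1 peak in any replicate and represents
"any evidence of binding".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .intervals import GenomicInterval, IntervalIndex, merge_intervals, overlaps
from .io import ScoredPeak

logger = logging.getLogger(__name__)


@dataclass
class ConsensusSite:
    interval: GenomicInterval
    species: str
    n_replicates_supporting: int
    site_id: str


def _qualifying(peaks: list[ScoredPeak], q_max: float) -> list[ScoredPeak]:
    kept = []
    n_missing = 0
    for pk in peaks:
        if pk.q is None:
            n_missing += 1
            continue
        if pk.q < q_max:
            kept.append(pk)
    if n_missing:
        logger.warning("excluded %d peaks lacking a q-value", n_missing)
    return kept


def high_confidence_consensus(
    replicates: list[list[ScoredPeak]],
    q_max: float = 0.01,
    species: str = "sp",
    mode: str = "union",
) -> list[ConsensusSite]:
    """Regions covered by a q < q_max peak in all replicates.

    Qualifying peaks from all replicates are pooled and merged into
    clusters (contiguous base-pair runs, so abutting peaks join); a
    cluster survives only when every replicate contributed at least one
    qualifying peak to it.  With
    ``mode="union"`` (default) the site takes the merged cluster
    coordinates; with ``mode="intersection"`` only base pairs covered by
    all replicates are emitted (possibly several runs per cluster).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    n_rep = len(replicates)
    pool: list[tuple[ScoredPeak, int]] = []
    for ridx, peaks in enumerate(replicates):
        for pk in _qualifying(peaks, q_max):
            pool.append((pk, ridx))
    pool.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end))

    sites: list[ConsensusSite] = []
    cluster: list[tuple[ScoredPeak, int]] = []

    def flush() -> None:
        if not cluster:
            return
        reps = {r for _, r in cluster}
        if len(reps) != n_rep:
            return
        if mode == "union":
            chrom = cluster[0][0].interval.chrom
            start = min(pk.interval.start for pk, _ in cluster)
            end = max(pk.interval.end for pk, _ in cluster)
            sites.append(
                ConsensusSite(GenomicInterval(chrom, start, end), species, n_rep, "")
            )
        else:
            per_rep = [
                merge_intervals([pk.interval for pk, r in cluster if r == ridx])
                for ridx in range(n_rep)
            ]
            for run in _common_runs(per_rep):
                sites.append(ConsensusSite(run, species, n_rep, ""))

    cur_chrom, cur_end = None, -1
    for pk, ridx in pool:
        iv = pk.interval
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cluster.append((pk, ridx))
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cluster = [(pk, ridx)]
            cur_chrom, cur_end = iv.chrom, iv.end
    flush()
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    for i, s in enumerate(sites):
        s.site_id = f"{species}_site_{i + 1:05d}"
    return sites


def _common_runs(per_rep: list[list[GenomicInterval]]) -> list[GenomicInterval]:
    """Maximal runs of bp covered by every replicate's merged intervals."""
    if any(not ivs for ivs in per_rep):
        return []
    chrom = per_rep[0][0].chrom
    edges = sorted(
        {iv.start for ivs in per_rep for iv in ivs}
        | {iv.end for ivs in per_rep for iv in ivs}
    )
    runs: list[GenomicInterval] = []
    open_start = None
    for a, b in zip(edges[:-1], edges[1:]):
        probe = GenomicInterval(chrom, a, b)
        covered = all(any(overlaps(probe, iv) for iv in ivs) for ivs in per_rep)
        if covered and open_start is None:
            open_start = a
        elif not covered and open_start is not None:
            runs.append(GenomicInterval(chrom, open_start, a))
            open_start = None
    if open_start is not None:
        runs.append(GenomicInterval(chrom, open_start, edges[-1]))
    return runs


def low_confidence_union(
    replicates: list[list[ScoredPeak]], q_max: float = 0.1
) -> list[GenomicInterval]:
    """Merged union of q < q_max peaks from any replicate."""
    if not replicates:
        raise ValueError("need at least one replicate")
    pool = [pk.interval for peaks in replicates for pk in _qualifying(peaks, q_max)]
    return merge_intervals(pool, merge_abutting=True)


def remove_blacklisted(sites, blacklist: list[GenomicInterval]):
    """Drop sites overlapping (>=1 bp) any blacklist interval.

    Works on ConsensusSite lists or plain interval lists; preserves
    order of survivors and logs the number removed.
    """
    if not blacklist:
        return list(sites)
    index = IntervalIndex(blacklist)
    kept = []
    removed = 0
    for s in sites:
        iv = s.interval if isinstance(s, ConsensusSite) else s
        if index.any_overlap(iv):
            removed += 1
        else:
            kept.append(s)
    if removed:
        logger.info("removed %d blacklisted sites", removed)
    return kept
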