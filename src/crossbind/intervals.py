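"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)``, the native BED /
narrowPeak convention; 1-based formats (GTF) are converted on read.  An
interval covers ``end - start`` base pairs and must be non-empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint in bp (left-of-centre for even lengths)."""
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base pair.

    Half-open semantics: abutting intervals ([100,200) vs [200,300)) do
    not overlap.  Strand is ignored.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(
    intervals: list[GenomicInterval], merge_abutting: bool = False
) -> list[GenomicInterval]:
    """Merge intervals sharing >=1 bp into maximal runs, sorted.

    By default abutting intervals stay separate (no shared base); with
    ``merge_abutting`` the output equals the connected runs of the
    combined base-pair set (GenomicRanges reduce semantics).  Strand is
    dropped on merged output.
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        joined = iv.start <= cur_end if merge_abutting else iv.start < cur_end
        if iv.chrom == cur_chrom and joined:
            cur_end = max(cur_end, iv.end)
        else:
            out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return out


def total_bp(intervals: list[GenomicInterval]) -> int:
    """Number of distinct base pairs covered by the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


@dataclass
class GeneModel:
    """A gene with one or more transcript start sites.

    ``tss_positions`` hold the transcription start of every transcript:
    the smallest span coordinate on the + strand, the largest (end - 1)
    on the - strand.
    """

    gene_id: str
    symbol: str
    strand: str
    span: GenomicInterval
    tss_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id} has no TSS")
        for tss in self.tss_positions:
            if not (self.span.start <= tss <= self.span.end):
                raise ValueError(
                    f"gene {self.gene_id}: TSS {tss} outside span {self.span}"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom


@dataclass(frozen=True)
class SignedTssDistance:
    """Distance from a point to a gene TSS, signed by gene strand.

    Negative = upstream of the TSS, positive = downstream, relative to
    the direction of transcription.
    """

    gene_id: str
    distance: int


def signed_distance(point: int, tss: int, strand: str) -> int:
    """Signed point-to-TSS distance following transcription direction."""
    d = point - tss
    return -d if strand == "-" else d


def nearest_tss(
    point: int, chrom: str, genes: list[GeneModel]
) -> SignedTssDistance | None:
    """Nearest gene TSS to ``point``, restricted to ``chrom``.

    Over all genes on the chromosome and all their TSSs, picks the TSS
    minimising ``|point - tss|``; ties broken by lexicographic gene_id,
    then by the smaller TSS coordinate.  Returns None when the
    chromosome carries no gene (callers drop such features from
    gene-level analyses).
    """
    if not genes:
        raise ValueError("empty gene list")
    best: tuple[int, str, int] | None = None
    best_strand = "."
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for tss in gene.tss_positions:
            key = (abs(point - tss), gene.gene_id, tss)
            if best is None or key < best:
                best = key
                best_strand = gene.strand
    if best is None:
        return None
    _, gene_id, tss = best
    return SignedTssDistance(gene_id, signed_distance(point, tss, best_strand))


def central_window(
    site: GenomicInterval, width: int = 40, chrom_size: int | None = None
) -> GenomicInterval:
    """Window of ``width`` bp centred on the site midpoint.

    Clamped at position 0 and at ``chrom_size`` (when known) with a
    logged warning rather than an error.
    """
    if width < 2 or width % 2:
        raise ValueError("width must be even and >= 2")
    mid = site.midpoint
    start, end = mid - width // 2, mid + width // 2
    if start < 0:
        logger.warning("central window of %s clamped at chromosome start", site)
        start = 0
    if chrom_size is not None and end > chrom_size:
        logger.warning("central window of %s clamped at chromosome end", site)
        end = chrom_size
    return GenomicInterval(site.chrom, start, end)


class IntervalIndex:
    """Overlap index over a fixed interval set (simple sorted-list scan).

    Suitable for the site/peak scales this pipeline handles (10^3-10^5
    intervals); query is binary search plus a short backward scan bound
    by the longest interval per chromosome.
    """

    def __init__(self, intervals: list[GenomicInterval]):
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        self._maxlen: dict[str, int] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            ivs.sort(key=lambda x: (x.start, x.end))
            self._maxlen[chrom] = max(iv.length for iv in ivs)

    def any_overlap(self, query: GenomicInterval) -> bool:
        return next(iter(self.overlapping(query)), None) is not None

    def overlapping(self, query: GenomicInterval):
        ivs = self._by_chrom.get(query.chrom)
        if not ivs:
            return
        maxlen = self._maxlen[query.chrom]
        lo = 0
        hi = len(ivs)
        # first candidate cannot start earlier than query.start - maxlen
        from bisect import bisect_left

        lo = bisect_left(ivs, (query.start - maxlen,), key=lambda x: (x.start,))
        for iv in ivs[lo:]:
            if iv.start >= query.end:
                break
            if iv.end > query.start:
                yield iv
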