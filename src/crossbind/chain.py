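"""UCSC chain parsing and interval lifting between genomes.

A chain is a gapped pairwise alignment: a header line

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by block lines ``size [dt dq]`` where ``size`` is an ungapped
aligned block, ``dt`` the gap on the target side and ``dq`` the gap on
the query side before the next block.  Query coordinates of a ``-``
strand chain live on the reverse-complemented query sequence and are
converted to forward-strand positions (``qSize - pos - 1``) when images
are formed.

Lifting follows the single-spanning-range rule: the image of an
interval is one range from the smallest to the largest aligned image
position on the query genome, regardless of internal gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class ChainParseError(ValueError):
    pass


@dataclass
class ChainAlignment:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]  # (aligned_size, dt, dq); last has (size,0,0)
    chain_id: str

    def validate(self) -> None:
        aligned = sum(b[0] for b in self.blocks)
        dt = sum(b[1] for b in self.blocks)
        dq = sum(b[2] for b in self.blocks)
        if aligned + dt != self.t_end - self.t_start:
            raise ChainParseError(
                f"chain {self.chain_id}: target arithmetic mismatch "
                f"({aligned}+{dt} != {self.t_end - self.t_start})"
            )
        if aligned + dq != self.q_end - self.q_start:
            raise ChainParseError(
                f"chain {self.chain_id}: query arithmetic mismatch "
                f"({aligned}+{dq} != {self.q_end - self.q_start})"
            )
        if self.blocks and self.blocks[-1][1:] != (0, 0):
            raise ChainParseError(f"chain {self.chain_id}: last block has gaps")

    def block_spans(self):
        """Yield (t_lo, t_hi, q_lo) per aligned block, chain coordinates."""
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            yield t, t + size, q
            t += size + dt
            q += size + dq

    def query_forward(self, pos: int) -> int:
        """Convert a chain-convention query position to forward strand."""
        if self.q_strand == "-":
            return self.q_size - pos - 1
        return pos


class LiftStatus(str, Enum):
    MAPPED = "mapped"
    UNMAPPED = "unmapped"
    SPLIT = "split_across_chromosomes"


@dataclass
class LiftResult:
    status: LiftStatus
    mapped_interval: GenomicInterval | None
    mapped_fraction: float

    @property
    def mapped(self) -> bool:
        return self.status is LiftStatus.MAPPED


def parse_chain(source) -> list[ChainAlignment]:
    close = False
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source)
        close = True
    else:
        fh = source
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (
            _,
            score,
            t_name,
            t_size,
            t_strand,
            t_start,
            t_end,
            q_name,
            q_size,
            q_strand,
            q_start,
            q_end,
            chain_id,
        ) = header
        chain = ChainAlignment(
            score=float(score),
            t_name=t_name,
            t_size=int(t_size),
            t_strand=t_strand,
            t_start=int(t_start),
            t_end=int(t_end),
            q_name=q_name,
            q_size=int(q_size),
            q_strand=q_strand,
            q_start=int(q_start),
            q_end=int(q_end),
            blocks=blocks,
            chain_id=chain_id,
        )
        chain.validate()
        chains.append(chain)
        header, blocks = None, []

    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) != 13:
                    raise ChainParseError(
                        f"line {lineno}: chain header needs 13 fields"
                    )
                blocks = []
            else:
                if header is None:
                    raise ChainParseError(f"line {lineno}: block before header")
                parts = line.split()
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ChainParseError(f"line {lineno}: malformed block line")
        finish()
    finally:
        if close:
            fh.close()
    return chains


def write_chain(chains: list[ChainAlignment], dest) -> None:
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for i, (size, dt, dq) in enumerate(c.blocks):
                if i == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size}\t{dt}\t{dq}\n")
            fh.write("\n")
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


class ChainIndex:
    """Chains grouped by source (target-side) chromosome."""

    def __init__(self, chains: list[ChainAlignment]):
        self.by_chrom: dict[str, list[ChainAlignment]] = {}
        for c in chains:
            self.by_chrom.setdefault(c.t_name, []).append(c)
        for lst in self.by_chrom.values():
            # best score first; deterministic tie-break on chain_id
            lst.sort(key=lambda c: (-c.score, c.chain_id))


def _chain_images(chain: ChainAlignment, iv: GenomicInterval):
    """Forward-strand query image extrema and aligned-bp count of ``iv``."""
    lo = hi = None
    aligned = 0
    for t0, t1, q0 in chain.block_spans():
        s, e = max(iv.start, t0), min(iv.end, t1)
        if s >= e:
            continue
        aligned += e - s
        qa = q0 + (s - t0)
        qb = q0 + (e - t0) - 1  # inclusive chain-coordinate endpoints
        fa, fb = chain.query_forward(qa), chain.query_forward(qb)
        blo, bhi = min(fa, fb), max(fa, fb)
        lo = blo if lo is None else min(lo, blo)
        hi = bhi if hi is None else max(hi, bhi)
    return lo, hi, aligned


def lift_interval(
    iv: GenomicInterval,
    chains: ChainIndex | list[ChainAlignment],
    use_all_chains: bool = False,
) -> LiftResult:
    """Map an interval through chains to the other genome.

    By default the highest-scoring chain with at least one aligned base
    in the interval is used alone (liftOver-like best-chain behaviour).
    With ``use_all_chains`` images from every overlapping chain are
    pooled, and images on more than one query chromosome yield the
    ``split_across_chromosomes`` status.
    """
    index = chains if isinstance(chains, ChainIndex) else ChainIndex(chains)
    candidates = index.by_chrom.get(iv.chrom, [])
    hits: list[tuple[ChainAlignment, int, int, int]] = []
    for chain in candidates:
        lo, hi, aligned = _chain_images(chain, iv)
        if aligned > 0:
            hits.append((chain, lo, hi, aligned))
            if not use_all_chains:
                break  # candidates sorted best-first
    if not hits:
        return LiftResult(LiftStatus.UNMAPPED, None, 0.0)
    chroms = {c.q_name for c, *_ in hits}
    if len(chroms) > 1:
        return LiftResult(LiftStatus.SPLIT, None, 0.0)
    lo = min(h[1] for h in hits)
    hi = max(h[2] for h in hits)
    if use_all_chains:
        # aligned counts may double-cover; cap at interval length
        aligned = min(sum(h[3] for h in hits), iv.length)
    else:
        aligned = hits[0][3]
    mapped = GenomicInterval(hits[0][0].q_name, lo, hi + 1)
    return LiftResult(LiftStatus.MAPPED, mapped, aligned / iv.length)


def lift_padded_site(
    site: GenomicInterval,
    chains: ChainIndex | list[ChainAlignment],
    pad: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> LiftResult:
    """Lift a site after symmetric padding, clamped at chromosome bounds."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    start = site.start - pad
    end = site.end + pad
    if start < 0:
        logger.warning("padded site %s clamped at chromosome start", site)
        start = 0
    if chrom_sizes is not None:
        size = chrom_sizes.get(site.chrom)
        if size is not None and end > size:
            logger.warning("padded site %s clamped at chromosome end", site)
            end = size
    return lift_interval(GenomicInterval(site.chrom, start, end), chains)
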