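"""Readers and writers for the plain-text genomics formats the pipeline
consumes: ENCODE narrowPeak, BED6, GTF, FASTA, chromosome sizes, TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .intervals import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


@dataclass
class ScoredPeak:
    """One replicate peak call.

    ``q`` is the FDR-adjusted significance on the probability scale,
    recovered from the narrowPeak -log10(qValue) column; None when the
    caller reported the -1 sentinel.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal: float = 0.0
    p: float | None = None
    q: float | None = None
    summit_offset: int | None = None
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.q is not None and not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must be a probability, got {self.q}")


def _open(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_narrowpeak(source, replicate_id: str | None = None) -> list[ScoredPeak]:
    """Parse a 10-column ENCODE narrowPeak file.

    Column 9 is -log10(qValue); -1 means "not available" and yields
    ``q=None`` with the peak retained.  Coordinates are taken as 0-based
    half-open, unchanged.
    """
    peaks: list[ScoredPeak] = []
    fh = _open(source)
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) != 10:
                raise ParseError(
                    f"narrowPeak line {lineno}: expected 10 columns, got {len(cols)}"
                )
            try:
                chrom = cols[0]
                start, end = int(cols[1]), int(cols[2])
                strand = cols[5] if cols[5] in ("+", "-") else "."
                signal = float(cols[6])
                neglog_p = float(cols[7])
                neglog_q = float(cols[8])
                summit = int(cols[9])
            except ValueError as exc:
                raise ParseError(f"narrowPeak line {lineno}: {exc}") from exc
            if end <= start:
                raise ParseError(
                    f"narrowPeak line {lineno}: end {end} <= start {start}"
                )
            peaks.append(
                ScoredPeak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=cols[3],
                    score=int(float(cols[4])),
                    signal=signal,
                    p=10.0 ** (-neglog_p) if neglog_p >= 0 else None,
                    q=min(1.0, 10.0 ** (-neglog_q)) if neglog_q >= 0 else None,
                    summit_offset=summit if summit >= 0 else None,
                    replicate_id=replicate_id,
                )
            )
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    return peaks


def _fmt_neglog10(p: float | None) -> str:
    import math

    if p is None:
        return "-1"
    return f"{-math.log10(max(p, 1e-300)):.5f}"


def write_narrowpeak(peaks: Iterable[ScoredPeak], dest) -> None:
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for pk in peaks:
            iv = pk.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        pk.name,
                        str(pk.score),
                        iv.strand if iv.strand != "." else ".",
                        f"{pk.signal:g}",
                        _fmt_neglog10(pk.p),
                        _fmt_neglog10(pk.q),
                        str(pk.summit_offset if pk.summit_offset is not None else -1),
                    ]
                )
                + "\n"
            )
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


def read_bed6(source) -> list[GenomicInterval]:
    """Read BED (3-6 columns) as intervals; name/score are discarded."""
    out: list[GenomicInterval] = []
    fh = _open(source)
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 3:
                raise ParseError(f"BED line {lineno}: fewer than 3 columns")
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    return out


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, float]], dest
) -> None:
    """Write (interval, name, score) triples as BED6."""
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for iv, name, score in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t"
                f"{iv.strand if iv.strand != '.' else '.'}\n"
            )
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


def _gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(source) -> list[GeneModel]:
    """Build gene models from GTF transcript records.

    GTF is 1-based inclusive; converted to 0-based half-open here.  The
    TSS of each transcript is its 5' end after strand resolution; the
    gene span is the union of its transcript spans.
    """
    tx: dict[str, dict] = {}
    fh = _open(source)
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"GTF line {lineno}: expected 9 columns")
            if cols[2] != "transcript":
                continue
            chrom, start1, end1, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _gtf_attributes(cols[8])
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise ParseError(f"GTF line {lineno}: missing gene_id")
            rec = tx.setdefault(
                gene_id,
                {
                    "symbol": attrs.get("gene_name", gene_id),
                    "chrom": chrom,
                    "strand": strand,
                    "starts": [],
                    "ends": [],
                    "tss": [],
                },
            )
            if rec["chrom"] != chrom:
                logger.warning("gene %s on multiple chromosomes; keeping first", gene_id)
                continue
            rec["starts"].append(start)
            rec["ends"].append(end)
            rec["tss"].append(start if strand == "+" else end - 1)
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    genes = []
    for gene_id, rec in tx.items():
        span = GenomicInterval(
            rec["chrom"], min(rec["starts"]), max(rec["ends"]), rec["strand"]
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=rec["symbol"],
                strand=rec["strand"],
                span=span,
                tss_positions=sorted(set(rec["tss"])),
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def read_chrom_sizes(source) -> dict[str, int]:
    sizes: dict[str, int] = {}
    fh = _open(source)
    try:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    return sizes


def read_fasta(source) -> dict[str, str]:
    """Whole-file FASTA reader returning uppercase sequences by name."""
    seqs: dict[str, list[str]] = {}
    name = None
    fh = _open(source)
    try:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError("FASTA sequence before header")
                seqs[name].append(line.upper())
    finally:
        if isinstance(source, (str, Path)):
            fh.close()
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], dest, width: int = 80) -> None:
    fh = open(dest, "w") if isinstance(dest, (str, Path)) else dest
    try:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if isinstance(dest, (str, Path)):
            fh.close()


def fetch_sequences(
    genome: dict[str, str], intervals: dict[str, GenomicInterval]
) -> dict[str, str]:
    """Extract uppercase sequences for named intervals from a genome dict."""
    out = {}
    for key, iv in intervals.items():
        seq = genome[iv.chrom][iv.start : iv.end]
        out[key] = seq.upper()
    return out


def read_ortholog_table(source) -> pd.DataFrame:
    """1:1 ortholog TSV with columns gene_a, gene_b (header required).

    Genes appearing more than once are dropped (the table must be 1:1).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "gene_a", cols[1]: "gene_b"})
    before = len(df)
    df = df[~df["gene_a"].duplicated(keep=False) & ~df["gene_b"].duplicated(keep=False)]
    if len(df) < before:
        logger.warning("dropped %d non-1:1 ortholog rows", before - len(df))
    return df[["gene_a", "gene_b"]].reset_index(drop=True)
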