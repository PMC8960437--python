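"""Two-species toy world with planted ground truth.

The generator builds a pair of small genomes related by a constructed
block alignment (a configurable fraction of each genome unalignable),
plants binding sites of known conservation class at known host genes,
and emits every input the pipeline consumes — replicate peak calls,
chains in both directions, gene annotations, a 1:1 ortholog table, TE
and blacklist tracks, genome sequence with planted motif instances, and
negative-binomial RNA-seq counts with study batch effects and
class-linked species effects — alongside the ground truth needed to
measure recovery.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import ChainAlignment, ChainIndex, write_chain
from .classify import SiteClass, classify_gene, GeneBindingProfile
from .intervals import GeneModel, GenomicInterval
from .io import ScoredPeak, write_fasta, write_narrowpeak
from .motifs import PWM, bundled_tbox_pwm
from .te import TEClass, TEFeature

logger = logging.getLogger(__name__)

SPECIES = ("A", "B")
BASES = np.array(list("ACGT"))

# site slots relative to the host TSS; >=1.6 kb apart so a 1 kb-padded
# lifted image can only reach its own partner's evidence
SLOTS = np.array([-5400, -3800, -2200, 1800, 3400, 5000])


def _default_motif_rates() -> dict[str, float]:
    return {
        "conserved_A": 0.121,
        "conserved_B": 0.132,
        "specific_own_A": 0.191,
        "specific_lifted_A": 0.067,  # lifted loci of A-specific sites, in B
        "specific_own_B": 0.182,
        "specific_lifted_B": 0.077,
    }


def _default_te_rates() -> dict[str, float]:
    return {
        "conserved_A": 0.034,
        "conserved_B": 0.006,
        "specific_A": 0.108,
        "specific_B": 0.06,
    }


def _default_expression_effects() -> dict[str, tuple[float, float]]:
    # log2 A/B mean and sd per gene class
    return {
        "conserved": (-0.59, 1.59),
        "alternative": (-0.21, 2.46),
        "a_specific": (1.95, 2.0),
        "b_specific": (-1.55, 2.0),
        "unbound": (0.0, 1.2),
    }


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    unalignable_fraction: float = 0.10
    aligned_block_bp: tuple[int, int] = (40_000, 68_000)
    genes_per_chrom: int = 85
    ortholog_fraction: float = 0.90
    tss_spacing_bp: int = 15_000
    segment_margin_bp: int = 7_000
    n_conserved_genes: int = 60
    n_alternative_genes: int = 25
    n_a_specific_genes: int = 15
    n_b_specific_genes: int = 15
    n_indeterminate_sites: int = 15  # per species, hosted at conserved genes
    site_width_bp: int = 200
    peak_jitter_bp: int = 30
    q_neglog_mean: float = 4.0
    q_neglog_sd: float = 0.75
    replicates: dict[str, int] = field(default_factory=lambda: {"A": 3, "B": 2})
    motif_rates: dict[str, float] = field(default_factory=_default_motif_rates)
    te_rates: dict[str, float] = field(default_factory=_default_te_rates)
    te_background_per_mb: float = 25.0
    gc_content: float = 0.40
    studies_per_species: int = 3
    samples_per_study: int = 2
    nb_dispersion: float = 0.05
    batch_log2_sd: float = 0.25
    expression_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_expression_effects
    )
    emit_sequence: bool = True  # off: skip genome sequence (coordinate-only worlds)

    def noise_free(self) -> "SyntheticConfig":
        """Same world, deterministic peak q-values and no boundary jitter."""
        return replace(self, q_neglog_sd=0.0, peak_jitter_bp=0)

    def validate(self) -> None:
        if not 0.0 <= self.unalignable_fraction < 0.5:
            raise ValueError("unalignable_fraction must be in [0, 0.5)")
        n_classed = (
            self.n_conserved_genes
            + self.n_alternative_genes
            + self.n_a_specific_genes
            + self.n_b_specific_genes
        )
        n_pairs_approx = int(
            self.n_chroms * self.genes_per_chrom * self.ortholog_fraction * 0.8
        )
        if n_classed > n_pairs_approx:
            raise ValueError(
                f"infeasible packing: {n_classed} classed gene pairs requested "
                f"but only ~{n_pairs_approx} ortholog pairs fit the genome"
            )


@dataclass
class SimGene:
    gene_id: str
    species: str
    chrom: str
    tss: int
    strand: str
    span: tuple[int, int]
    tss2: int | None = None
    pair_idx: int | None = None  # index into ortholog pair list
    gene_class: str | None = None  # planted class, on ortholog genes

    def to_model(self) -> GeneModel:
        tss = sorted({self.tss} | ({self.tss2} if self.tss2 is not None else set()))
        return GeneModel(
            gene_id=self.gene_id,
            symbol=self.gene_id,
            strand=self.strand,
            span=GenomicInterval(self.chrom, self.span[0], self.span[1], self.strand),
            tss_positions=tss,
        )


@dataclass
class SimSite:
    species: str
    chrom: str
    start: int
    end: int
    true_class: str  # SiteClass values
    host_gene: str  # intended nearest gene ("" for gap sites near fillers)
    image: tuple[str, int, int] | None  # other-species coordinates
    motif_own: bool = False
    motif_image: bool = False
    te: TEFeature | None = None


class World:
    """A built synthetic world: inputs plus ground truth."""

    def __init__(self, config: SyntheticConfig):
        self.config = config
        self.segments: dict[int, list[tuple[int, int, int]]] = {}
        self.gaps: dict[str, list[tuple[str, int, int]]] = {"A": [], "B": []}
        self.sizes: dict[str, dict[str, int]] = {"A": {}, "B": {}}
        self.chains: dict[str, list[ChainAlignment]] = {}
        self.genes: dict[str, list[SimGene]] = {"A": [], "B": []}
        self.pairs: list[tuple[SimGene, SimGene]] = []
        self.sites: list[SimSite] = []
        self.peaks: dict[str, list[list[ScoredPeak]]] = {}
        self.blacklist: dict[str, list[GenomicInterval]] = {"A": [], "B": []}
        self.tes: dict[str, list[TEFeature]] = {"A": [], "B": []}
        self.sequences: dict[str, dict[str, str]] = {}
        self.counts: dict[str, pd.DataFrame] = {}
        self.sample_meta: dict[str, pd.DataFrame] = {}
        self.pwm: PWM = bundled_tbox_pwm()
        self.truth_genes: pd.DataFrame | None = None

    # -- coordinate helpers -------------------------------------------------
    def chrom_name(self, species: str, ci: int) -> str:
        return f"chr{species}{ci + 1}"

    def map_pos(self, species_from: str, ci: int, pos: int) -> int | None:
        """Image of a position in the other species, None if unaligned."""
        segs = self.segments[ci]
        col = 0 if species_from == "A" else 1
        starts = [s[col] for s in segs]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        a, b, ln = segs[i]
        src = a if species_from == "A" else b
        dst = b if species_from == "A" else a
        if src <= pos < src + ln:
            return dst + (pos - src)
        return None

    def gene_models(self, species: str) -> list[GeneModel]:
        return [g.to_model() for g in sorted(self.genes[species], key=lambda g: g.gene_id)]

    def ortholog_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a.gene_id for a, _ in self.pairs],
                "gene_b": [b.gene_id for _, b in self.pairs],
            }
        )

    def chain_index(self, direction: str) -> ChainIndex:
        return ChainIndex(self.chains[direction])

    def truth_sites(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "species": s.species,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "true_class": s.true_class,
                    "host_gene": s.host_gene,
                    "image_chrom": s.image[0] if s.image else "",
                    "image_start": s.image[1] if s.image else -1,
                    "image_end": s.image[2] if s.image else -1,
                    "motif_own": s.motif_own,
                    "motif_image": s.motif_image,
                    "te_overlap": s.te is not None,
                    "te_class": s.te.te_class.value if s.te else "none",
                }
            )
        return pd.DataFrame(rows).sort_values(["species", "chrom", "start"]).reset_index(
            drop=True
        )

    # -- recovery metrics ---------------------------------------------------
    def match_true_class(self, site_table: pd.DataFrame, species: str) -> pd.Series:
        """For each truth site of a species, the recovered class or 'missing'.

        A truth site is matched to a pipeline consensus site when their
        intervals overlap; planted sites are far enough apart that the
        match is unique."""
        truth = [s for s in self.sites if s.species == species]
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for _, row in site_table.iterrows():
            by_chrom.setdefault(row["chrom"], []).append(
                (row["start"], row["end"], row["site_class"])
            )
        for lst in by_chrom.values():
            lst.sort()
        out = []
        for s in truth:
            found = "missing"
            for start, end, cls in by_chrom.get(s.chrom, []):
                if start < s.end and s.start < end:
                    found = cls
                    break
            out.append(found)
        return pd.Series(out, index=[f"{s.chrom}:{s.start}" for s in truth])

    def site_recovery(self, table_a: pd.DataFrame, table_b: pd.DataFrame) -> float:
        correct = total = 0
        for species, table in (("A", table_a), ("B", table_b)):
            truth = [s for s in self.sites if s.species == species]
            got = self.match_true_class(table, species)
            for s, g in zip(truth, got):
                total += 1
                correct += int(s.true_class == g)
        return correct / total if total else 1.0

    def gene_recovery(self, gene_table: pd.DataFrame) -> float:
        truth = self.truth_genes.set_index(["gene_a", "gene_b"])["true_class"]
        got = gene_table.set_index(["gene_a", "gene_b"])["gene_class"]
        got = got.reindex(truth.index)
        return float((truth == got).mean())

    # -- emission -----------------------------------------------------------
    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        header = f"# crossbind synthetic world, seed={seed}\n"
        for sp in SPECIES:
            write_fasta(
                {
                    f"{name} seed={seed}": seq
                    for name, seq in self.sequences[sp].items()
                },
                out / f"genome_{sp}.fa",
            )
            with open(out / f"sizes_{sp}.tsv", "w") as fh:
                fh.write(header)
                for name, size in self.sizes[sp].items():
                    fh.write(f"{name}\t{size}\n")
            with open(out / f"genes_{sp}.gtf", "w") as fh:
                fh.write(header)
                for g in sorted(self.genes[sp], key=lambda g: (g.chrom, g.tss)):
                    for ti, tss in enumerate(
                        [g.tss] + ([g.tss2] if g.tss2 is not None else [])
                    ):
                        if g.strand == "+":
                            start, end = tss, g.span[1]
                        else:
                            start, end = g.span[0], tss + 1
                        attrs = (
                            f'gene_id "{g.gene_id}"; transcript_id '
                            f'"{g.gene_id}.t{ti + 1}"; gene_name "{g.gene_id}";'
                        )
                        fh.write(
                            f"{g.chrom}\tsim\ttranscript\t{start + 1}\t{end}\t.\t"
                            f"{g.strand}\t.\t{attrs}\n"
                        )
            for ridx, peaks in enumerate(self.peaks[sp], start=1):
                write_narrowpeak(peaks, out / f"peaks_{sp}_rep{ridx}.narrowPeak")
            with open(out / f"blacklist_{sp}.bed", "w") as fh:
                fh.write(header)
                for iv in self.blacklist[sp]:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            with open(out / f"te_{sp}.bed", "w") as fh:
                fh.write(header)
                for i, te in enumerate(self.tes[sp]):
                    iv = te.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{te.name}#{te.te_class.value}\t0\t.\n"
                    )
            for label, df in (
                (f"counts_{sp}.tsv", self.counts[sp]),
                (f"samples_{sp}.tsv", self.sample_meta[sp]),
            ):
                with open(out / label, "w") as fh:
                    fh.write(header)
                    df.to_csv(fh, sep="\t", index=(label.startswith("counts")))
        write_chain(self.chains["AB"], out / "A_to_B.chain")
        write_chain(self.chains["BA"], out / "B_to_A.chain")
        with open(out / "orthologs.tsv", "w") as fh:
            fh.write(header)
            self.ortholog_table().to_csv(fh, sep="\t", index=False)
        (out / "pwm.jaspar").write_text(
            Path(__file__).parent.joinpath("data", "tbox_synthetic.jaspar").read_text()
        )
        with open(out / "truth_sites.tsv", "w") as fh:
            fh.write(header)
            self.truth_sites().to_csv(fh, sep="\t", index=False)
        with open(out / "truth_genes.tsv", "w") as fh:
            fh.write(header)
            self.truth_genes.to_csv(fh, sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["aligned_block_bp"] = list(cfg["aligned_block_bp"])
        (out / "world.json").write_text(json.dumps(cfg, indent=2, default=str) + "\n")
        run_cfg = {
            "peaks_a": [
                f"peaks_A_rep{i + 1}.narrowPeak"
                for i in range(self.config.replicates["A"])
            ],
            "peaks_b": [
                f"peaks_B_rep{i + 1}.narrowPeak"
                for i in range(self.config.replicates["B"])
            ],
            "blacklist_a": "blacklist_A.bed",
            "blacklist_b": "blacklist_B.bed",
            "chain_ab": "A_to_B.chain",
            "chain_ba": "B_to_A.chain",
            "gtf_a": "genes_A.gtf",
            "gtf_b": "genes_B.gtf",
            "orthologs": "orthologs.tsv",
            "sizes_a": "sizes_A.tsv",
            "sizes_b": "sizes_B.tsv",
            "te_a": "te_A.bed",
            "te_b": "te_B.bed",
            "genome_a": "genome_A.fa",
            "genome_b": "genome_B.fa",
            "counts_a": "counts_A.tsv",
            "counts_b": "counts_B.tsv",
            "samples_a": "samples_A.tsv",
            "samples_b": "samples_B.tsv",
            "pwms": "pwm.jaspar",
            "seed": seed,
        }
        with open(out / "run_config.yaml", "w") as fh:
            import yaml

            yaml.safe_dump(run_cfg, fh, sort_keys=True)
        return out


# ---------------------------------------------------------------------------


def build_world(config: SyntheticConfig | None = None) -> World:
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    world = World(config)
    _build_alignment(world, rng)
    _build_genes(world, rng)
    _assign_gene_classes(world, rng)
    _place_sites(world, rng)
    _place_gap_sites(world, rng)
    _emit_peaks(world, rng)
    _build_sequences(world, rng)
    _place_tes(world, rng)
    _emit_counts(world, rng)
    _derive_truth_genes(world)
    return world


def _build_alignment(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    u = cfg.unalignable_fraction
    blk_lo, blk_hi = cfg.aligned_block_bp
    gap_mean = 0 if u == 0 else 2 * (blk_lo + blk_hi) / 2 * u / (1 - u)
    for ci in range(cfg.n_chroms):
        segs: list[tuple[int, int, int]] = []
        pos_a = pos_b = 0
        k = 0
        while pos_a < cfg.chrom_length:
            ln = cfg.chrom_length if u == 0 else int(rng.integers(blk_lo, blk_hi + 1))
            segs.append((pos_a, pos_b, ln))
            pos_a += ln
            pos_b += ln
            if pos_a >= cfg.chrom_length or u == 0:
                break
            gap = max(3000, int(gap_mean * rng.uniform(0.7, 1.3)))
            if k % 2 == 0:
                world.gaps["A"].append((world.chrom_name("A", ci), pos_a, gap))
                pos_a += gap
            else:
                world.gaps["B"].append((world.chrom_name("B", ci), pos_b, gap))
                pos_b += gap
            k += 1
        world.segments[ci] = segs
        name_a, name_b = world.chrom_name("A", ci), world.chrom_name("B", ci)
        world.sizes["A"][name_a] = segs[-1][0] + segs[-1][2]
        world.sizes["B"][name_b] = segs[-1][1] + segs[-1][2]
    # drop gaps the while-loop may have left dangling past the final block
    for sp in SPECIES:
        world.gaps[sp] = [
            g for g in world.gaps[sp] if g[1] + g[2] <= world.sizes[sp][g[0]]
        ]
    # chains, both directions
    for direction in ("AB", "BA"):
        chains = []
        for ci in range(world.config.n_chroms):
            segs = world.segments[ci]
            t_col, q_col = (0, 1) if direction == "AB" else (1, 0)
            t_name = world.chrom_name(direction[0], ci)
            q_name = world.chrom_name(direction[1], ci)
            blocks = []
            for i, seg in enumerate(segs):
                if i + 1 < len(segs):
                    nxt = segs[i + 1]
                    dt = nxt[t_col] - (seg[t_col] + seg[2])
                    dq = nxt[q_col] - (seg[q_col] + seg[2])
                else:
                    dt = dq = 0
                blocks.append((seg[2], dt, dq))
            chain = ChainAlignment(
                score=1000.0,
                t_name=t_name,
                t_size=world.sizes[direction[0]][t_name],
                t_strand="+",
                t_start=segs[0][t_col],
                t_end=segs[-1][t_col] + segs[-1][2],
                q_name=q_name,
                q_size=world.sizes[direction[1]][q_name],
                q_strand="+",
                q_start=segs[0][q_col],
                q_end=segs[-1][q_col] + segs[-1][2],
                blocks=blocks,
                chain_id=str(ci + 1),
            )
            chain.validate()
            chains.append(chain)
        world.chains[direction] = chains


def _build_genes(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    pair_counter = 0
    solo_a: list[SimGene] = []
    for ci in range(cfg.n_chroms):
        candidates = []
        for a_start, b_start, ln in world.segments[ci]:
            pos = a_start + cfg.segment_margin_bp
            while pos < a_start + ln - cfg.segment_margin_bp:
                candidates.append(pos)
                pos += cfg.tss_spacing_bp + int(rng.integers(0, 3000))
        if len(candidates) < cfg.genes_per_chrom:
            raise ValueError("infeasible packing: not enough gene positions")
        chosen = candidates[: cfg.genes_per_chrom]
        for pos in chosen:
            strand = "+" if rng.random() < 0.5 else "-"
            is_ortholog = rng.random() < cfg.ortholog_fraction
            tss2 = None
            if rng.random() < 0.3:
                delta = int(rng.integers(50, 301))
                tss2 = pos + delta if strand == "+" else pos - delta
            span = (min(pos, tss2 or pos) - 2000, max(pos, tss2 or pos) + 3000)
            chrom_a = world.chrom_name("A", ci)
            if is_ortholog:
                pair_counter += 1
                gid_a = f"GA{pair_counter:04d}"
                gid_b = f"GB{pair_counter:04d}"
                gene_a = SimGene(gid_a, "A", chrom_a, pos, strand, span, tss2,
                                 pair_idx=pair_counter - 1)
                pos_b = world.map_pos("A", ci, pos)
                tss2_b = world.map_pos("A", ci, tss2) if tss2 is not None else None
                span_b = (
                    min(pos_b, tss2_b or pos_b) - 2000,
                    max(pos_b, tss2_b or pos_b) + 3000,
                )
                gene_b = SimGene(
                    gid_b, "B", world.chrom_name("B", ci), pos_b, strand, span_b,
                    tss2_b, pair_idx=pair_counter - 1
                )
                world.genes["A"].append(gene_a)
                world.genes["B"].append(gene_b)
                world.pairs.append((gene_a, gene_b))
            else:
                gid = f"GAX{len(solo_a) + 1:03d}"
                gene_a = SimGene(gid, "A", chrom_a, pos, strand, span, tss2)
                world.genes["A"].append(gene_a)
                solo_a.append(gene_a)
    # B-only genes in B gaps (non-ortholog fillers)
    n_solo_b = len(solo_a)
    big_gaps = [g for g in world.gaps["B"] if g[2] >= 3000]
    for i in range(min(n_solo_b, len(big_gaps))):
        chrom, start, ln = big_gaps[i]
        tss = start + ln // 2
        strand = "+" if rng.random() < 0.5 else "-"
        world.genes["B"].append(
            SimGene(f"GBX{i + 1:03d}", "B", chrom, tss, strand, (tss - 500, tss + 800))
        )


def _assign_gene_classes(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    order = rng.permutation(len(world.pairs))
    wanted = (
        ["conserved"] * cfg.n_conserved_genes
        + ["alternative"] * cfg.n_alternative_genes
        + ["a_specific"] * cfg.n_a_specific_genes
        + ["b_specific"] * cfg.n_b_specific_genes
    )
    if len(wanted) > len(world.pairs):
        raise ValueError("infeasible packing: more classed genes than ortholog pairs")
    for idx, cls in zip(order, wanted):
        ga, gb = world.pairs[idx]
        ga.gene_class = gb.gene_class = cls
    for ga, gb in world.pairs:
        if ga.gene_class is None:
            ga.gene_class = gb.gene_class = "unbound"


def _site_interval(world: World, species: str, ci: int, centre: int) -> tuple[int, int]:
    w = world.config.site_width_bp
    return centre - w // 2, centre + w - w // 2


def _image_interval(
    world: World, species: str, ci: int, start: int, end: int
) -> tuple[str, int, int] | None:
    other = "B" if species == "A" else "A"
    lo = world.map_pos(species, ci, start)
    hi = world.map_pos(species, ci, end - 1)
    if lo is None or hi is None:
        return None
    return world.chrom_name(other, ci), lo, hi + 1


def _place_sites(world: World, rng: np.random.Generator) -> None:
    """Plant class-consistent sites at each classed gene's slots."""
    cfg = world.config
    conserved_hosts: list[tuple[SimGene, SimGene, list[int]]] = []

    def add_site(species, ci, gene, slot, cls, with_image=True):
        tss = gene.tss if gene.species == species else None
        assert tss is not None
        centre = gene.tss + slot
        start, end = _site_interval(world, species, ci, centre)
        image = _image_interval(world, species, ci, start, end) if with_image else None
        site = SimSite(
            species=species,
            chrom=gene.chrom,
            start=start,
            end=end,
            true_class=cls,
            host_gene=gene.gene_id,
            image=image,
        )
        world.sites.append(site)
        return site

    for ga, gb in world.pairs:
        cls = ga.gene_class
        ci = int(ga.chrom[-1]) - 1
        if cls == "unbound":
            continue
        free = list(rng.permutation(SLOTS))
        if cls == "conserved":
            n_pairs = int(rng.integers(1, 3))
            for _ in range(n_pairs):
                slot = free.pop()
                site_a = add_site("A", ci, ga, slot, SiteClass.CONSERVED.value)
                # partner site at the exact image coordinates
                img = site_a.image
                world.sites.append(
                    SimSite(
                        species="B",
                        chrom=img[0],
                        start=img[1],
                        end=img[2],
                        true_class=SiteClass.CONSERVED.value,
                        host_gene=gb.gene_id,
                        image=(ga.chrom, site_a.start, site_a.end),
                    )
                )
            if rng.random() < 0.25 and free:
                add_site("A", ci, ga, free.pop(), SiteClass.SPECIES_SPECIFIC.value)
            if rng.random() < 0.25 and free:
                slot = free.pop()
                centre_b = world.map_pos("A", ci, ga.tss + slot)
                site = SimSite(
                    species="B",
                    chrom=gb.chrom,
                    start=centre_b - cfg.site_width_bp // 2,
                    end=centre_b + cfg.site_width_bp - cfg.site_width_bp // 2,
                    true_class=SiteClass.SPECIES_SPECIFIC.value,
                    host_gene=gb.gene_id,
                    image=None,
                )
                site.image = _image_interval(world, "B", ci, site.start, site.end)
                world.sites.append(site)
            conserved_hosts.append((ga, gb, free))
        elif cls == "alternative":
            add_site("A", ci, ga, free.pop(), SiteClass.SPECIES_SPECIFIC.value)
            slot = free.pop()
            centre_b = world.map_pos("A", ci, ga.tss + slot)
            site = SimSite(
                species="B",
                chrom=gb.chrom,
                start=centre_b - cfg.site_width_bp // 2,
                end=centre_b + cfg.site_width_bp - cfg.site_width_bp // 2,
                true_class=SiteClass.SPECIES_SPECIFIC.value,
                host_gene=gb.gene_id,
                image=None,
            )
            site.image = _image_interval(world, "B", ci, site.start, site.end)
            world.sites.append(site)
        elif cls == "a_specific":
            n = 1 + int(rng.random() < 0.3)
            for _ in range(n):
                add_site("A", ci, ga, free.pop(), SiteClass.SPECIES_SPECIFIC.value)
        elif cls == "b_specific":
            n = 1 + int(rng.random() < 0.3)
            for _ in range(n):
                slot = free.pop()
                centre_b = world.map_pos("A", ci, ga.tss + slot)
                site = SimSite(
                    species="B",
                    chrom=gb.chrom,
                    start=centre_b - cfg.site_width_bp // 2,
                    end=centre_b + cfg.site_width_bp - cfg.site_width_bp // 2,
                    true_class=SiteClass.SPECIES_SPECIFIC.value,
                    host_gene=gb.gene_id,
                    image=None,
                )
                site.image = _image_interval(world, "B", ci, site.start, site.end)
                world.sites.append(site)
    # indeterminate sites on conserved hosts with free slots
    for species in SPECIES:
        hosts = [h for h in conserved_hosts if h[2]]
        take = min(cfg.n_indeterminate_sites, len(hosts))
        order = rng.permutation(len(hosts))[:take]
        for hi in order:
            ga, gb, free = hosts[hi]
            ci = int(ga.chrom[-1]) - 1
            slot = free.pop()
            if species == "A":
                centre = ga.tss + slot
                chrom = ga.chrom
                host = ga.gene_id
            else:
                centre = world.map_pos("A", ci, ga.tss + slot)
                chrom = gb.chrom
                host = gb.gene_id
            start, end = _site_interval(world, species, ci, centre)
            site = SimSite(
                species=species,
                chrom=chrom,
                start=start,
                end=end,
                true_class=SiteClass.INDETERMINATE.value,
                host_gene=host,
                image=_image_interval(world, species, ci, start, end),
            )
            world.sites.append(site)


def _nearest_gene(world: World, species: str, chrom: str, pos: int) -> SimGene | None:
    best = None
    best_key = None
    for g in world.genes[species]:
        if g.chrom != chrom:
            continue
        for tss in [g.tss] + ([g.tss2] if g.tss2 is not None else []):
            key = (abs(pos - tss), g.gene_id)
            if best_key is None or key < best_key:
                best_key, best = key, g
    return best


def _place_gap_sites(world: World, rng: np.random.Generator) -> None:
    """Sites in unalignable gaps; expected fraction matches the config."""
    cfg = world.config
    u = cfg.unalignable_fraction
    if u == 0:
        return
    margin = 1000 + cfg.site_width_bp // 2 + 200
    for species in SPECIES:
        k_alignable = sum(1 for s in world.sites if s.species == species)
        n_gap = int(rng.binomial(round(k_alignable / (1 - u)), u))
        usable = [g for g in world.gaps[species] if g[2] >= 2 * margin + 200]
        placed = 0
        tries = 0
        while placed < n_gap and tries < 50 * n_gap:
            tries += 1
            chrom, gstart, glen = usable[int(rng.integers(len(usable)))]
            centre = gstart + margin + int(rng.integers(glen - 2 * margin))
            host = _nearest_gene(world, species, chrom, centre)
            ok_class = host is None or host.pair_idx is None or host.gene_class in (
                "conserved",
                "alternative",
            )
            near = any(
                s.species == species and s.chrom == chrom and abs((s.start + s.end) // 2 - centre) < 3000
                for s in world.sites
            )
            if not ok_class or near:
                continue
            start, end = _site_interval(world, species, 0, centre)
            world.sites.append(
                SimSite(
                    species=species,
                    chrom=chrom,
                    start=start,
                    end=end,
                    true_class=SiteClass.NOT_LIFTED.value,
                    host_gene=host.gene_id if host else "",
                    image=None,
                )
            )
            placed += 1
        if placed < n_gap:
            logger.warning(
                "placed only %d of %d gap sites for species %s", placed, n_gap, species
            )


def _draw_q_high(cfg: SyntheticConfig, rng: np.random.Generator) -> float:
    neglog = rng.normal(cfg.q_neglog_mean, cfg.q_neglog_sd) if cfg.q_neglog_sd else cfg.q_neglog_mean
    return float(10.0 ** (-max(0.1, neglog)))


def _emit_peaks(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    for species in SPECIES:
        n_rep = cfg.replicates[species]
        reps: list[list[ScoredPeak]] = [[] for _ in range(n_rep)]
        own = sorted(
            (s for s in world.sites if s.species == species),
            key=lambda s: (s.chrom, s.start),
        )
        counter = 0
        for site in own:
            counter += 1
            for ridx in range(n_rep):
                j = cfg.peak_jitter_bp
                ds = int(rng.integers(-j, j + 1)) if j else 0
                de = int(rng.integers(-j, j + 1)) if j else 0
                start = max(0, site.start + ds)
                end = max(start + 50, site.end + de)
                reps[ridx].append(
                    ScoredPeak(
                        interval=GenomicInterval(site.chrom, start, end),
                        name=f"{species}_r{ridx + 1}_p{counter:05d}",
                        score=500,
                        signal=10.0,
                        p=1e-6,
                        q=_draw_q_high(cfg, rng),
                        replicate_id=f"{species}_rep{ridx + 1}",
                    )
                )
        # sub-threshold evidence in THIS species at images of the other
        # species' indeterminate sites
        other = "B" if species == "A" else "A"
        for site in sorted(
            (s for s in world.sites if s.species == other
             and s.true_class == SiteClass.INDETERMINATE.value),
            key=lambda s: (s.chrom, s.start),
        ):
            if site.image is None:
                continue
            chrom, start, end = site.image
            ridx = int(rng.integers(cfg.replicates[species]))
            counter += 1
            q = float(rng.uniform(0.02, 0.08)) if cfg.q_neglog_sd else 0.05
            reps[ridx].append(
                ScoredPeak(
                    interval=GenomicInterval(chrom, start, end),
                    name=f"{species}_r{ridx + 1}_w{counter:05d}",
                    score=100,
                    signal=2.0,
                    p=1e-3,
                    q=q,
                    replicate_id=f"{species}_rep{ridx + 1}",
                )
            )
        # weak decoys (q >= 0.1, excluded everywhere) and blacklisted decoys
        for ci in range(cfg.n_chroms):
            chrom = world.chrom_name(species, ci)
            for d in range(3):
                counter += 1
                pos = int(rng.integers(1000, world.sizes[species][chrom] - 1000))
                reps[0].append(
                    ScoredPeak(
                        interval=GenomicInterval(chrom, pos, pos + 150),
                        name=f"{species}_decoy{counter:05d}",
                        score=10,
                        signal=1.0,
                        p=0.05,
                        q=float(rng.uniform(0.15, 0.9)),
                        replicate_id=f"{species}_rep1",
                    )
                )
        margin = 1000 + cfg.site_width_bp
        usable = [g for g in world.gaps[species] if g[2] >= 2 * margin + 200]
        for b in range(2):
            if b >= len(usable):
                break
            chrom, gstart, glen = usable[-(b + 1)]
            centre = gstart + glen // 2
            near_site = any(
                s.species == species and s.chrom == chrom
                and abs((s.start + s.end) // 2 - centre) < 3000
                for s in world.sites
            )
            if near_site:
                continue
            counter += 1
            start, end = centre - 100, centre + 100
            for ridx in range(n_rep):
                reps[ridx].append(
                    ScoredPeak(
                        interval=GenomicInterval(chrom, start, end),
                        name=f"{species}_bl{counter:05d}",
                        score=400,
                        signal=8.0,
                        p=1e-6,
                        q=_draw_q_high(cfg, rng),
                        replicate_id=f"{species}_rep{ridx + 1}",
                    )
                )
            world.blacklist[species].append(
                GenomicInterval(chrom, start - 100, end + 100)
            )
        for r in reps:
            r.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        world.peaks[species] = reps


def _build_sequences(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    if not cfg.emit_sequence:
        world.sequences = {sp: {} for sp in SPECIES}
        return
    gc = cfg.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = world.pwm.consensus
    rc = consensus[::-1].translate(str.maketrans("ACGT", "TGCA"))
    for species in SPECIES:
        world.sequences[species] = {}
        for chrom, size in world.sizes[species].items():
            arr = rng.choice(np.arange(4), size=size, p=probs)
            world.sequences[species][chrom] = arr

    def plant(species, chrom, centre):
        motif = consensus if rng.random() < 0.5 else rc
        start = centre - len(motif) // 2
        arr = world.sequences[species][chrom]
        codes = np.frombuffer(motif.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        arr[start : start + len(motif)] = lut[codes]

    rates = cfg.motif_rates
    for site in world.sites:
        sp = site.species
        if site.true_class == SiteClass.SPECIES_SPECIFIC.value:
            own_rate = rates[f"specific_own_{sp}"]
            lifted_rate = rates[f"specific_lifted_{sp}"]
        else:
            own_rate = rates[f"conserved_{sp}"]
            lifted_rate = None
        centre = (site.start + site.end) // 2
        if rng.random() < own_rate:
            plant(sp, site.chrom, centre)
            site.motif_own = True
        if lifted_rate is not None and site.image is not None:
            if rng.random() < lifted_rate:
                chrom_i, s_i, e_i = site.image
                plant("B" if sp == "A" else "A", chrom_i, (s_i + e_i) // 2)
                site.motif_image = True
    # conserved partners: the same planted status must appear at the
    # image of an A-conserved site only through its own B partner site,
    # which was planted independently above.
    for species in SPECIES:
        world.sequences[species] = {
            chrom: "".join(BASES[arr])
            for chrom, arr in world.sequences[species].items()
        }


_TE_CLASS_MIX = {
    "specific": (["LINE1", "LTR", "SINE", "LINE2", "DNA"], [0.45, 0.3, 0.15, 0.05, 0.05]),
    "conserved": (["SINE", "LINE2", "DNA", "LINE1", "LTR"], [0.4, 0.2, 0.2, 0.1, 0.1]),
    "background": (["SINE", "LINE1", "LINE2", "LTR", "DNA", "other"],
                   [0.3, 0.25, 0.15, 0.15, 0.1, 0.05]),
}


def _place_tes(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    counter = 0
    for species in SPECIES:
        feats: list[TEFeature] = []
        mids: dict[str, list[int]] = {}
        own = sorted(
            (s for s in world.sites if s.species == species),
            key=lambda s: (s.chrom, s.start),
        )
        for site in own:
            mids.setdefault(site.chrom, []).append((site.start + site.end) // 2)
        for site in own:
            spec = site.true_class == SiteClass.SPECIES_SPECIFIC.value
            rate = cfg.te_rates[f"specific_{species}" if spec else f"conserved_{species}"]
            if rng.random() >= rate:
                continue
            counter += 1
            mid = (site.start + site.end) // 2
            length = int(rng.integers(300, 1501))
            start = mid - 20 - int(rng.integers(0, length - 40 + 1))
            classes, weights = _TE_CLASS_MIX["specific" if spec else "conserved"]
            te_class = TEClass(classes[int(rng.choice(len(classes), p=weights))])
            feat = TEFeature(
                GenomicInterval(site.chrom, max(0, start), start + length),
                te_class,
                f"TE{counter:05d}",
            )
            feats.append(feat)
            site.te = feat
        # background TEs, never enclosing a site's central window
        for chrom, size in world.sizes[species].items():
            site_mids = np.array(sorted(mids.get(chrom, [])))
            n_bg = int(round(size / 1e6 * cfg.te_background_per_mb))
            placed = 0
            while placed < n_bg:
                length = int(rng.integers(200, 1201))
                start = int(rng.integers(0, size - length))
                lo = np.searchsorted(site_mids, start + 20)
                hi = np.searchsorted(site_mids, start + length - 20, side="right")
                if hi > lo:  # would enclose a site's central window
                    continue
                counter += 1
                classes, weights = _TE_CLASS_MIX["background"]
                te_class = TEClass(classes[int(rng.choice(len(classes), p=weights))])
                feats.append(
                    TEFeature(
                        GenomicInterval(chrom, start, start + length),
                        te_class,
                        f"TE{counter:05d}",
                    )
                )
                placed += 1
        feats.sort(key=lambda f: (f.interval.chrom, f.interval.start))
        world.tes[species] = feats


def _emit_counts(world: World, rng: np.random.Generator) -> None:
    cfg = world.config
    effects = cfg.expression_effects
    # one species log2 effect per ortholog pair, by planted gene class
    pair_effect: dict[int, float] = {}
    for idx, (ga, _) in enumerate(world.pairs):
        mean, sd = effects[ga.gene_class]
        pair_effect[idx] = float(rng.normal(mean, sd))
    base_mean: dict[str, float] = {}
    for species in SPECIES:
        for g in sorted(world.genes[species], key=lambda g: g.gene_id):
            if g.pair_idx is not None and g.species == "B":
                # share the base with the A ortholog
                base_mean[g.gene_id] = base_mean[f"GA{g.pair_idx + 1:04d}"]
            else:
                base_mean[g.gene_id] = float(rng.lognormal(np.log(300), 1.0))
    r = 1.0 / cfg.nb_dispersion if cfg.nb_dispersion > 0 else None
    for species in SPECIES:
        genes = sorted(world.genes[species], key=lambda g: g.gene_id)
        samples = []
        studies = []
        for si in range(cfg.studies_per_species):
            for ri in range(cfg.samples_per_study):
                samples.append(f"{species}_s{si + 1}_r{ri + 1}")
                studies.append(f"study_{species}{si + 1}")
        mat = np.zeros((len(genes), len(samples)))
        for gi, g in enumerate(genes):
            eff = pair_effect.get(g.pair_idx, 0.0) if g.pair_idx is not None else 0.0
            sign = 0.5 if species == "A" else -0.5
            mu_gene = base_mean[g.gene_id] * 2.0 ** (sign * eff)
            for si in range(cfg.studies_per_species):
                batch = (
                    2.0 ** rng.normal(0.0, cfg.batch_log2_sd)
                    if cfg.batch_log2_sd > 0
                    else 1.0
                )
                mu = mu_gene * batch
                for ri in range(cfg.samples_per_study):
                    col = si * cfg.samples_per_study + ri
                    if r is None:
                        mat[gi, col] = round(mu)
                    else:
                        mat[gi, col] = rng.negative_binomial(r, r / (r + mu))
        world.counts[species] = pd.DataFrame(
            mat.astype(int), index=[g.gene_id for g in genes], columns=samples
        )
        world.counts[species].index.name = "gene_id"
        world.sample_meta[species] = pd.DataFrame(
            {"sample": samples, "species": species, "study": studies}
        )


def _derive_truth_genes(world: World) -> None:
    """Gene-class ground truth from the planted site classes.

    Applies the same classification rule a perfect observer would,
    then checks it against the planted intent (self-validation)."""
    per_gene: dict[str, dict] = {}
    low_evidence: dict[str, set] = {"A": set(), "B": set()}
    for s in world.sites:
        rec = per_gene.setdefault(
            s.host_gene, {"n": 0, "cons": False, "spec": False}
        )
        if s.host_gene:
            rec["n"] += 1
            rec["cons"] |= s.true_class == SiteClass.CONSERVED.value
            rec["spec"] |= s.true_class == SiteClass.SPECIES_SPECIFIC.value
        if s.true_class == SiteClass.INDETERMINATE.value and s.image is not None:
            # sub-threshold peak at the image, assigned to the partner gene
            other = "B" if s.species == "A" else "A"
            host = _nearest_gene(world, other, s.image[0], (s.image[1] + s.image[2]) // 2)
            if host is not None:
                low_evidence[other].add(host.gene_id)
    rows = []
    mismatches = 0
    for ga, gb in world.pairs:
        ia = per_gene.get(ga.gene_id, {"n": 0, "cons": False, "spec": False})
        ib = per_gene.get(gb.gene_id, {"n": 0, "cons": False, "spec": False})
        profile = GeneBindingProfile(
            gene_a=ga.gene_id,
            gene_b=gb.gene_id,
            n_sites_a=ia["n"],
            n_sites_b=ib["n"],
            has_conserved_a=ia["cons"],
            has_conserved_b=ib["cons"],
            has_specific_a=ia["spec"],
            has_specific_b=ib["spec"],
            any_evidence_a=ia["n"] > 0 or ga.gene_id in low_evidence["A"],
            any_evidence_b=ib["n"] > 0 or gb.gene_id in low_evidence["B"],
        )
        derived = classify_gene(profile).value
        if derived != ga.gene_class:
            mismatches += 1
        rows.append(
            {
                "gene_a": ga.gene_id,
                "gene_b": gb.gene_id,
                "true_class": derived,
                "planted_class": ga.gene_class,
                "n_sites_a": ia["n"],
                "n_sites_b": ib["n"],
                "dn": profile.dn,
            }
        )
    if mismatches:
        raise AssertionError(
            f"self-validation failed: {mismatches} planted gene classes are "
            "inconsistent with the planted sites"
        )
    world.truth_genes = pd.DataFrame(rows)
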