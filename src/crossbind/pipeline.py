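"""End-to-end orchestration: consensus -> lift -> classify -> genes ->
expression -> motifs -> TE statistics, with report tables on disk.

Every stage is a pure function of (inputs, parameters, seed); rerunning
with the same seed reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chain import ChainIndex, LiftStatus, lift_interval, parse_chain
from .classify import (
    assign_sites_to_genes,
    assign_to_genes,
    build_gene_profiles,
    classify_all_sites,
    classify_genes,
)
from .consensus import (
    ConsensusSite,
    high_confidence_consensus,
    low_confidence_union,
    remove_blacklisted,
)
from .expression import (
    class_divergence_stats,
    divergence_table,
    extreme_tail_enrichment,
    normalize_and_center,
    ratio_vs_count_difference,
)
from .intervals import GenomicInterval
from .io import (
    read_bed6,
    read_chrom_sizes,
    read_fasta,
    read_gtf_genes,
    read_narrowpeak,
    read_ortholog_table,
)
from .motifs import known_motif_enrichment, load_pwm_file, motif_proportion, scan_sites
from .te import (
    TEIndex,
    chisq_independence,
    class_by_teclass_table,
    overlap_table,
    permutation_chisq,
    read_te_bed,
    te_attribution,
    tss_distance_tests,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    q_high: float = 0.01
    q_low: float = 0.1
    pad: int = 1000
    fimo_p: float = 0.004
    te_window: int = 40
    n_perm: int = 10_000
    tail_cutoff: float = 5.0
    dn_clamp: int = 5
    consensus_mode: str = "union"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.q_high < self.q_low):
            raise ValueError("need 0 < q_high < q_low")
        for name in ("pad", "fimo_p", "te_window", "n_perm", "tail_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Inputs:
    """In-memory bundle of everything the analysis consumes."""

    peaks: dict[str, list[list]]  # species -> replicate peak lists
    blacklist: dict[str, list[GenomicInterval]]
    chains_ab: ChainIndex
    chains_ba: ChainIndex
    genes: dict[str, list]
    orthologs: pd.DataFrame
    sizes: dict[str, dict[str, int]]
    tes: dict[str, list]
    genomes: dict[str, dict[str, str]]
    counts: dict[str, pd.DataFrame]
    sample_meta: dict[str, pd.DataFrame]
    pwms: list


def inputs_from_world(world) -> Inputs:
    """Bundle a synthetic world without a disk round-trip."""
    return Inputs(
        peaks=world.peaks,
        blacklist=world.blacklist,
        chains_ab=world.chain_index("AB"),
        chains_ba=world.chain_index("BA"),
        genes={sp: world.gene_models(sp) for sp in ("A", "B")},
        orthologs=world.ortholog_table(),
        sizes=world.sizes,
        tes=world.tes,
        genomes=world.sequences,
        counts=world.counts,
        sample_meta=world.sample_meta,
        pwms=[world.pwm],
    )


def _require(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"stage {stage}: required input {p} is missing")
    return p


def load_inputs(cfg: dict) -> Inputs:
    """Read every input named in a run-config mapping (see docs)."""
    peaks = {}
    for sp, key in (("A", "peaks_a"), ("B", "peaks_b")):
        peaks[sp] = [
            read_narrowpeak(_require(p, "peak_consensus"), replicate_id=f"{sp}_rep{i+1}")
            for i, p in enumerate(cfg[key])
        ]
    blacklist = {
        sp: (read_bed6(_require(cfg[k], "peak_consensus")) if cfg.get(k) else [])
        for sp, k in (("A", "blacklist_a"), ("B", "blacklist_b"))
    }
    chains_ab = ChainIndex(parse_chain(_require(cfg["chain_ab"], "chain_lift")))
    chains_ba = ChainIndex(parse_chain(_require(cfg["chain_ba"], "chain_lift")))
    genes = {
        "A": read_gtf_genes(_require(cfg["gtf_a"], "site_gene_classify")),
        "B": read_gtf_genes(_require(cfg["gtf_b"], "site_gene_classify")),
    }
    orthologs = read_ortholog_table(_require(cfg["orthologs"], "site_gene_classify"))
    sizes = {
        "A": read_chrom_sizes(_require(cfg["sizes_a"], "genome_core")),
        "B": read_chrom_sizes(_require(cfg["sizes_b"], "genome_core")),
    }
    tes = {
        "A": read_te_bed(_require(cfg["te_a"], "te_enrichment")),
        "B": read_te_bed(_require(cfg["te_b"], "te_enrichment")),
    }
    genomes = {
        "A": read_fasta(_require(cfg["genome_a"], "motif_analysis")),
        "B": read_fasta(_require(cfg["genome_b"], "motif_analysis")),
    }
    counts = {}
    meta = {}
    for sp, ck, mk in (("A", "counts_a", "samples_a"), ("B", "counts_b", "samples_b")):
        counts[sp] = pd.read_csv(
            _require(cfg[ck], "expression_divergence"), sep="\t", index_col=0,
            comment="#",
        )
        meta[sp] = pd.read_csv(
            _require(cfg[mk], "expression_divergence"), sep="\t", comment="#"
        )
    pwms = load_pwm_file(_require(cfg["pwms"], "motif_analysis"))
    return Inputs(
        peaks=peaks,
        blacklist=blacklist,
        chains_ab=chains_ab,
        chains_ba=chains_ba,
        genes=genes,
        orthologs=orthologs,
        sizes=sizes,
        tes=tes,
        genomes=genomes,
        counts=counts,
        sample_meta=meta,
        pwms=pwms,
    )


def analyse(inputs: Inputs, params: PipelineParams | None = None) -> dict:
    """Run the full analysis; returns a report dict of tables and stats."""
    params = params or PipelineParams()
    report: dict = {"params": asdict(params), "version": __version__}

    # --- consensus ---------------------------------------------------------
    high: dict[str, list[ConsensusSite]] = {}
    low: dict[str, list[GenomicInterval]] = {}
    for sp in ("A", "B"):
        sites = high_confidence_consensus(
            inputs.peaks[sp], params.q_high, species=sp, mode=params.consensus_mode
        )
        high[sp] = remove_blacklisted(sites, inputs.blacklist[sp])
        # artifact regions cannot count as binding evidence either
        low[sp] = remove_blacklisted(
            low_confidence_union(inputs.peaks[sp], params.q_low),
            inputs.blacklist[sp],
        )

    # --- lift + site classification ---------------------------------------
    table_a, table_b, site_summary = classify_all_sites(
        high["A"],
        high["B"],
        low["A"],
        low["B"],
        inputs.chains_ab,
        inputs.chains_ba,
        pad=params.pad,
        sizes_a=inputs.sizes["A"],
        sizes_b=inputs.sizes["B"],
    )
    report["site_table"] = {"A": table_a, "B": table_b}
    report["site_summary"] = site_summary

    # --- gene assignment and classification --------------------------------
    assign = {}
    low_assign = {}
    for sp, table in (("A", table_a), ("B", table_b)):
        assign[sp] = assign_sites_to_genes(high[sp], inputs.genes[sp])
        low_assign[sp] = assign_to_genes(
            {f"{sp}_low_{i + 1:05d}": iv for i, iv in enumerate(low[sp])},
            inputs.genes[sp],
        )
    profiles = build_gene_profiles(
        inputs.orthologs,
        table_a,
        table_b,
        assign["A"],
        assign["B"],
        low_assign["A"],
        low_assign["B"],
    )
    gene_table = classify_genes(profiles)
    report["gene_table"] = gene_table
    bound = gene_table[gene_table["gene_class"] != "unbound"]
    gene_summary = (
        bound["gene_class"].value_counts().rename_axis("gene_class").reset_index(name="n")
    )
    gene_summary["proportion"] = gene_summary["n"] / gene_summary["n"].sum()
    report["gene_summary"] = gene_summary

    # --- expression divergence --------------------------------------------
    log_a, log_b = normalize_and_center(
        inputs.counts["A"], inputs.sample_meta["A"],
        inputs.counts["B"], inputs.sample_meta["B"],
    )
    records = divergence_table(
        log_a, inputs.sample_meta["A"], log_b, inputs.sample_meta["B"], inputs.orthologs
    )
    records = records.merge(
        gene_table[["gene_a", "gene_b", "gene_class", "dn"]],
        on=["gene_a", "gene_b"],
        how="left",
    )
    records["gene_class"] = records["gene_class"].fillna("unbound")
    report["divergence"] = records
    report["class_stats"] = class_divergence_stats(records)
    report["tail_enrichment"] = extreme_tail_enrichment(records, params.tail_cutoff)
    both_bound = records[records["gene_class"].isin(["conserved", "alternative"])]
    try:
        reg = ratio_vs_count_difference(both_bound)
        report["regression"] = asdict(reg)
    except ValueError as exc:
        logger.warning("count-difference regression skipped: %s", exc)
        report["regression"] = {"error": str(exc)}

    # --- motif analysis ----------------------------------------------------
    focal = inputs.pwms[0]
    prop_rows = []
    enrich_cols = {}
    for sp, table in (("A", table_a), ("B", table_b)):
        other = "B" if sp == "A" else "A"
        chains = inputs.chains_ab if sp == "A" else inputs.chains_ba
        site_iv = {s.site_id: s.interval for s in high[sp]}
        sets: dict[str, dict[str, str]] = {}
        sets[f"{sp}_all"] = {
            sid: inputs.genomes[sp][iv.chrom][iv.start : iv.end]
            for sid, iv in site_iv.items()
        }
        for cls, label in (("conserved", "conserved"), ("species_specific", "specific")):
            ids = table.loc[table["site_class"] == cls, "site_id"]
            sets[f"{sp}_{label}"] = {sid: sets[f"{sp}_all"][sid] for sid in ids}
        # lifted loci of specific sites, unpadded lift into the other genome
        lifted = {}
        for sid in table.loc[table["site_class"] == "species_specific", "site_id"]:
            res = lift_interval(site_iv[sid], chains)
            if res.status is LiftStatus.MAPPED:
                iv = res.mapped_interval
                lifted[f"{sid}_lift"] = inputs.genomes[other][iv.chrom][iv.start : iv.end]
        sets[f"{sp}_specific_lifted"] = lifted
        for name, seqs in sets.items():
            if not seqs:
                continue
            _, flags = scan_sites(seqs, focal, params.fimo_p)
            est = motif_proportion(flags)
            prop_rows.append(
                {
                    "site_set": name,
                    "k": est.k,
                    "n": est.n,
                    "proportion": est.proportion,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        if sets[f"{sp}_specific"] and sets[f"{sp}_conserved"]:
            enr = known_motif_enrichment(
                sets[f"{sp}_specific"], sets[f"{sp}_conserved"], inputs.pwms,
                params.fimo_p,
            )
            enrich_cols[f"{sp}_specific"] = enr.set_index("motif")["neglog10_p"]
            enr2 = known_motif_enrichment(
                sets[f"{sp}_conserved"], sets[f"{sp}_specific"], inputs.pwms,
                params.fimo_p,
            )
            enrich_cols[f"{sp}_conserved"] = enr2.set_index("motif")["neglog10_p"]
    report["motif_proportions"] = pd.DataFrame(prop_rows)
    report["motif_enrichment"] = (
        pd.DataFrame(enrich_cols) if enrich_cols else pd.DataFrame()
    )

    # --- TE statistics ------------------------------------------------------
    te_stats = {}
    rng_seed = params.seed
    for sp, table in (("A", table_a), ("B", table_b)):
        te_idx = TEIndex(inputs.tes[sp])
        site_iv = {s.site_id: s.interval for s in high[sp]}
        attribution = te_attribution(
            site_iv, te_idx, params.te_window, inputs.sizes[sp]
        )
        cls = table.set_index("site_id")["site_class"]
        attribution["site_class"] = attribution["site_id"].map(cls)
        comp = attribution[
            attribution["site_class"].isin(["conserved", "species_specific"])
        ]
        tab = overlap_table(comp["site_class"], comp["te_overlap"])
        try:
            contingency = chisq_independence(tab)
        except ValueError as exc:  # degenerate table (e.g. no TE overlap at all)
            logger.warning("TE chi-square skipped for %s: %s", sp, exc)
            contingency = None
        perm = permutation_chisq(
            comp["site_class"].to_numpy(),
            comp["te_overlap"].to_numpy(),
            n_permutations=params.n_perm,
            seed=rng_seed + (0 if sp == "A" else 1),
        )
        try:
            by_class = class_by_teclass_table(
                comp.set_index("site_id")["site_class"], comp
            )
        except ValueError as exc:
            logger.warning("TE class table skipped for %s: %s", sp, exc)
            by_class = None
        # TSS-distance profile per site class (Kruskal-Wallis on |distance|)
        merged = table.merge(
            assign[sp], left_on="site_id", right_on="feature_id"
        )
        groups = {
            c: g["tss_distance"].tolist()
            for c, g in merged.groupby("site_class")
            if c in ("conserved", "species_specific", "indeterminate")
        }
        try:
            dist = tss_distance_tests(groups)
        except ValueError as exc:
            dist = {"error": str(exc)}
        te_stats[sp] = {
            "attribution": attribution,
            "overlap_table": tab,
            "chi2": contingency.chi2 if contingency else None,
            "p_analytic": contingency.p_analytic if contingency else None,
            "residuals": contingency.std_residuals if contingency else None,
            "permutation": perm,
            "class_by_teclass": by_class,
            "tss_distance": dist,
        }
    report["te"] = te_stats
    return report


def _df_to_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_report(report: dict, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in ("A", "B"):
        _df_to_tsv(report["site_table"][sp], out / f"site_classes_{sp}.tsv")
    _df_to_tsv(report["site_summary"], out / "site_class_summary.tsv")
    _df_to_tsv(report["gene_table"], out / "gene_classes.tsv")
    _df_to_tsv(report["gene_summary"], out / "gene_class_summary.tsv")
    _df_to_tsv(report["divergence"], out / "expression_divergence.tsv")
    _df_to_tsv(report["class_stats"], out / "class_divergence_stats.tsv")
    _df_to_tsv(report["tail_enrichment"], out / "tail_enrichment.tsv")
    _df_to_tsv(report["motif_proportions"], out / "motif_proportions.tsv")
    if len(report["motif_enrichment"]):
        _df_to_tsv(report["motif_enrichment"], out / "motif_enrichment.tsv", index=True)
    for sp in ("A", "B"):
        te = report["te"][sp]
        _df_to_tsv(te["attribution"], out / f"te_attribution_{sp}.tsv")
        _df_to_tsv(te["overlap_table"], out / f"te_contingency_{sp}.tsv", index=True)
        if te["residuals"] is not None:
            _df_to_tsv(te["residuals"], out / f"te_residuals_{sp}.tsv", index=True)
        if te["class_by_teclass"] is not None:
            _df_to_tsv(
                te["class_by_teclass"].observed, out / f"te_by_class_{sp}.tsv",
                index=True,
            )
        perm = te["permutation"]
        (out / f"te_permutation_{sp}.json").write_text(
            json.dumps(
                {
                    "observed_chi2": round(perm.observed_chi2, 6),
                    "analytic_chi2": round(te["chi2"], 6) if te["chi2"] is not None
                    else None,
                    "p_analytic": float(f"{te['p_analytic']:.6g}")
                    if te["p_analytic"] is not None else None,
                    "n_permutations": perm.n_permutations,
                    "p_empirical": round(perm.p_empirical, 8),
                    "p_mid": round(perm.p_mid, 8),
                    "seed": perm.seed,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        dist = te["tss_distance"]
        if "bins" in dist:
            _df_to_tsv(dist["bins"], out / f"tss_distance_bins_{sp}.tsv")
            (out / f"tss_distance_{sp}.json").write_text(
                json.dumps(
                    {"H": round(dist["H"], 6), "p": float(f"{dist['p']:.6g}"),
                     "groups": dist["groups"]},
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            )
    (out / "regression.json").write_text(
        json.dumps(
            {k: (round(v, 8) if isinstance(v, float) else v)
             for k, v in report["regression"].items()},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    (out / "run_log.json").write_text(
        json.dumps(
            {"params": report["params"], "version": report["version"]},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return out


def run_all(config_path: str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """Load a YAML run config, execute every stage, write the report."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(config_path).parent
    for key, value in list(cfg.items()):
        if isinstance(value, str) and ("/" in value or "." in value) and key != "seed":
            cfg[key] = str((base / value)) if not Path(value).is_absolute() else value
        if isinstance(value, list):
            cfg[key] = [
                str(base / v) if not Path(v).is_absolute() else v for v in value
            ]
    param_keys = {f.name for f in PipelineParams.__dataclass_fields__.values()}
    params = PipelineParams(
        **{k: v for k, v in cfg.items() if k in param_keys}
    )
    if seed is not None:
        params.seed = seed
    inputs = load_inputs(cfg)
    report = analyse(inputs, params)
    write_report(report, outdir)
    return report
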