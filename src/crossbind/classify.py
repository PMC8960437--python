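"""Conservation classification of binding sites and target genes.

A high-confidence site in one species is lifted (with 1 kb padding) to
the other species' genome and called

* ``conserved``        — its image overlaps a high-confidence site there;
* ``species_specific`` — its image overlaps no binding evidence at all
  (nothing in the union of q < 0.1 peaks across replicates);
* ``indeterminate``    — in between (sub-threshold evidence);
* ``not_lifted``       — no aligned base in the other genome.

Gene-level classes on 1:1 ortholog pairs follow from the classes of the
sites assigned (nearest TSS to site midpoint) to each gene:
``conserved`` (a conserved site on both sides), ``alternative`` (bound
on both sides through species-specific sites, no conserved site),
``a_specific``/``b_specific`` (high-confidence binding on one side and
no evidence of any kind on the other), else ``unbound``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .chain import ChainIndex, LiftResult, LiftStatus, lift_padded_site
from .consensus import ConsensusSite
from .intervals import GeneModel, GenomicInterval, IntervalIndex, nearest_tss

logger = logging.getLogger(__name__)


class SiteClass(str, Enum):
    CONSERVED = "conserved"
    SPECIES_SPECIFIC = "species_specific"
    INDETERMINATE = "indeterminate"
    NOT_LIFTED = "not_lifted"


class GeneClass(str, Enum):
    CONSERVED = "conserved"
    ALTERNATIVE = "alternative"
    A_SPECIFIC = "a_specific"
    B_SPECIFIC = "b_specific"
    UNBOUND = "unbound"


def classify_site(
    site: ConsensusSite,
    lift: LiftResult,
    other_high: IntervalIndex,
    other_low: IntervalIndex,
) -> SiteClass:
    """Classify one high-confidence site given its lifted image."""
    if lift.status is not LiftStatus.MAPPED:
        return SiteClass.NOT_LIFTED
    image = lift.mapped_interval
    if other_high.any_overlap(image):
        return SiteClass.CONSERVED
    if not other_low.any_overlap(image):
        return SiteClass.SPECIES_SPECIFIC
    return SiteClass.INDETERMINATE


def classify_sites_one_direction(
    sites: list[ConsensusSite],
    chains: ChainIndex,
    other_high: list[ConsensusSite],
    other_low: list[GenomicInterval],
    pad: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Site table for one species: class and lifted coordinates."""
    high_idx = IntervalIndex([s.interval for s in other_high]) if other_high else _EMPTY
    low_idx = IntervalIndex(other_low) if other_low else _EMPTY
    rows = []
    for site in sites:
        lift = lift_padded_site(site.interval, chains, pad=pad, chrom_sizes=chrom_sizes)
        cls = classify_site(site, lift, high_idx, low_idx)
        img = lift.mapped_interval
        rows.append(
            {
                "site_id": site.site_id,
                "chrom": site.interval.chrom,
                "start": site.interval.start,
                "end": site.interval.end,
                "site_class": cls.value,
                "lift_status": lift.status.value,
                "mapped_fraction": round(lift.mapped_fraction, 6),
                "lifted_chrom": img.chrom if img else "",
                "lifted_start": img.start if img else -1,
                "lifted_end": img.end if img else -1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "chrom",
            "start",
            "end",
            "site_class",
            "lift_status",
            "mapped_fraction",
            "lifted_chrom",
            "lifted_start",
            "lifted_end",
        ],
    )


class _Empty:
    def any_overlap(self, query) -> bool:
        return False


_EMPTY = _Empty()


def classify_all_sites(
    sites_a: list[ConsensusSite],
    sites_b: list[ConsensusSite],
    low_a: list[GenomicInterval],
    low_b: list[GenomicInterval],
    chains_ab: ChainIndex,
    chains_ba: ChainIndex,
    pad: int = 1000,
    sizes_a: dict[str, int] | None = None,
    sizes_b: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Classify both species' site sets independently.

    Returns (table_a, table_b, summary); the summary counts classes and
    the fraction of sites whose padded coordinates lifted at all.
    """
    tab_a = classify_sites_one_direction(sites_a, chains_ab, sites_b, low_b, pad, sizes_a)
    tab_b = classify_sites_one_direction(sites_b, chains_ba, sites_a, low_a, pad, sizes_b)
    rows = []
    for species, tab in (("A", tab_a), ("B", tab_b)):
        n = len(tab)
        counts = tab["site_class"].value_counts()
        lifted = int((tab["lift_status"] == LiftStatus.MAPPED.value).sum())
        row = {"species": species, "n_sites": n, "fraction_lifted": lifted / n if n else 0.0}
        for cls in SiteClass:
            row[f"n_{cls.value}"] = int(counts.get(cls.value, 0))
        rows.append(row)
    return tab_a, tab_b, pd.DataFrame(rows)


def assign_to_genes(
    intervals: dict[str, GenomicInterval], genes: list[GeneModel]
) -> pd.DataFrame:
    """Nearest-TSS gene assignment of interval midpoints.

    Features on chromosomes without genes get an empty gene_id and are
    excluded from gene-level statistics downstream.
    """
    rows = []
    for key, iv in intervals.items():
        hit = nearest_tss(iv.midpoint, iv.chrom, genes)
        if hit is None:
            rows.append({"feature_id": key, "gene_id": "", "tss_distance": 0})
        else:
            rows.append(
                {"feature_id": key, "gene_id": hit.gene_id, "tss_distance": hit.distance}
            )
    return pd.DataFrame(rows, columns=["feature_id", "gene_id", "tss_distance"])


def assign_sites_to_genes(
    sites: list[ConsensusSite], genes: list[GeneModel]
) -> pd.DataFrame:
    return assign_to_genes({s.site_id: s.interval for s in sites}, genes)


@dataclass
class GeneBindingProfile:
    gene_a: str
    gene_b: str
    n_sites_a: int
    n_sites_b: int
    has_conserved_a: bool
    has_conserved_b: bool
    has_specific_a: bool
    has_specific_b: bool
    any_evidence_a: bool
    any_evidence_b: bool

    @property
    def dn_raw(self) -> int:
        return self.n_sites_a - self.n_sites_b

    @property
    def dn(self) -> int:
        """Binding-site count difference clamped to [-5, +5]."""
        return max(-5, min(5, self.dn_raw))


def build_gene_profiles(
    pairs: pd.DataFrame,
    site_table_a: pd.DataFrame,
    site_table_b: pd.DataFrame,
    assign_a: pd.DataFrame,
    assign_b: pd.DataFrame,
    low_assign_a: pd.DataFrame | None = None,
    low_assign_b: pd.DataFrame | None = None,
) -> list[GeneBindingProfile]:
    """Aggregate site classes per 1:1 ortholog pair.

    ``low_assign_*`` are gene assignments of the low-confidence union
    intervals and define "any evidence of binding" at gene level; when
    omitted, high-confidence sites alone count as evidence.
    """
    def per_gene(table: pd.DataFrame, assign: pd.DataFrame):
        merged = table.merge(assign, left_on="site_id", right_on="feature_id")
        merged = merged[merged["gene_id"] != ""]
        info: dict[str, dict] = {}
        for gene_id, grp in merged.groupby("gene_id"):
            classes = set(grp["site_class"])
            info[gene_id] = {
                "n": len(grp),
                "cons": SiteClass.CONSERVED.value in classes,
                "spec": SiteClass.SPECIES_SPECIFIC.value in classes,
            }
        return info

    info_a = per_gene(site_table_a, assign_a)
    info_b = per_gene(site_table_b, assign_b)
    low_genes_a = (
        set(low_assign_a.loc[low_assign_a["gene_id"] != "", "gene_id"])
        if low_assign_a is not None
        else set()
    )
    low_genes_b = (
        set(low_assign_b.loc[low_assign_b["gene_id"] != "", "gene_id"])
        if low_assign_b is not None
        else set()
    )
    profiles = []
    for _, row in pairs.iterrows():
        ga, gb = row["gene_a"], row["gene_b"]
        ia = info_a.get(ga, {"n": 0, "cons": False, "spec": False})
        ib = info_b.get(gb, {"n": 0, "cons": False, "spec": False})
        profiles.append(
            GeneBindingProfile(
                gene_a=ga,
                gene_b=gb,
                n_sites_a=ia["n"],
                n_sites_b=ib["n"],
                has_conserved_a=ia["cons"],
                has_conserved_b=ib["cons"],
                has_specific_a=ia["spec"],
                has_specific_b=ib["spec"],
                any_evidence_a=ia["n"] > 0 or ga in low_genes_a,
                any_evidence_b=ib["n"] > 0 or gb in low_genes_b,
            )
        )
    return profiles


def classify_gene(p: GeneBindingProfile) -> GeneClass:
    if p.has_conserved_a and p.has_conserved_b:
        return GeneClass.CONSERVED
    if (
        p.has_specific_a
        and p.has_specific_b
        and not p.has_conserved_a
        and not p.has_conserved_b
    ):
        return GeneClass.ALTERNATIVE
    if p.n_sites_a > 0 and not p.any_evidence_b and not p.has_conserved_a:
        return GeneClass.A_SPECIFIC
    if p.n_sites_b > 0 and not p.any_evidence_a and not p.has_conserved_b:
        return GeneClass.B_SPECIFIC
    return GeneClass.UNBOUND


def classify_genes(profiles: list[GeneBindingProfile]) -> pd.DataFrame:
    """Gene-class table over ortholog pairs.

    ``unbound`` is the catch-all for pairs fitting none of the four
    definitions; the ``bound_but_unclassified`` flag marks pairs that do
    carry high-confidence sites yet fail every definition (excluded
    from class statistics, like indeterminate sites)."""
    rows = []
    for p in profiles:
        cls = classify_gene(p)
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "gene_class": cls.value,
                "n_sites_a": p.n_sites_a,
                "n_sites_b": p.n_sites_b,
                "dn": p.dn,
                "dn_raw": p.dn_raw,
                "bound_but_unclassified": cls is GeneClass.UNBOUND
                and (p.n_sites_a > 0 or p.n_sites_b > 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "gene_class",
            "n_sites_a",
            "n_sites_b",
            "dn",
            "dn_raw",
            "bound_but_unclassified",
        ],
    )
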