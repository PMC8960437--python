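"""Transposable-element overlap statistics for binding-site classes.

A site "overlaps" a TE only when its central 40 bp window is fully
enclosed by a single TE interval.  Class-by-overlap contingency tables
are tested with Pearson's chi-square (no continuity correction, so the
observed statistic is exchangeable with the permutation null) plus a
label-permutation test, and cell-wise standardized residuals
(O-E)/sqrt(E) localise the enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval, central_window

logger = logging.getLogger(__name__)


class TEClass(str, Enum):
    LINE1 = "LINE1"
    LINE2 = "LINE2"
    LTR = "LTR"
    SINE = "SINE"
    DNA = "DNA"
    OTHER = "other"


@dataclass
class TEFeature:
    interval: GenomicInterval
    te_class: TEClass
    name: str = "."


def normalise_te_class(label: str) -> TEClass:
    label = label.strip()
    for cls in TEClass:
        if cls.value.lower() == label.lower():
            return cls
    # RepeatMasker-style coarse classes
    upper = label.upper()
    if upper.startswith("L1") or upper == "LINE/L1":
        return TEClass.LINE1
    if upper.startswith("L2") or upper == "LINE/L2":
        return TEClass.LINE2
    if upper.startswith("LTR"):
        return TEClass.LTR
    if upper.startswith("SINE") or upper in ("ALU", "B1", "B2"):
        return TEClass.SINE
    if upper.startswith("DNA"):
        return TEClass.DNA
    return TEClass.OTHER


def read_te_bed(source, class_map: dict[str, str] | None = None) -> list[TEFeature]:
    """BED6 TE track; repeat class from a ``name#class`` suffix or map."""
    features: list[TEFeature] = []
    close = False
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh = source
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 4:
                raise ValueError(f"TE BED line {lineno}: need >=4 columns")
            name = cols[3]
            if "#" in name:
                base, _, cls_label = name.partition("#")
            else:
                base, cls_label = name, (class_map or {}).get(name, "other")
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            features.append(
                TEFeature(
                    GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand),
                    normalise_te_class(cls_label),
                    base,
                )
            )
    finally:
        if close:
            fh.close()
    return features


class TEIndex:
    """Per-chromosome interval tree over TE features."""

    def __init__(self, features: list[TEFeature]):
        self.trees: dict[str, IntervalTree] = {}
        for feat in features:
            tree = self.trees.setdefault(feat.interval.chrom, IntervalTree())
            tree.addi(feat.interval.start, feat.interval.end, feat)

    def enclosing(self, window: GenomicInterval) -> TEFeature | None:
        """Longest single TE fully containing the window (tie: class name)."""
        tree = self.trees.get(window.chrom)
        if tree is None:
            return None
        hits = [
            h.data
            for h in tree.overlap(window.start, window.end)
            if h.begin <= window.start and h.end >= window.end
        ]
        if not hits:
            return None
        if len(hits) > 1:
            logger.debug("window %s enclosed by %d TEs", window, len(hits))
        hits.sort(key=lambda f: (-f.interval.length, f.te_class.value, f.name))
        return hits[0]


def te_overlap_flag(
    site: GenomicInterval,
    te_index: TEIndex,
    window_bp: int = 40,
    chrom_size: int | None = None,
) -> bool:
    """True iff one TE fully encloses the site's central window."""
    window = central_window(site, window_bp, chrom_size)
    return te_index.enclosing(window) is not None


def te_attribution(
    sites: dict[str, GenomicInterval],
    te_index: TEIndex,
    window_bp: int = 40,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-site enclosure flag and the class of the enclosing TE."""
    rows = []
    for site_id in sorted(sites):
        iv = sites[site_id]
        size = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        feat = te_index.enclosing(central_window(iv, window_bp, size))
        rows.append(
            {
                "site_id": site_id,
                "te_overlap": feat is not None,
                "te_class": feat.te_class.value if feat else "none",
                "te_name": feat.name if feat else "",
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "te_overlap", "te_class", "te_name"])


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p_analytic: float
    std_residuals: pd.DataFrame


def chisq_independence(
    table: pd.DataFrame | np.ndarray, residuals: str = "pearson"
) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    ``residuals='pearson'`` gives (O-E)/sqrt(E); ``'relative'`` gives
    the literal (O-E)/E variant.
    """
    obs = pd.DataFrame(table).astype(float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, expected = stats.chi2_contingency(obs.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    if residuals == "pearson":
        resid = (obs - exp) / np.sqrt(exp)
    elif residuals == "relative":
        resid = (obs - exp) / exp
    else:
        raise ValueError(f"unknown residual type {residuals!r}")
    return ContingencyResult(obs, exp, float(chi2), int(df), float(p), resid)


def overlap_table(classes, flags) -> pd.DataFrame:
    """site-class x {TE, no TE} count table."""
    classes = pd.Series(list(classes), name="site_class")
    flags = pd.Series(list(flags), name="te_overlap").astype(bool)
    tab = pd.crosstab(classes, flags)
    tab = tab.reindex(columns=[True, False], fill_value=0)
    tab.columns = ["te", "no_te"]
    return tab.sort_index()


@dataclass
class PermutationResult:
    observed_chi2: float
    n_permutations: int
    n_ge_observed: int
    p_empirical: float  # add-one, ties counted: (1 + #{null >= obs}) / (n + 1)
    p_mid: float  # mid-p (half weight on ties): calibrated under discrete nulls
    null_mean: float
    null_sd: float
    seed: int


def _chi2_from_true_counts(
    k_true: np.ndarray, row_tot: np.ndarray, total_true: int, n: int
) -> float:
    """Pearson chi2 of the classes x {flag, not} table from per-class
    TRUE counts; margins are fixed so expecteds are precomputable."""
    e_true = row_tot * (total_true / n)
    e_false = row_tot - e_true
    o_false = row_tot - k_true
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (k_true - e_true) ** 2 / e_true + (o_false - e_false) ** 2 / e_false
    return float(np.nansum(terms))


def permutation_chisq(
    classes, flags, n_permutations: int = 10_000, seed: int = 0
) -> PermutationResult:
    """Label-permutation null for the class-by-overlap chi-square.

    The boolean overlap flags are shuffled against the fixed class
    labels; the empirical p uses the add-one correction
    (1 + #{null >= observed}) / (n + 1).
    """
    classes = np.asarray(list(classes))
    flags = np.asarray(list(flags), dtype=bool)
    labels, class_idx = np.unique(classes, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need >=2 site classes")
    n = len(flags)
    row_tot = np.bincount(class_idx, minlength=len(labels)).astype(float)
    total_true = int(flags.sum())
    k_obs = np.bincount(class_idx[flags], minlength=len(labels)).astype(float)
    observed = _chi2_from_true_counts(k_obs, row_tot, total_true, n)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(flags)
        k = np.bincount(class_idx[perm], minlength=len(labels)).astype(float)
        null[i] = _chi2_from_true_counts(k, row_tot, total_true, n)
    n_gt = int((null > observed + 1e-12).sum())
    n_eq = int((np.abs(null - observed) <= 1e-12).sum())
    n_ge = n_gt + n_eq
    return PermutationResult(
        observed_chi2=observed,
        n_permutations=n_permutations,
        n_ge_observed=n_ge,
        p_empirical=(1 + n_ge) / (n_permutations + 1),
        p_mid=(1 + n_gt + 0.5 * n_eq) / (n_permutations + 1),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        seed=seed,
    )


def class_by_teclass_table(
    site_classes: pd.Series | dict, attribution: pd.DataFrame
) -> ContingencyResult:
    """site-class x TE-class contingency (with a no-TE column)."""
    if isinstance(site_classes, dict):
        site_classes = pd.Series(site_classes)
    merged = attribution.copy()
    merged["site_class"] = merged["site_id"].map(site_classes)
    merged = merged[merged["site_class"].notna()]
    tab = pd.crosstab(merged["site_class"], merged["te_class"])
    order = [c.value for c in TEClass if c.value in tab.columns]
    if "none" in tab.columns:
        order += ["none"]
    return chisq_independence(tab[order])


def distance_bins(distances) -> pd.DataFrame:
    """Signed TSS-distance bins (<=1 kb, 1-10 kb, 10-100 kb, >100 kb)."""
    edges = [-np.inf, -1e5, -1e4, -1e3, 0, 1e3, 1e4, 1e5, np.inf]
    labels = [
        "<-100kb",
        "-100kb..-10kb",
        "-10kb..-1kb",
        "-1kb..0",
        "0..1kb",
        "1kb..10kb",
        "10kb..100kb",
        ">100kb",
    ]
    cats = pd.cut(pd.Series(list(distances), dtype=float), bins=edges, labels=labels)
    counts = cats.value_counts().reindex(labels).fillna(0).astype(int)
    return pd.DataFrame({"bin": labels, "count": counts.to_numpy()})


def tss_distance_tests(groups: dict[str, list[float]]) -> dict:
    """Kruskal-Wallis on absolute TSS distances across feature groups.

    Empty groups are dropped with a warning.  Also emits a per-group
    signed distance binning table for stacked-proportion displays.
    """
    kept = {}
    for name, dists in groups.items():
        if len(dists) == 0:
            logger.warning("group %s has no features; dropped", name)
            continue
        kept[name] = np.abs(np.asarray(dists, dtype=float))
    if len(kept) < 2:
        raise ValueError("need >=2 non-empty groups")
    h, p = stats.kruskal(*kept.values())
    bins = []
    for name, dists in groups.items():
        if name not in kept:
            continue
        tab = distance_bins(dists)
        tab.insert(0, "group", name)
        bins.append(tab)
    return {
        "H": float(h),
        "p": float(p),
        "groups": {k: len(v) for k, v in kept.items()},
        "bins": pd.concat(bins, ignore_index=True),
    }
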