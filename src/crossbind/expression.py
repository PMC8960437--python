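"""Cross-species expression divergence and its link to binding classes.

Counts from each species are normalised with median-of-ratios size
factors, log2(x+1) transformed, study (batch) centred per gene, and
zero-centred per species (subtracting the species grand mean) before
cross-species contrasts.  Divergence per ortholog is the difference of
per-study mean log2 expression, tested with Welch's unequal-variance t
on the study means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq convention).

    The reference is the per-gene geometric mean over samples, using
    genes expressed in every sample; each sample's factor is the median
    ratio of its counts to the reference.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_geo = np.log(mat[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(mat[positive]) - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    sf = size_factors(counts)
    return np.log2(counts / sf + pseudocount)


def center_by_study(log_expr: pd.DataFrame, studies: pd.Series) -> pd.DataFrame:
    """Remove per-gene study (batch) effects, preserving the gene mean.

    For each gene, samples of a study get the study mean subtracted and
    the gene grand mean added back.  Studies with a single sample are
    left untouched (their batch effect is unidentifiable).
    """
    studies = studies.reindex(log_expr.columns)
    out = log_expr.copy()
    grand = log_expr.mean(axis=1)
    for study, cols in studies.groupby(studies).groups.items():
        cols = list(cols)
        if len(cols) < 2:
            logger.warning("study %s has a single sample; centering skipped", study)
            continue
        study_mean = log_expr[cols].mean(axis=1)
        out[cols] = log_expr[cols].sub(study_mean, axis=0).add(grand, axis=0)
    return out


def zero_center(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract the species grand mean (one scalar over all cells)."""
    return log_expr - log_expr.to_numpy().mean()


def normalize_and_center(
    counts_a: pd.DataFrame,
    meta_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    meta_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-species pipeline: size factors, log2, batch, zero-centre.

    ``meta_*`` need columns ``sample`` and ``study``.
    """
    out = []
    for counts, meta in ((counts_a, meta_a), (counts_b, meta_b)):
        studies = meta.set_index("sample")["study"]
        log_expr = normalize_counts(counts, pseudocount)
        log_expr = center_by_study(log_expr, studies)
        out.append(zero_center(log_expr))
    return out[0], out[1]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    log2_ratio: float


def welch_divergence(values_a, values_b) -> WelchResult:
    """Welch's unequal-variance two-sample t test on study means.

    ``log2_ratio`` = mean(values_a) - mean(values_b).  With zero
    variance in both groups, p is 1 for equal means and the smallest
    positive float otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 values per species")
    ratio = float(a.mean() - b.mean())
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0.0:
        if ratio == 0.0:
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0, ratio)
        return WelchResult(math.inf if ratio > 0 else -math.inf, 1.0,
                           float(np.finfo(float).tiny), ratio)
    t = ratio / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(max(p, np.finfo(float).tiny)), ratio)


def study_means(log_expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean log2 expression per study (genes x studies)."""
    studies = meta.set_index("sample")["study"].reindex(log_expr.columns)
    return log_expr.T.groupby(studies).mean().T


def divergence_table(
    log_a: pd.DataFrame,
    meta_a: pd.DataFrame,
    log_b: pd.DataFrame,
    meta_b: pd.DataFrame,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """DivergenceRecord table over ortholog pairs.

    One row per pair present in both expression matrices: log2 ratio
    (species A minus species B), Welch t, df, unadjusted p, and the
    per-study means behind them.
    """
    sm_a = study_means(log_a, meta_a)
    sm_b = study_means(log_b, meta_b)
    rows = []
    for _, pair in pairs.iterrows():
        ga, gb = pair["gene_a"], pair["gene_b"]
        if ga not in sm_a.index or gb not in sm_b.index:
            continue
        va = sm_a.loc[ga].to_numpy()
        vb = sm_b.loc[gb].to_numpy()
        res = welch_divergence(va, vb)
        row = {
            "gene_a": ga,
            "gene_b": gb,
            "log2_ratio": res.log2_ratio,
            "t_stat": res.t,
            "df": res.df,
            "p_unadjusted": res.p,
        }
        for i, v in enumerate(va, 1):
            row[f"a_study{i}_mean"] = v
        for i, v in enumerate(vb, 1):
            row[f"b_study{i}_mean"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def class_divergence_stats(
    records: pd.DataFrame, reference_class: str = "conserved"
) -> pd.DataFrame:
    """Per-class divergence summary and tests against the reference.

    For each gene class: n, mean and sd of log2_ratio, Welch t/p versus
    the reference class, and (versus the reference) a two-sided
    variance-ratio F test.  Classes with fewer than 2 genes get NaNs.
    ``records`` needs columns ``gene_class`` and ``log2_ratio``.
    """
    ref = records.loc[records["gene_class"] == reference_class, "log2_ratio"].to_numpy()
    rows = []
    for cls, grp in records.groupby("gene_class"):
        vals = grp["log2_ratio"].to_numpy()
        row = {
            "gene_class": cls,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "t_vs_ref": np.nan,
            "p_vs_ref": np.nan,
            "f_vs_ref": np.nan,
            "p_f_vs_ref": np.nan,
        }
        if cls != reference_class and len(vals) >= 2 and len(ref) >= 2:
            res = welch_divergence(vals, ref)
            row["t_vs_ref"] = res.t
            row["p_vs_ref"] = res.p
            f = ref.var(ddof=1) / vals.var(ddof=1)
            cdf = stats.f.cdf(f, len(ref) - 1, len(vals) - 1)
            row["f_vs_ref"] = float(f)
            row["p_f_vs_ref"] = float(2 * min(cdf, 1 - cdf))
        rows.append(row)
    return pd.DataFrame(rows).sort_values("gene_class").reset_index(drop=True)


def extreme_tail_enrichment(
    records: pd.DataFrame,
    cutoff: float = 5.0,
    high_class: str = "a_specific",
    low_class: str = "b_specific",
) -> pd.DataFrame:
    """Over-representation of specific classes in the ratio tails.

    For each tail: a 2x2 table of {class of interest vs all other
    classes} x {beyond the cutoff in the matching direction vs not},
    Pearson chi-square p, and the proportion of tail genes belonging to
    the class.  An empty tail yields a missing p with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rows = []
    for tail, cls in (("high", high_class), ("low", low_class)):
        in_tail = (
            records["log2_ratio"] > cutoff
            if tail == "high"
            else records["log2_ratio"] < -cutoff
        )
        is_cls = records["gene_class"] == cls
        k = int((in_tail & is_cls).sum())
        n_tail = int(in_tail.sum())
        table = np.array(
            [
                [k, int((is_cls & ~in_tail).sum())],
                [n_tail - k, int((~is_cls & ~in_tail).sum())],
            ]
        )
        if n_tail == 0:
            logger.warning("empty %s tail at cutoff %g", tail, cutoff)
            p = np.nan
            chi2 = np.nan
        else:
            try:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            except ValueError:  # a zero margin (e.g. class absent)
                logger.warning("degenerate %s-tail table at cutoff %g", tail, cutoff)
                chi2, p = np.nan, np.nan
        rows.append(
            {
                "tail": tail,
                "gene_class": cls,
                "n_tail": n_tail,
                "n_class_in_tail": k,
                "tail_proportion": k / n_tail if n_tail else np.nan,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_slope: float
    stderr: float
    n: int


def ratio_vs_count_difference(records: pd.DataFrame) -> RegressionResult:
    """OLS of log2 expression ratio on the clamped site-count difference.

    Intended for genes bound in both species (conserved or alternative
    classes); the caller does the filtering.  ``records`` needs columns
    ``log2_ratio`` and ``dn``.
    """
    y = records["log2_ratio"].to_numpy(dtype=float)
    x = records["dn"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("site-count difference is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_slope=float(model.pvalues[1]),
        stderr=float(model.bse[1]),
        n=len(y),
    )
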