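"""Repertoire diversity and association statistics.

The breadth of the expressed TRA repertoire in each sample is the
Shannon-Weaver index H' = -sum_i p_i ln p_i over the abundance proportions
of the TRA genes (natural log, the community-ecology convention).
Genotype effects on H' are assessed by one-way ANOVA followed by Dunnett's
many-to-one comparisons against control.

Retention-expression association uses Pearson's product-moment correlation
with a two-tailed p from the t transform (n - 2 df). Families of
category-level retention comparisons (per-gene KO vs control ratios,
Wilcoxon signed-rank by default) are corrected by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from trasplice.counting import ExpressionTable
from trasplice.errors import DataError, ParameterError

__all__ = [
    "shannon_weaver",
    "diversity_table",
    "diversity_compare",
    "pearson",
    "bh_fdr",
    "category_retention_tests",
]


def shannon_weaver(abundances, base: float | None = None) -> float:
    """Shannon-Weaver diversity H' of an abundance vector.

    Natural-log units by default; pass ``base=2`` for bits. Zero entries
    contribute nothing; an all-zero vector has no defined diversity.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise DataError("negative abundance")
    total = x.sum()
    if total == 0:
        raise DataError("all-zero abundance vector has undefined diversity")
    p = x / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def diversity_table(
    expr: ExpressionTable, tra_genes, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample H' over the expressed-TRA repertoire.

    Returns one row per sample with ``genotype``, ``H_prime`` and
    ``n_tra_expressed`` (TRA genes with positive RPKM in that sample).
    """
    tra = pd.Index(tra_genes).intersection(expr.gene_ids)
    rows = []
    for _, rec in design.iterrows():
        s = rec["sample_id"]
        vec = expr.rpkm.loc[tra, s].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": s,
                "genotype": rec["genotype"],
                "H_prime": shannon_weaver(vec),
                "n_tra_expressed": int((vec > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def diversity_compare(
    diversity: pd.DataFrame, control: str = "control"
) -> dict:
    """One-way ANOVA across genotypes plus Dunnett many-to-one comparisons.

    ``diversity`` is the output of :func:`diversity_table`. Returns a dict
    with the ANOVA F and p, and per-knockout Dunnett-adjusted p values
    against the control group (exact multivariate-t quantiles).
    """
    groups = {g: sub["H_prime"].to_numpy(dtype=float) for g, sub in diversity.groupby("genotype")}
    if len(groups) < 2:
        raise ParameterError("need >= 2 genotypes to compare diversity")
    if any(len(v) < 2 for v in groups.values()):
        raise ParameterError("need >= 2 samples per genotype")
    if control not in groups:
        raise ParameterError(f"control group {control!r} absent")
    f, p = sps.f_oneway(*groups.values())
    others = [g for g in groups if g != control]
    # the multivariate-t tail probability is evaluated by quasi-Monte Carlo;
    # pin its stream so identical inputs give identical reports
    dun = sps.dunnett(
        *(groups[g] for g in others), control=groups[control], rng=np.random.default_rng(0)
    )
    comparisons = {
        g: {"statistic": float(dun.statistic[i]), "p_value": float(dun.pvalue[i])}
        for i, g in enumerate(others)
    }
    return {
        "anova_F": float(f),
        "anova_p": float(p),
        "method": "one-way ANOVA + Dunnett (exact)",
        "comparisons": comparisons,
        "group_means": {g: float(v.mean()) for g, v in groups.items()},
    }


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with two-tailed p (t transform, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("pearson needs two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in the input order.

    q_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1. NaN p values are
    left out of the family and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise DataError("p values must lie in [0, 1]")
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def category_retention_tests(
    retention: pd.DataFrame,
    categories: pd.DataFrame,
    contrasts: dict[str, str] | None = None,
    control: str = "control",
    test: str = "wilcoxon",
    category_subset=None,
) -> pd.DataFrame:
    """Per-category paired comparison of gene retention ratios, KO vs control.

    For each TRA category and each knockout genotype, the per-gene
    retention indices under the knockout are compared with the same genes'
    control indices (paired over genes; Wilcoxon signed-rank by default,
    ``test="ttest"`` for the paired t). BH q values are computed across the
    whole family of comparisons. Categories with fewer than 3 genes with
    defined ratios on both sides are flagged untestable (NaN p).
    """
    if contrasts is None:
        contrasts = {g: g for g in retention.columns if g != control}
    cats = category_subset or [c for c in sorted(categories["category"].unique()) if c.startswith("TRA_")]
    rows = []
    for cat in cats:
        genes = categories.index[categories["category"] == cat]
        block = retention.reindex(genes)
        for label, geno in contrasts.items():
            pair = block[[control, geno]].dropna()
            n = len(pair)
            if n < 3:
                p = np.nan
                stat = np.nan
            else:
                diffs = pair[geno] - pair[control]
                if test == "wilcoxon":
                    if (diffs == 0).all():
                        stat, p = np.nan, 1.0
                    else:
                        stat, p = sps.wilcoxon(pair[geno], pair[control])
                elif test == "ttest":
                    stat, p = sps.ttest_rel(pair[geno], pair[control])
                    if np.isnan(p) and np.isclose(diffs.mean(), 0):
                        p = 1.0
                else:
                    raise ParameterError(f"unknown test {test!r}")
            rows.append(
                {
                    "category": cat,
                    "contrast": label,
                    "n_genes": n,
                    "mean_control": float(pair[control].mean()) if n else np.nan,
                    "mean_ko": float(pair[geno].mean()) if n else np.nan,
                    "statistic": float(stat) if stat == stat else np.nan,
                    "p_value": float(p) if p == p else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["untestable"] = out["p_value"].isna()
    return out
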