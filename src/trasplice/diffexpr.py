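"""Two-contrast differential expression and TRA dependence categorization.

Each knockout is compared with control by an unpaired, equal-variance
(Student's) two-tailed t test on log2(RPKM + eps), with the fold change
taken on the linear group means. A gene is "down" when p < 0.05 and
FC < 0.5, "up" when p < 0.05 and FC > 2 (strict inequalities throughout).
No multiple-testing correction is applied at this per-gene stage.

Expressed TRA genes are then partitioned by their down flags in the two
contrasts: down only in Prmt5-cKO -> TRA_Prmt5; only in Aire-KO ->
TRA_Aire; in both -> TRA_shared; in neither -> TRA_other. Non-TRA and
non-expressed genes complete the partition of the gene universe.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from trasplice.counting import ExpressionTable
from trasplice.errors import DataError, ParameterError

__all__ = [
    "TRA_CATEGORIES",
    "ALL_CATEGORIES",
    "expressed_filter",
    "diff_test",
    "categorize_tras",
    "summarize_categories",
]

TRA_CATEGORIES = ("TRA_Prmt5", "TRA_Aire", "TRA_shared", "TRA_other")
ALL_CATEGORIES = TRA_CATEGORIES + ("non_TRA", "not_expressed")


def _group_samples(design: pd.DataFrame, genotype: str) -> list[str]:
    samples = design.loc[design["genotype"] == genotype, "sample_id"].tolist()
    if not samples:
        raise ParameterError(f"no samples with genotype {genotype!r} in design")
    return samples


def expressed_filter(
    expr: ExpressionTable, design: pd.DataFrame, group: str = "control"
) -> pd.Index:
    """Genes with mean RPKM strictly above zero in the reference group."""
    samples = _group_samples(design, group)
    means = expr.rpkm[samples].mean(axis=1)
    return expr.gene_ids[means.to_numpy() > 0]


def diff_test(
    expr: ExpressionTable,
    design: pd.DataFrame,
    contrast: str,
    control: str = "control",
    alpha: float = 0.05,
    fc_down: float = 0.5,
    fc_up: float = 2.0,
    eps: float = 0.01,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-gene KO vs control t test with fold-change flags.

    Returns a DataFrame indexed by gene with columns ``mean_control``,
    ``mean_ko``, ``fold_change``, ``p_value``, ``down``, ``up`` and
    ``untestable``. Genes that are constant zero on both sides carry an
    undefined p value and are flagged untestable.
    """
    ko_samples = _group_samples(design, contrast)
    ctrl_samples = _group_samples(design, control)
    if len(ko_samples) < 2 or len(ctrl_samples) < 2:
        raise ParameterError("need >= 2 replicates on each side of the contrast")
    ko = expr.rpkm[ko_samples].to_numpy(dtype=float)
    ctrl = expr.rpkm[ctrl_samples].to_numpy(dtype=float)

    mean_ko = ko.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    fc = np.where(mean_ctrl > 0, mean_ko / np.where(mean_ctrl > 0, mean_ctrl, 1.0), (mean_ko + eps) / eps)

    if log_scale:
        a, b = np.log2(ko + eps), np.log2(ctrl + eps)
    else:
        a, b = ko, ctrl
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant genes trip scipy's precision-loss warning; their
        # p values are cleaned up just below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # zero pooled variance: identical constant groups are a non-result, not NaN
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(np.isnan(p) & equal_means, 1.0, p)

    untestable = (ko == 0).all(axis=1) & (ctrl == 0).all(axis=1)
    p = np.where(untestable, np.nan, p)

    sig = p < alpha
    down = sig & (fc < fc_down) & ~untestable
    up = sig & (fc > fc_up) & ~untestable
    return pd.DataFrame(
        {
            "mean_control": mean_ctrl,
            "mean_ko": mean_ko,
            "fold_change": fc,
            "p_value": p,
            "down": down,
            "up": up,
            "untestable": untestable,
        },
        index=expr.gene_ids,
    )


def categorize_tras(
    tra_genes,
    diff_prmt5: pd.DataFrame,
    diff_aire: pd.DataFrame,
    expressed,
) -> pd.DataFrame:
    """Partition the gene universe into the six dependence categories.

    The universe is the (shared) index of the two contrast tables; every
    gene receives exactly one label.
    """
    if not diff_prmt5.index.equals(diff_aire.index):
        raise DataError("the two contrasts cover different gene universes")
    universe = diff_prmt5.index
    tra_genes = pd.Index(tra_genes)
    expressed = pd.Index(expressed)
    missing = tra_genes.difference(universe)
    if len(missing):
        raise DataError(f"{len(missing)} TRA genes missing from a contrast (first: {missing[0]})")

    is_tra = universe.isin(tra_genes)
    is_expr = universe.isin(expressed)
    down_p = diff_prmt5["down"].to_numpy(dtype=bool)
    down_a = diff_aire["down"].to_numpy(dtype=bool)

    category = np.where(
        ~is_expr,
        "not_expressed",
        np.where(
            ~is_tra,
            "non_TRA",
            np.select(
                [down_p & ~down_a, ~down_p & down_a, down_p & down_a],
                ["TRA_Prmt5", "TRA_Aire", "TRA_shared"],
                default="TRA_other",
            ),
        ),
    )
    return pd.DataFrame({"category": category}, index=universe)


def _round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_categories(table: pd.DataFrame) -> dict:
    """Counts and one-decimal percentages of the four expressed-TRA classes.

    Percentages are of the expressed-TRA total, rounded half away from
    zero. Also reports the share of Prmt5-dependent TRAs (TRA_Prmt5 u
    TRA_shared) that are Aire-dependent, i.e. shared / (TRA_Prmt5 +
    TRA_shared).
    """
    if table.empty:
        return {"counts": {}, "percentages": {}, "total_expressed_tra": 0}
    counts = {c: int((table["category"] == c).sum()) for c in TRA_CATEGORIES}
    total = sum(counts.values())
    percentages = {
        c: _round_half_up(100.0 * counts[c] / total) if total else 0.0 for c in TRA_CATEGORIES
    }
    prmt5_dep = counts["TRA_Prmt5"] + counts["TRA_shared"]
    share = _round_half_up(100.0 * counts["TRA_shared"] / prmt5_dep) if prmt5_dep else float("nan")
    return {
        "counts": counts,
        "total_expressed_tra": total,
        "percentages": percentages,
        "prmt5_dependent_total": prmt5_dep,
        "prmt5_dependent_aire_share_pct": share,
        "non_tra": int((table["category"] == "non_TRA").sum()),
        "not_expressed": int((table["category"] == "not_expressed").sum()),
    }
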