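"""Per-gene intron retention index, fold changes and category summaries.

The intron retention index of a gene in a genotype is the fraction of its
reads that are intronic,

    IRI = intron reads / (exon reads + intron reads),

with replicates pooled (ratio of summed counts) by default — robust for
low-count genes; a mean-of-per-sample-ratios alternative is available.
Genes with no reads in the group, and single-exon genes (no intron to
retain), carry an undefined index.

A knockout's retention change per gene is (IRI_ko + eps) / (IRI_ctrl +
eps) with a small eps guarding zero indices; genes with fold change > 1.5
are flagged as increased retention, < 0.75 as decreased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trasplice.counting import FeatureCountMatrix
from trasplice.errors import ParameterError

__all__ = [
    "intron_retention_index",
    "min_read_filter",
    "retention_fold_change",
    "retention_by_genotype",
    "category_retention_table",
    "CategoryRetentionSummary",
]


def _group_samples(design: pd.DataFrame, group: str) -> list[str]:
    samples = design.loc[design["genotype"] == group, "sample_id"].tolist()
    if not samples:
        raise ParameterError(f"no samples with genotype {group!r}")
    return samples


def intron_retention_index(
    counts: FeatureCountMatrix,
    design: pd.DataFrame,
    group: str,
    aggregation: str = "pooled",
) -> pd.Series:
    """Per-gene intron/total read ratio for one genotype.

    ``aggregation="pooled"`` divides summed intron counts by summed totals
    across the group's replicates; ``"mean"`` averages per-sample ratios.
    Genes with zero group total (or no intron, under "mean", in a sample
    with no reads) yield NaN. Single-exon genes are *not* masked here; use
    ``counts.intronic_length > 0`` to restrict the analysis universe.
    """
    samples = _group_samples(design, group)
    intron = counts.intron[samples].to_numpy(dtype=float)
    total = intron + counts.exon[samples].to_numpy(dtype=float)
    if aggregation == "pooled":
        num, den = intron.sum(axis=1), total.sum(axis=1)
        ratio = np.divide(num, den, out=np.full(len(num), np.nan), where=den > 0)
    elif aggregation == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            per_sample = np.where(total > 0, intron / np.where(total > 0, total, 1.0), np.nan)
        ratio = np.nanmean(np.where(np.isnan(per_sample), np.nan, per_sample), axis=1)
    else:
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    return pd.Series(ratio, index=counts.gene_ids, name=f"iri_{group}")


def min_read_filter(
    counts: FeatureCountMatrix,
    design: pd.DataFrame,
    group: str,
    threshold: int = 10,
) -> pd.Index:
    """Genes whose pooled exon+intron total in the group is >= threshold
    (inclusive)."""
    samples = _group_samples(design, group)
    totals = counts.total()[samples].sum(axis=1)
    return counts.gene_ids[totals.to_numpy() >= threshold]


def retention_fold_change(
    index_ko: pd.Series,
    index_control: pd.Series,
    eps: float = 1e-3,
    fc_up: float = 1.5,
    fc_down: float = 0.75,
) -> pd.DataFrame:
    """KO/control retention fold change with increased/decreased flags.

    Both indices get the same eps so genes at exactly zero retention stay
    comparable. An undefined index on either side propagates to NaN with
    both flags False.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    ko = index_ko.to_numpy(dtype=float)
    ctrl = index_control.reindex(index_ko.index).to_numpy(dtype=float)
    fc = (ko + eps) / (ctrl + eps)
    defined = ~np.isnan(fc)
    return pd.DataFrame(
        {
            "retention_fc": fc,
            "increased": defined & (fc > fc_up),
            "decreased": defined & (fc < fc_down),
        },
        index=index_ko.index,
    )


def retention_by_genotype(
    counts: FeatureCountMatrix,
    design: pd.DataFrame,
    aggregation: str = "pooled",
) -> pd.DataFrame:
    """Retention index matrix: genes x genotypes present in the design."""
    out = {}
    for g in design["genotype"].unique():
        out[g] = intron_retention_index(counts, design, g, aggregation=aggregation)
    return pd.DataFrame(out)


@dataclass
class CategoryRetentionSummary:
    """Per-category retention distributions and the top-k induced panel."""

    #: mapping category -> genes x genotypes retention-ratio matrix
    ratios: dict[str, pd.DataFrame]
    #: categories x genotypes mean retention ratio
    means: pd.DataFrame
    #: top-k genes by retention fold change (KO/control), with their ratios
    top_panel: pd.DataFrame
    warnings: list[str]


def category_retention_table(
    retention: pd.DataFrame,
    categories: pd.DataFrame,
    fold_change: pd.Series | None = None,
    top_k: int = 30,
) -> CategoryRetentionSummary:
    """Group per-gene retention ratios by TRA category.

    Parameters
    ----------
    retention
        Genes x genotypes retention-index matrix (NaN = undefined).
    categories
        Output of :func:`trasplice.diffexpr.categorize_tras`.
    fold_change
        Per-gene retention fold change used to order the top-k panel
        (typically the Prmt5-cKO/control change); panel omitted if None.
    """
    cats = categories["category"]
    ratios: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []
    means = {}
    for cat in sorted(cats.unique()):
        genes = cats.index[cats == cat]
        block = retention.reindex(genes).dropna(how="all")
        if block.empty:
            warnings.append(f"category {cat} has no genes with defined retention")
        ratios[cat] = block
        means[cat] = block.mean(axis=0)
    means_df = pd.DataFrame(means).T
    means_df.index.name = "category"
    if fold_change is not None:
        order = fold_change.reindex(retention.index).dropna().sort_values(ascending=False)
        top = order.index[:top_k]
        top_panel = retention.reindex(top).assign(retention_fc=fold_change.reindex(top))
    else:
        top_panel = pd.DataFrame(columns=list(retention.columns) + ["retention_fc"])
    return CategoryRetentionSummary(ratios=ratios, means=means_df, top_panel=top_panel, warnings=warnings)
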