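"""Tissue-specificity scoring by Shannon entropy and TRA classification.

A gene's expression vector across a multi-tissue atlas is normalized to a
probability distribution and scored by its Shannon entropy in bits,

    H(g) = -sum_t p_t log2 p_t,   p_t = x_t / sum_t x_t.

A uniformly expressed gene attains the maximum log2(n_tissues); a gene
expressed in a single tissue scores 0. Genes scoring strictly below a
threshold (default 3.0 bits, roughly "supported by fewer than eight
tissues") are classified as tissue-restricted antigens (TRAs).

Entropy is computed on linear expression proportions with no pseudocount;
genes whose atlas row is all zero have no defined distribution and are
excluded from classification rather than assigned a score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trasplice.errors import DataError, ParameterError

__all__ = ["TissueAtlas", "EntropyResult", "entropy_score", "entropy_scores", "classify_tras"]


@dataclass
class TissueAtlas:
    """Genes x tissues non-negative expression matrix (arbitrary linear units).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per tissue.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[1] < 2:
            raise DataError("atlas needs at least 2 tissues")
        if df.index.has_duplicates:
            raise DataError("duplicate gene ids in atlas")
        if df.columns.has_duplicates:
            raise DataError("duplicate tissue ids in atlas")
        if (df.to_numpy() < 0).any():
            raise DataError("negative expression values in atlas")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def tissue_ids(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def from_tsv(cls, path) -> "TissueAtlas":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class EntropyResult:
    """Per-gene entropy score, TRA flag and atlas total.

    ``table`` has columns ``entropy_bits`` (NaN when the atlas row is all
    zero), ``total_expression`` and ``is_tra`` (pandas nullable boolean, NA
    for undefined genes). ``excluded`` lists the all-zero genes.
    """

    table: pd.DataFrame
    threshold: float
    excluded: pd.Index = field(default_factory=lambda: pd.Index([]))

    @property
    def tra_genes(self) -> pd.Index:
        return self.table.index[self.table["is_tra"].fillna(False).to_numpy(dtype=bool)]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def entropy_score(expression_vector) -> float:
    """Shannon entropy in bits of one gene's tissue expression profile.

    Zero entries contribute nothing. Raises :class:`DataError` on negative
    entries or an all-zero vector, and :class:`ParameterError` for vectors
    shorter than two tissues.
    """
    x = np.asarray(expression_vector, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("expression vector must cover at least 2 tissues")
    if (x < 0).any():
        raise DataError("negative expression value")
    total = x.sum()
    if total == 0:
        raise DataError("all-zero expression vector has undefined entropy")
    p = x / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def entropy_scores(values: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`entropy_score` over the rows of a genes x tissues
    matrix. All-zero rows yield NaN."""
    x = values.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = x / totals[:, None]
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
    h = -(p * logp).sum(axis=1)
    h[totals == 0] = np.nan
    return pd.Series(h, index=values.index, name="entropy_bits")


def classify_tras(atlas: TissueAtlas, threshold: float = 3.0) -> EntropyResult:
    """Score every atlas gene and flag TRAs as ``entropy < threshold``.

    The inequality is strict: a gene scoring exactly at the threshold is not
    a TRA. Genes with zero total atlas expression are excluded from the
    classification universe and reported via ``EntropyResult.excluded``.
    """
    if threshold <= 0:
        raise ParameterError(f"entropy threshold must be positive, got {threshold}")
    h = entropy_scores(atlas.values)
    total = atlas.values.sum(axis=1)
    is_tra = pd.array(h < threshold, dtype="boolean")
    is_tra[h.isna().to_numpy()] = pd.NA
    table = pd.DataFrame(
        {"entropy_bits": h, "total_expression": total, "is_tra": is_tra},
        index=atlas.gene_ids,
    )
    excluded = atlas.gene_ids[h.isna().to_numpy()]
    return EntropyResult(table=table, threshold=threshold, excluded=excluded)
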