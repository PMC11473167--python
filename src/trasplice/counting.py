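"""Gene models, exon/intron read assignment and RPKM expression.

Coordinates are BED-style (0-based, half-open) everywhere in memory; GTF
(1-based, inclusive) is converted at the parser boundary only.

Read assignment convention
--------------------------
For a read overlapping exactly one gene:

* intronic if it overlaps any intronic base of that gene — a read crossing
  an exon-intron junction is direct evidence of a retained intron, so the
  boundary rule is "any intron overlap => intronic";
* exonic if it lies entirely within the gene's merged exon union;
* otherwise (hanging off the gene edge without touching an intron) it is
  left unassigned.

Reads overlapping two or more genes are discarded as ambiguous rather than
fractionally assigned; reads overlapping no gene are intergenic. Strand is
ignored (unstranded protocol assumed). Per-sample tallies of every discard
class are kept so that

    exon + intron + ambiguous + intergenic + unassigned_edge = total reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from trasplice.errors import DataError, ParameterError

__all__ = [
    "GeneModel",
    "FeatureCountMatrix",
    "ExpressionTable",
    "derive_introns",
    "count_reads",
    "rpkm",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
]

Interval = tuple[int, int]


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if e <= s:
            raise DataError(f"malformed interval ({s}, {e}): end <= start")
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:  # abutting exons merge too
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene on a chromosome; introns are derived.

    ``exons`` are merged, sorted, non-overlapping 0-based half-open
    intervals. Introns are the gaps between consecutive merged exons, so a
    single-exon gene has none and abutting exons produce none.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    @classmethod
    def from_exons(cls, gene_id: str, chrom: str, exons: Iterable[Interval], strand: str = "+") -> "GeneModel":
        merged = _merge_intervals(exons)
        if not merged:
            raise DataError(f"gene {gene_id} has no exons")
        return cls(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(merged))

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intronic_length(self) -> int:
        return sum(e - s for s, e in self.introns)


def derive_introns(model: GeneModel) -> list[Interval]:
    """Gaps between consecutive merged exons (empty for single-exon genes)."""
    return list(model.introns)


@dataclass
class FeatureCountMatrix:
    """Paired exon/intron count matrices (genes x samples) plus feature lengths."""

    exon: pd.DataFrame
    intron: pd.DataFrame
    exonic_length: pd.Series
    intronic_length: pd.Series
    assignment_summary: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.exon.index.equals(self.intron.index) or not self.exon.columns.equals(self.intron.columns):
            raise DataError("exon and intron matrices must share genes and samples")
        for mat in (self.exon, self.intron):
            arr = mat.to_numpy()
            if (arr < 0).any():
                raise DataError("negative counts")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise DataError("counts must be integral")

    @property
    def gene_ids(self) -> pd.Index:
        return self.exon.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.exon.columns

    def total(self) -> pd.DataFrame:
        """Per-gene per-sample exon + intron totals."""
        return self.exon + self.intron

    def to_tsv(self, path) -> None:
        out = pd.DataFrame(index=self.gene_ids)
        for s in self.sample_ids:
            out[f"{s}_exon"] = self.exon[s]
            out[f"{s}_intron"] = self.intron[s]
        out["exonic_length"] = self.exonic_length
        out["intronic_length"] = self.intronic_length
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        samples = sorted({c[: -len("_exon")] for c in df.columns if c.endswith("_exon")})
        exon = df[[f"{s}_exon" for s in samples]].copy()
        exon.columns = samples
        intron = df[[f"{s}_intron" for s in samples]].copy()
        intron.columns = samples
        return cls(
            exon=exon.astype(int),
            intron=intron.astype(int),
            exonic_length=df["exonic_length"].astype(int),
            intronic_length=df["intronic_length"].astype(int),
        )


@dataclass
class ExpressionTable:
    """RPKM expression matrix with the library sizes used to compute it."""

    rpkm: pd.DataFrame
    library_size: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.rpkm.columns

    def to_tsv(self, path) -> None:
        self.rpkm.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, library_size: pd.Series | None = None) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if library_size is None:
            library_size = pd.Series(np.nan, index=df.columns)
        return cls(rpkm=df, library_size=library_size)


class _GeneIndex:
    """Interval lookup over gene spans plus per-gene exon/intron membership."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self.trees: dict[str, IntervalTree] = {}
        for i, m in enumerate(self.models):
            self.trees.setdefault(m.chrom, IntervalTree())[m.start : m.end] = i
        # precomputed per-gene structures for the classification step
        self._exon_starts = [[s for s, _ in m.exons] for m in self.models]
        self._introns = [m.introns for m in self.models]

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[int]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def classify(self, gene_idx: int, start: int, end: int) -> str:
        """'intron' | 'exon' | 'edge' for a read overlapping this gene."""
        for s, e in self._introns[gene_idx]:
            if start < e and s < end:
                return "intron"
        exons = self.models[gene_idx].exons
        starts = self._exon_starts[gene_idx]
        j = bisect.bisect_right(starts, start) - 1
        if j >= 0 and exons[j][0] <= start and end <= exons[j][1]:
            return "exon"
        return "edge"


def count_reads(
    reads_by_sample: Mapping[str, pd.DataFrame],
    models: Sequence[GeneModel],
) -> FeatureCountMatrix:
    """Assign read placements to exon/intron features per gene and sample.

    Parameters
    ----------
    reads_by_sample
        Mapping sample id -> BED-like DataFrame with at least ``chrom``,
        ``start``, ``end`` columns (0-based, half-open).
    models
        Gene models sharing the reads' coordinate system.

    Returns a :class:`FeatureCountMatrix` whose ``assignment_summary``
    records per-sample totals of every assignment class, satisfying the
    conservation identity exon + intron + ambiguous + intergenic +
    unassigned_edge = total input reads.
    """
    index = _GeneIndex(models)
    gene_ids = pd.Index([m.gene_id for m in models], name="gene_id")
    if gene_ids.has_duplicates:
        raise DataError("duplicate gene ids in models")
    samples = list(reads_by_sample)
    n_genes = len(models)
    exon = np.zeros((n_genes, len(samples)), dtype=np.int64)
    intron = np.zeros_like(exon)
    summary_rows = []
    for si, sample in enumerate(samples):
        bed = reads_by_sample[sample]
        _validate_bed(bed)
        tallies = {"ambiguous": 0, "intergenic": 0, "unassigned_edge": 0}
        chroms = bed["chrom"].to_numpy()
        starts = bed["start"].to_numpy()
        ends = bed["end"].to_numpy()
        for chrom, start, end in zip(chroms, starts, ends):
            hits = index.overlapping_genes(chrom, int(start), int(end))
            if not hits:
                tallies["intergenic"] += 1
            elif len(hits) > 1:
                tallies["ambiguous"] += 1
            else:
                kind = index.classify(hits[0], int(start), int(end))
                if kind == "intron":
                    intron[hits[0], si] += 1
                elif kind == "exon":
                    exon[hits[0], si] += 1
                else:
                    tallies["unassigned_edge"] += 1
        tallies["exon"] = int(exon[:, si].sum())
        tallies["intron"] = int(intron[:, si].sum())
        tallies["total"] = len(bed)
        summary_rows.append(tallies)
    summary = pd.DataFrame(summary_rows, index=pd.Index(samples, name="sample"))
    return FeatureCountMatrix(
        exon=pd.DataFrame(exon, index=gene_ids, columns=samples),
        intron=pd.DataFrame(intron, index=gene_ids, columns=samples),
        exonic_length=pd.Series([m.exonic_length for m in models], index=gene_ids, name="exonic_length"),
        intronic_length=pd.Series([m.intronic_length for m in models], index=gene_ids, name="intronic_length"),
        assignment_summary=summary,
    )


def _validate_bed(bed: pd.DataFrame) -> None:
    for col in ("chrom", "start", "end"):
        if col not in bed.columns:
            raise DataError(f"BED frame missing column {col!r}")
    bad = bed.index[(bed["end"] <= bed["start"]).to_numpy()]
    if len(bad):
        raise DataError(f"invalid BED interval (end <= start) at line {int(bad[0]) + 1}")


def rpkm(counts: FeatureCountMatrix) -> ExpressionTable:
    """Reads per kilobase of exon per million mapped reads.

    rpkm_gs = 1e9 * exon_count_gs / (library_size_s * exonic_length_g),
    where the library size of a sample is the total of all assigned feature
    reads (exon + intron) — "mapped reads" including intron-retaining
    transcripts.
    """
    if (counts.exonic_length <= 0).any():
        bad = counts.exonic_length.index[counts.exonic_length <= 0][0]
        raise DataError(f"gene {bad} has non-positive exonic length")
    lib = counts.total().sum(axis=0).astype(float)
    if (lib == 0).any():
        raise DataError("zero library size for sample(s): " + ", ".join(lib.index[lib == 0]))
    values = 1e9 * counts.exon.div(lib, axis=1).div(counts.exonic_length, axis=0)
    return ExpressionTable(rpkm=values, library_size=lib.rename("library_size"))


# ---------------------------------------------------------------------------
# Format boundaries: GTF (1-based inclusive) and BED6 (0-based half-open)

def write_gtf(models: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF with gene and exon features."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            fh.write(
                f"{m.chrom}\ttrasplice\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\ttrasplice\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[GeneModel]:
    """Read gene models (exon features grouped by gene_id) from a GTF file."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes["gene_id"][0]
        rec = by_gene.setdefault(gid, {"chrom": exon.seqid, "strand": exon.strand, "exons": []})
        rec["exons"].append((exon.start - 1, exon.end))  # GTF -> half-open
    return [
        GeneModel.from_exons(gid, rec["chrom"], rec["exons"], strand=rec["strand"] or "+")
        for gid, rec in sorted(by_gene.items())
    ]


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame (0-based, half-open)."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    except Exception as exc:  # pragma: no cover - parser detail
        raise DataError(f"cannot parse BED file {path}: {exc}") from exc
    if len(bed):
        _validate_bed(bed)
    return bed


def write_bed(reads: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in reads.columns]
    reads[cols].to_csv(path, sep="\t", header=False, index=False)
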