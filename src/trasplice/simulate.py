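"""Synthetic data generator with planted ground truth.

Emulates the structure of the study design this package analyzes: a
multi-tissue expression atlas with planted tissue-restricted genes, gene
models on a synthetic chromosome, and bulk RNA-seq exon/intron counts for
mTEC samples from three genotypes (control, Prmt5-cKO, Aire-KO).

Effect structure
----------------
Each TRA gene is planted into one dependence class:

==============  =======================  ==========================
class           downregulated in         splicing-deficient in
==============  =======================  ==========================
prmt5_only      prmt5_ko                 prmt5_ko
aire_only       aire_ko                  aire_ko
shared          both knockouts           both knockouts
other           neither                  neither
==============  =======================  ==========================

For gene g in a sample of genotype G, the expected total read count is
``mu = baseline * downreg_fc`` if g is affected in G (else baseline), split
into intron reads ``mu * pi`` and exon reads ``mu * (1 - pi)`` where the
intron fraction ``pi`` jumps from ``base_intron_frac`` to
``deficient_intron_frac`` in affected genotypes. Splicing failure thereby
couples mature-expression loss to increased intron retention by
construction, the inverse correlation the downstream statistics measure.

Counts are negative-binomial (gamma-Poisson) around these expectations;
``nb_dispersion=None`` selects a deterministic mode in which each count is
the rounded expectation, for exact recovery tests. ``nb_dispersion=0``
gives Poisson noise.

One global seed drives named substreams ("truth", "atlas", "models",
"counts", "reads"), so every generator can be re-run independently and
reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trasplice.counting import FeatureCountMatrix, GeneModel
from trasplice.entropy import TissueAtlas
from trasplice.errors import DataError, ParameterError

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "GENOTYPES",
    "make_design",
    "simulation_truth",
    "simulate_atlas",
    "simulate_gene_models",
    "simulate_counts",
    "simulate_read_intervals",
]

GENOTYPES = ("control", "prmt5_ko", "aire_ko")

#: genotypes in which a gene of each planted class is both downregulated and
#: splicing-deficient
AFFECTED_GENOTYPES: Mapping[str, tuple[str, ...]] = {
    "prmt5_only": ("prmt5_ko",),
    "aire_only": ("aire_ko",),
    "shared": ("prmt5_ko", "aire_ko"),
    "other": (),
}

_CATEGORY_LABEL = {
    "prmt5_only": "TRA_Prmt5",
    "aire_only": "TRA_Aire",
    "shared": "TRA_shared",
    "other": "TRA_other",
}


@dataclass
class SimulationParams:
    """Study-scale defaults for the simulated experiment.

    Defaults encode the conditions of the recovery experiments: 2,000 genes
    of which 25% are TRAs spread over a 16-tissue atlas, three replicates
    per genotype, five-fold downregulation of affected genes
    (``downreg_fc=0.2``) and an intron-read fraction rising from 5% to 35%
    under splicing deficiency. Per-gene sequencing depth is drawn
    log-uniformly from ``depth_range`` (>= 500 expected reads per gene); set
    ``mean_depth`` to rescale baselines to a fixed expected total per
    sample instead.
    """

    n_genes: int = 2000
    n_tissues: int = 16
    frac_tra: float = 0.25
    tra_breadth: tuple[int, int] = (1, 3)
    category_probs: dict[str, float] = field(
        default_factory=lambda: {"prmt5_only": 0.25, "aire_only": 0.25, "shared": 0.25, "other": 0.25}
    )
    downreg_fc: float = 0.2
    base_intron_frac: float = 0.05
    deficient_intron_frac: float = 0.35
    depth_range: tuple[float, float] = (500.0, 3000.0)
    mean_depth: float | None = None
    nb_dispersion: float | None = 0.05
    n_replicates: int = 3
    frac_silent: float = 0.05
    frac_single_exon: float = 0.10
    atlas_high: float = 100.0
    atlas_low: float = 1.0
    atlas_noise_sd: float = 0.25
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (100, 300)
    intron_length: tuple[int, int] = (100, 500)
    gene_spacer: int = 1000
    read_length: int = 50
    chrom: str = "chrSim"
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_tra", "base_intron_frac", "deficient_intron_frac", "frac_silent", "frac_single_exon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.downreg_fc:
            raise ParameterError("downreg_fc must be non-negative")
        if set(self.category_probs) != set(AFFECTED_GENOTYPES):
            raise ParameterError(f"category_probs keys must be {sorted(AFFECTED_GENOTYPES)}")
        if any(p < 0 for p in self.category_probs.values()):
            raise ParameterError("category_probs must be non-negative")
        if abs(sum(self.category_probs.values()) - 1.0) > 1e-9:
            raise ParameterError("category_probs must sum to 1")
        if self.n_replicates < 2:
            raise ParameterError("n_replicates must be >= 2")
        if self.deficient_intron_frac <= self.base_intron_frac:
            raise ParameterError("deficient_intron_frac must exceed base_intron_frac")
        if self.n_tissues < 4:
            raise ParameterError("n_tissues must be >= 4")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if not 1 <= self.tra_breadth[0] <= self.tra_breadth[1] <= self.n_tissues:
            raise ParameterError("tra_breadth must satisfy 1 <= lo <= hi <= n_tissues")
        if self.nb_dispersion is not None and self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be >= 0 or None")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationParams":
        d = dict(d)
        for key in ("tra_breadth", "depth_range", "exons_per_gene", "exon_length", "intron_length"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        p = cls(**d)
        p.validate()
        return p


@dataclass
class SimulationTruth:
    """Planted per-gene ground truth.

    ``table`` columns: ``true_category`` (pipeline label), ``planted_class``
    (raw class or ``non_tra``/``not_expressed``), ``is_tra``, ``breadth``,
    ``baseline`` expected reads and, per genotype G, ``mu_<G>`` (expected
    total reads) and ``pi_<G>`` (intron fraction).
    """

    table: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_in_class(self, label: str) -> pd.Index:
        return self.table.index[self.table["true_category"] == label]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _substream(seed: int, name: str) -> np.random.Generator:
    # independent, reproducible named substream of the global seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def make_design(params: SimulationParams) -> pd.DataFrame:
    """Sample sheet: one row per sample with genotype and replicate index."""
    rows = [
        {"sample_id": f"{g}_{r + 1}", "genotype": g, "replicate": r + 1}
        for g in GENOTYPES
        for r in range(params.n_replicates)
    ]
    return pd.DataFrame(rows)


def simulation_truth(params: SimulationParams) -> SimulationTruth:
    """Draw the planted gene-level ground truth for a seed.

    Deterministic per (params, seed); every other generator derives from it
    so atlas, models and counts agree on which genes are TRAs.
    """
    params.validate()
    rng = _substream(params.seed, "truth")
    n = params.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    is_tra = np.zeros(n, dtype=bool)
    n_tra = int(round(params.frac_tra * n))
    is_tra[rng.choice(n, size=n_tra, replace=False)] = True

    classes = np.array(["non_tra"] * n, dtype=object)
    cat_names = sorted(params.category_probs)
    probs = np.array([params.category_probs[c] for c in cat_names])
    classes[is_tra] = rng.choice(cat_names, size=n_tra, p=probs)

    # silent genes (not expressed in mTECs) are drawn from the classes with
    # no knockout effect, mirroring atlas TRAs that the tissue never expresses
    eligible = np.flatnonzero((classes == "non_tra") | (classes == "other"))
    n_silent = min(int(round(params.frac_silent * n)), len(eligible))
    silent = np.zeros(n, dtype=bool)
    if n_silent:
        silent[rng.choice(eligible, size=n_silent, replace=False)] = True

    breadth = rng.integers(params.tra_breadth[0], params.tra_breadth[1] + 1, size=n)
    breadth[~is_tra] = params.n_tissues

    lo, hi = params.depth_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if params.mean_depth is not None:
        baseline *= params.mean_depth / baseline.sum()
    baseline[silent] = 0.0

    # single-exon (unspliceable) genes only among unaffected classes, so the
    # splicing phenotype is always measurable where it is planted
    single_exon = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(((classes == "non_tra") | (classes == "other")) & ~silent)
    n_single = int(round(params.frac_single_exon * len(idx)))
    if n_single:
        single_exon[rng.choice(idx, size=n_single, replace=False)] = True

    label = np.where(
        silent,
        "not_expressed",
        np.where(is_tra, [ _CATEGORY_LABEL.get(c, "non_TRA") for c in classes ], "non_TRA"),
    )

    table = pd.DataFrame(
        {
            "true_category": label,
            "planted_class": np.where(silent, "not_expressed", classes),
            "is_tra": is_tra,
            "breadth": breadth,
            "single_exon": single_exon,
            "baseline": baseline,
        },
        index=gene_ids,
    )
    for g in GENOTYPES:
        affected = np.array(
            [g in AFFECTED_GENOTYPES.get(c, ()) for c in table["planted_class"]]
        )
        mu = baseline * np.where(affected, params.downreg_fc, 1.0)
        pi = np.where(affected, params.deficient_intron_frac, params.base_intron_frac)
        pi = np.where(single_exon, 0.0, pi)
        table[f"mu_{g}"] = mu
        table[f"pi_{g}"] = pi
    return SimulationTruth(table=table)


def simulate_atlas(params: SimulationParams) -> tuple[TissueAtlas, SimulationTruth]:
    """Multi-tissue expression atlas with planted tissue-restricted genes.

    TRA rows concentrate expression (level ``atlas_high``) in ``breadth``
    random tissues and are near-silent (``atlas_low``) elsewhere; non-TRA
    rows are approximately uniform. Multiplicative log-normal noise of
    scale ``atlas_noise_sd`` roughens both.
    """
    truth = simulation_truth(params)
    rng = _substream(params.seed, "atlas")
    n, t = params.n_genes, params.n_tissues
    values = np.full((n, t), params.atlas_high)
    is_tra = truth.table["is_tra"].to_numpy()
    breadth = truth.table["breadth"].to_numpy()
    for i in np.flatnonzero(is_tra):
        row = np.full(t, params.atlas_low)
        row[rng.choice(t, size=int(breadth[i]), replace=False)] = params.atlas_high
        values[i] = row
    if params.atlas_noise_sd > 0:
        values *= rng.lognormal(0.0, params.atlas_noise_sd, size=values.shape)
    atlas = TissueAtlas(
        pd.DataFrame(values, index=truth.gene_ids, columns=[f"tissue_{j + 1:02d}" for j in range(t)])
    )
    return atlas, truth


def simulate_gene_models(params: SimulationParams) -> list[GeneModel]:
    """Gene models tiled along one synthetic chromosome.

    Every gene planted as spliceable gets 2+ exons (hence >= 1 intron);
    single-exon genes are those the truth marks ``single_exon``. Genes are
    separated by a fixed spacer so no two genes overlap.
    """
    truth = simulation_truth(params)
    rng = _substream(params.seed, "models")
    models: list[GeneModel] = []
    cursor = params.gene_spacer
    single_exon = truth.table["single_exon"].to_numpy()
    for i, gid in enumerate(truth.gene_ids):
        n_exons = 1 if single_exon[i] else int(rng.integers(params.exons_per_gene[0], params.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for k in range(n_exons):
            ex_len = int(rng.integers(params.exon_length[0], params.exon_length[1] + 1))
            exons.append((pos, pos + ex_len))
            pos += ex_len
            if k < n_exons - 1:
                pos += int(rng.integers(params.intron_length[0], params.intron_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel.from_exons(gid, params.chrom, exons, strand=strand))
        cursor = pos + params.gene_spacer
    return models


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return np.round(mean).astype(np.int64)
    if dispersion == 0:
        return rng.poisson(mean).astype(np.int64)
    # gamma-Poisson mixture: var = mean + dispersion * mean^2
    shape = 1.0 / dispersion
    lam = np.where(mean > 0, rng.gamma(shape, np.maximum(mean, 1e-300) / shape), 0.0)
    return rng.poisson(lam).astype(np.int64)


def simulate_counts(
    params: SimulationParams,
    models: Sequence[GeneModel],
    design: pd.DataFrame,
) -> tuple[FeatureCountMatrix, SimulationTruth]:
    """Exon/intron count matrices for every sample in the design."""
    truth = simulation_truth(params)
    unknown = set(design["genotype"]) - set(GENOTYPES)
    if unknown:
        raise ParameterError(f"unknown genotype(s) in design: {sorted(unknown)}")
    by_id = {m.gene_id: m for m in models}
    missing = [g for g in truth.gene_ids if g not in by_id]
    if missing:
        raise DataError(f"{len(missing)} genes lack a model (first: {missing[0]})")
    rng = _substream(params.seed, "counts")
    exon = {}
    intron = {}
    for _, row in design.iterrows():
        sample, genotype = row["sample_id"], row["genotype"]
        mu = truth.table[f"mu_{genotype}"].to_numpy()
        pi = truth.table[f"pi_{genotype}"].to_numpy()
        exon[sample] = _draw_counts(rng, mu * (1.0 - pi), params.nb_dispersion)
        intron[sample] = _draw_counts(rng, mu * pi, params.nb_dispersion)
    gene_ids = truth.gene_ids
    counts = FeatureCountMatrix(
        exon=pd.DataFrame(exon, index=gene_ids),
        intron=pd.DataFrame(intron, index=gene_ids),
        exonic_length=pd.Series({g: by_id[g].exonic_length for g in gene_ids}, name="exonic_length"),
        intronic_length=pd.Series({g: by_id[g].intronic_length for g in gene_ids}, name="intronic_length"),
    )
    return counts, truth


def simulate_read_intervals(
    counts: FeatureCountMatrix,
    models: Sequence[GeneModel],
    read_length: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Place BED read intervals realizing a count matrix exactly.

    Per gene and sample, emits exactly ``exon_count`` reads fully inside a
    single exon and ``intron_count`` reads fully inside an intron, so
    re-counting the output with :func:`trasplice.counting.count_reads`
    reproduces the matrix bit-exactly.
    """
    by_id = {m.gene_id: m for m in models}
    missing = [g for g in counts.gene_ids if g not in by_id]
    if missing:
        raise DataError(f"{len(missing)} genes in counts lack a model (first: {missing[0]})")
    used = [by_id[g] for g in counts.gene_ids]
    features = [iv for m in used for iv in m.exons] + [iv for m in used for iv in m.introns]
    min_feature = min((e - s for s, e in features), default=read_length)
    if read_length > min_feature:
        raise ParameterError(
            f"read_length {read_length} exceeds smallest feature ({min_feature} bp)"
        )
    rng = _substream(seed, "reads")
    out: dict[str, pd.DataFrame] = {}
    for sample in counts.sample_ids:
        rows = []
        rid = 0
        for gid in counts.gene_ids:
            m = by_id[gid]
            for kind, n in (("exon", counts.exon.at[gid, sample]), ("intron", counts.intron.at[gid, sample])):
                n = int(n)
                if n == 0:
                    continue
                ivs = m.exons if kind == "exon" else m.introns
                if not ivs:
                    raise DataError(f"gene {gid} has {kind} counts but no {kind} intervals")
                widths = np.array([e - s - read_length + 1 for s, e in ivs], dtype=float)
                widths = np.maximum(widths, 0.0)
                pick = rng.choice(len(ivs), size=n, p=widths / widths.sum())
                for j in pick:
                    s0, e0 = ivs[j]
                    start = int(rng.integers(s0, e0 - read_length + 1))
                    rows.append((m.chrom, start, start + read_length, f"{sample}.r{rid}", 0, "+"))
                    rid += 1
        bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
        out[sample] = bed.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return out
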