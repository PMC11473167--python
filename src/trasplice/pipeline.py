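"""End-to-end orchestration: simulate -> classify -> count -> categorize ->
retention -> stats, from a single config with one global seed.

Every stage persists its table under the run directory and contributes to
a machine-readable ``report.json``; the same config and seed reproduce the
report bit for bit. When the run simulates its own data the report also
carries recovery metrics against the planted truth (category balanced
accuracy, retention-flag sensitivity and false-flag rate), which is how
the package checks itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trasplice._version import __version__
from trasplice.counting import (
    ExpressionTable,
    FeatureCountMatrix,
    count_reads,
    read_bed,
    read_gtf,
    rpkm,
    write_bed,
    write_gtf,
)
from trasplice.diffexpr import (
    TRA_CATEGORIES,
    categorize_tras,
    diff_test,
    expressed_filter,
    summarize_categories,
)
from trasplice.entropy import TissueAtlas, classify_tras
from trasplice.errors import ParameterError
from trasplice.retention import (
    category_retention_table,
    min_read_filter,
    retention_by_genotype,
    retention_fold_change,
)
from trasplice.simulate import (
    SimulationParams,
    make_design,
    simulate_atlas,
    simulate_counts,
    simulate_gene_models,
    simulate_read_intervals,
)
from trasplice.stats import (
    category_retention_tests,
    diversity_compare,
    diversity_table,
    pearson,
)

__all__ = ["Thresholds", "PipelineConfig", "run_pipeline", "make_report_figures"]

log = logging.getLogger("trasplice")


@dataclass
class Thresholds:
    """Every decision threshold of the analysis, at its default value."""

    entropy: float = 3.0  # bits; TRA iff entropy < this (strict)
    de_alpha: float = 0.05
    de_fc_down: float = 0.5
    de_fc_up: float = 2.0
    de_eps: float = 0.01
    retention_fc_up: float = 1.5
    retention_fc_down: float = 0.75
    retention_eps: float = 1e-3
    min_reads: int = 10
    q: float = 0.05

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ParameterError(f"threshold {name} must be positive, got {v}")


@dataclass
class PipelineConfig:
    """One run: either simulate all inputs or load them from files.

    Exactly one input mode applies: ``mode="simulate"`` generates atlas,
    models, design and counts from ``simulation``; ``mode="files"`` reads
    ``atlas_tsv``, ``design_tsv`` and either ``counts_tsv`` or ``gtf`` +
    per-sample BED files.
    """

    seed: int = 0
    out_dir: str = "trasplice_run"
    mode: str = "simulate"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    emit_reads: bool = False  # simulate BEDs and re-count them (slower)
    atlas_tsv: str | None = None
    design_tsv: str | None = None
    counts_tsv: str | None = None
    gtf: str | None = None
    beds: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    retention_aggregation: str = "pooled"

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ParameterError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        self.thresholds.validate()
        if self.mode == "files":
            if self.atlas_tsv is None or self.design_tsv is None:
                raise ParameterError("files mode requires atlas_tsv and design_tsv")
            if self.counts_tsv is None and (self.gtf is None or not self.beds):
                raise ParameterError("files mode requires counts_tsv, or gtf plus beds")
        else:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulation" in raw:
            raw["simulation"] = SimulationParams.from_dict(raw["simulation"])
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    """In-memory handles to everything a run produced (report + frames)."""

    report: dict
    atlas: TissueAtlas
    design: pd.DataFrame
    counts: FeatureCountMatrix
    expression: ExpressionTable
    entropy: pd.DataFrame
    diff: dict[str, pd.DataFrame]
    categories: pd.DataFrame
    retention: pd.DataFrame
    retention_fc: dict[str, pd.DataFrame]
    truth: pd.DataFrame | None = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (pd.Index, np.ndarray)):
        return list(o)
    return str(o)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis and persist every intermediate table."""
    config.validate()
    th = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "trasplice", "version": __version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    # -- inputs ------------------------------------------------------------
    truth_df = None
    if config.mode == "simulate":
        params = config.simulation
        params.seed = config.seed
        atlas, truth = simulate_atlas(params)
        models = simulate_gene_models(params)
        design = make_design(params)
        counts, _ = simulate_counts(params, models, design)
        truth_df = truth.table
        if config.emit_reads:
            beds = simulate_read_intervals(
                counts, models, read_length=params.read_length, seed=config.seed
            )
            for sample, bed in beds.items():
                write_bed(bed, out / f"reads_{sample}.bed")
            counts = count_reads(beds, models)
        atlas.to_tsv(out / "atlas.tsv")
        write_gtf(models, out / "models.gtf")
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        truth.to_tsv(out / "truth.tsv")
    else:
        atlas = TissueAtlas.from_tsv(config.atlas_tsv)
        design = pd.read_csv(config.design_tsv, sep="\t")
        if config.counts_tsv is not None:
            counts = FeatureCountMatrix.from_tsv(config.counts_tsv)
        else:
            models = read_gtf(config.gtf)
            beds = {s: read_bed(p) for s, p in config.beds.items()}
            counts = count_reads(beds, models)
    counts.to_tsv(out / "counts.tsv")
    report["stages"]["inputs"] = {
        "n_genes": len(counts.gene_ids),
        "n_samples": len(counts.sample_ids),
        "n_atlas_genes": len(atlas.gene_ids),
        "n_tissues": len(atlas.tissue_ids),
    }
    log.info("inputs: %s", report["stages"]["inputs"])

    # -- TRA classification ------------------------------------------------
    entropy_res = classify_tras(atlas, threshold=th.entropy)
    entropy_res.to_tsv(out / "entropy.tsv")
    tra_genes = entropy_res.tra_genes
    report["stages"]["classify"] = {
        "n_tra": len(tra_genes),
        "n_excluded_zero": len(entropy_res.excluded),
        "threshold_bits": th.entropy,
    }
    log.info("classify: %s", report["stages"]["classify"])

    # -- expression and differential tests ---------------------------------
    expr = rpkm(counts)
    expr.to_tsv(out / "rpkm.tsv")
    expressed = expressed_filter(expr, design, group="control")
    diff = {}
    for geno in ("prmt5_ko", "aire_ko"):
        diff[geno] = diff_test(
            expr,
            design,
            contrast=geno,
            alpha=th.de_alpha,
            fc_down=th.de_fc_down,
            fc_up=th.de_fc_up,
            eps=th.de_eps,
        )
        diff[geno].to_csv(out / f"diffexpr_{geno}.tsv", sep="\t", index_label="gene_id")
    report["stages"]["diffexpr"] = {
        "n_expressed": len(expressed),
        **{
            f"n_down_{g}": int(d["down"].sum()) for g, d in diff.items()
        },
        **{
            f"n_up_{g}": int(d["up"].sum()) for g, d in diff.items()
        },
    }
    log.info("diffexpr: %s", report["stages"]["diffexpr"])

    # -- categorization ----------------------------------------------------
    categories = categorize_tras(tra_genes, diff["prmt5_ko"], diff["aire_ko"], expressed)
    categories.to_csv(out / "categories.tsv", sep="\t", index_label="gene_id")
    summary = summarize_categories(categories)
    report["stages"]["categories"] = summary
    log.info("categories: %s", summary["counts"])

    # -- intron retention --------------------------------------------------
    spliceable = counts.gene_ids[counts.intronic_length.to_numpy() > 0]
    retention = retention_by_genotype(counts, design, aggregation=config.retention_aggregation)
    retention = retention.reindex(spliceable)
    retention.to_csv(out / "retention.tsv", sep="\t", index_label="gene_id")
    retention_fc = {}
    for geno in ("prmt5_ko", "aire_ko"):
        keep = min_read_filter(counts, design, geno, threshold=th.min_reads).intersection(spliceable)
        fc = retention_fold_change(
            retention[geno].reindex(keep),
            retention["control"].reindex(keep),
            eps=th.retention_eps,
            fc_up=th.retention_fc_up,
            fc_down=th.retention_fc_down,
        )
        retention_fc[geno] = fc
        fc.to_csv(out / f"retention_fc_{geno}.tsv", sep="\t", index_label="gene_id")
    report["stages"]["retention"] = {
        "n_spliceable": len(spliceable),
        "n_single_exon_excluded": int((counts.intronic_length.to_numpy() == 0).sum()),
        **{
            f"n_increased_{g}": int(fc["increased"].sum()) for g, fc in retention_fc.items()
        },
        **{
            f"n_decreased_{g}": int(fc["decreased"].sum()) for g, fc in retention_fc.items()
        },
    }
    log.info("retention: %s", report["stages"]["retention"])

    cat_summary = category_retention_table(
        retention,
        categories,
        fold_change=retention_fc["prmt5_ko"]["retention_fc"],
        top_k=30,
    )
    cat_summary.means.to_csv(out / "retention_category_means.tsv", sep="\t")
    cat_summary.top_panel.to_csv(out / "retention_top30.tsv", sep="\t", index_label="gene_id")

    # -- statistics --------------------------------------------------------
    stats_report: dict = {}
    div = diversity_table(expr, tra_genes.intersection(expressed), design)
    div.to_csv(out / "diversity.tsv", sep="\t")
    stats_report["diversity"] = diversity_compare(div)

    # retention change vs expression change over expressed TRA genes
    tra_expr = tra_genes.intersection(expressed).intersection(retention_fc["prmt5_ko"].index)
    rfc = retention_fc["prmt5_ko"]["retention_fc"].reindex(tra_expr)
    efc = diff["prmt5_ko"]["fold_change"].reindex(tra_expr)
    ok = rfc.notna() & efc.notna() & (efc > 0)
    if ok.sum() >= 3:
        r, p = pearson(np.log2(rfc[ok]), np.log2(efc[ok]))
        stats_report["retention_vs_expression"] = {"r": r, "p": p, "n": int(ok.sum())}
    else:
        stats_report["retention_vs_expression"] = {"r": None, "p": None, "n": int(ok.sum())}

    cat_tests = category_retention_tests(retention, categories)
    cat_tests.to_csv(out / "category_retention_tests.tsv", sep="\t", index=False)
    stats_report["category_retention_tests"] = cat_tests.to_dict(orient="records")
    report["stages"]["stats"] = stats_report
    log.info(
        "stats: diversity p(prmt5)=%.3g r=%s",
        stats_report["diversity"]["comparisons"].get("prmt5_ko", {}).get("p_value", float("nan")),
        stats_report["retention_vs_expression"]["r"],
    )

    # -- recovery against planted truth ------------------------------------
    if truth_df is not None:
        report["stages"]["recovery"] = _recovery_metrics(
            truth_df, categories, retention_fc["prmt5_ko"], report
        )
        log.info("recovery: %s", report["stages"]["recovery"])

    report_path = out / "report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    return RunResult(
        report=report,
        atlas=atlas,
        design=design,
        counts=counts,
        expression=expr,
        entropy=entropy_res.table,
        diff=diff,
        categories=categories,
        retention=retention,
        retention_fc=retention_fc,
        truth=truth_df,
    )


def _recovery_metrics(
    truth: pd.DataFrame, categories: pd.DataFrame, fc_prmt5: pd.DataFrame, report: dict
) -> dict:
    """Compare pipeline calls with the planted truth."""
    merged = truth.join(categories, how="inner")
    recalls = {}
    for cat in TRA_CATEGORIES:
        mask = merged["true_category"] == cat
        if mask.sum():
            recalls[cat] = float((merged.loc[mask, "category"] == cat).mean())
    balanced_accuracy = float(np.mean(list(recalls.values()))) if recalls else float("nan")

    deficient = merged.index[
        merged["planted_class"].isin(["prmt5_only", "shared"]) & ~merged["single_exon"]
    ]
    flagged = fc_prmt5["increased"]
    d_idx = pd.Index(deficient).intersection(flagged.index)
    sensitivity = float(flagged.reindex(d_idx).mean()) if len(d_idx) else float("nan")
    others = merged.index[merged["planted_class"] == "other"]
    o_idx = pd.Index(others).intersection(flagged.index)
    false_rate = float(flagged.reindex(o_idx).mean()) if len(o_idx) else float("nan")
    return {
        "per_class_recall": recalls,
        "balanced_accuracy": balanced_accuracy,
        "retention_flag_sensitivity": sensitivity,
        "retention_flag_false_rate": false_rate,
        "n_deficient_evaluated": len(d_idx),
        "n_other_evaluated": len(o_idx),
    }


def make_report_figures(run_dir, fig_dir=None) -> list[Path]:
    """Render presentation plots from a completed run directory.

    Purely presentational: reads the persisted TSVs and draws the DE
    scatter per contrast, the retention-vs-expression scatter, the
    retention fold-change bar panel, the category mean-retention heatmap
    and a PCA of sample expression. Empty panels are skipped with a note.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    fig_dir = Path(fig_dir) if fig_dir else run_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    eps = 0.01
    expr = pd.read_csv(run_dir / "rpkm.tsv", sep="\t", index_col="gene_id")
    design = pd.read_csv(run_dir / "design.tsv", sep="\t") if (run_dir / "design.tsv").exists() else None

    for geno in ("prmt5_ko", "aire_ko"):
        path = run_dir / f"diffexpr_{geno}.tsv"
        if not path.exists():
            continue
        de = pd.read_csv(path, sep="\t", index_col="gene_id")
        fig, ax = plt.subplots(figsize=(5, 5))
        x = np.log2(de["mean_control"] + eps)
        y = np.log2(de["mean_ko"] + eps)
        color = np.where(de["down"], "tab:blue", np.where(de["up"], "tab:red", "0.7"))
        ax.scatter(x, y, s=4, c=color, linewidths=0)
        lims = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.plot(lims, lims, color="k", lw=0.5)
        ax.set_xlabel("log2 RPKM, control")
        ax.set_ylabel(f"log2 RPKM, {geno}")
        ax.set_title(f"Differential expression: {geno}")
        p = fig_dir / f"de_scatter_{geno}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fc_path = run_dir / "retention_fc_prmt5_ko.tsv"
    de_path = run_dir / "diffexpr_prmt5_ko.tsv"
    if fc_path.exists() and de_path.exists():
        rfc = pd.read_csv(fc_path, sep="\t", index_col="gene_id")
        de = pd.read_csv(de_path, sep="\t", index_col="gene_id")
        joined = rfc.join(de["fold_change"], how="inner").dropna()
        joined = joined[joined["fold_change"] > 0]
        if len(joined) >= 3:
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.scatter(
                np.log2(joined["retention_fc"]), np.log2(joined["fold_change"]), s=6, c="0.4", linewidths=0
            )
            ax.set_xlabel("log2 retention fold change (KO/control)")
            ax.set_ylabel("log2 expression fold change (KO/control)")
            ax.set_title("Retention vs expression, Prmt5-cKO")
            p = fig_dir / "retention_vs_expression.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        srt = rfc["retention_fc"].dropna().sort_values(ascending=False)
        if len(srt):
            fig, ax = plt.subplots(figsize=(7, 3.5))
            colors = np.where(srt > 1.5, "tab:red", np.where(srt < 0.75, "tab:blue", "0.7"))
            ax.bar(range(len(srt)), np.log2(srt), color=colors, width=1.0)
            ax.set_xlabel("genes (ranked)")
            ax.set_ylabel("log2 retention fold change")
            ax.set_title("Intron retention change per gene, Prmt5-cKO")
            p = fig_dir / "retention_bar.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)

    means_path = run_dir / "retention_category_means.tsv"
    if means_path.exists():
        means = pd.read_csv(means_path, sep="\t", index_col="category")
        if means.size:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            im = ax.imshow(means.to_numpy(dtype=float), aspect="auto", cmap="viridis")
            ax.set_xticks(range(means.shape[1]), means.columns, rotation=45, ha="right")
            ax.set_yticks(range(means.shape[0]), means.index)
            fig.colorbar(im, ax=ax, label="mean intron ratio")
            ax.set_title("Mean intron retention by category")
            fig.tight_layout()
            p = fig_dir / "category_retention_heatmap.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        else:
            log.info("category means empty; heatmap omitted")

    if design is not None and len(expr.columns) >= 3:
        x = np.log2(expr.to_numpy(dtype=float).T + eps)
        x = x - x.mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        pcs = u[:, :2] * s[:2]
        var = s**2 / (s**2).sum()
        fig, ax = plt.subplots(figsize=(5, 4.5))
        for geno, sub in design.groupby("genotype"):
            idx = [expr.columns.get_loc(s_) for s_ in sub["sample_id"]]
            ax.scatter(pcs[idx, 0], pcs[idx, 1], label=geno, s=30)
        ax.set_xlabel(f"PC1 ({100 * var[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * var[1]:.1f}%)")
        ax.legend()
        ax.set_title("PCA of sample expression")
        fig.tight_layout()
        p = fig_dir / "pca.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
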