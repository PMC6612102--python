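"""End-to-end orchestration: ingest -> models -> contrasts -> calls -> reports.

`run_pipeline` executes the whole analysis on either a pair of
expression/clinical TSVs or a simulated cohort, and returns every
intermediate object plus a manifest of survivor counts at each filter.
`PipelineResult.write` emits the standard TSV reports and a JSON
manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import (
    ContrastResult,
    apply_contrasts,
    control_contrasts,
    interstage_contrasts,
)
from .groups import STAGES
from .ingest import (
    ExpressionDataset,
    drop_missing_stage,
    filter_low_variance,
    merge_clinical,
)
from .linmod import (
    GeneFitResults,
    LinModError,
    ModeratedStats,
    build_design,
    ebayes_moderate,
    estimate_meanvar_weights,
    fit_gene_models,
    regulation_status,
    results_table,
)
from .monotonic import classify_monotonic_frame, group_means, rank_monotonic
from .simulate import SimConfig, SyntheticTruth, generate_dataset
from .stagespec import (
    build_stage_calls,
    partition_report,
    prune_stage4,
    significance_cascade,
)


@dataclass
class PipelineConfig:
    """Thresholds and switches of the full analysis.

    Defaults are the published thresholds: sigma >= 1 gene filter,
    |lfc| > 2 differential-expression call, adjusted p < 0.001 versus
    control, raw p < 0.05 for inter-stage contrasts, adjusted p < 0.05
    for the monotonic screen, and top-10 stage-IV pruning. Mean-variance
    precision weights are applied to the genome-wide baseline scan only.
    """

    sigma_min: float = 1.0
    lfc_threshold: float = 2.0
    p_control: float = 0.001
    p_inter: float = 0.05
    p_monotonic: float = 0.05
    stage4_top_n: int = 10
    weights_baseline: bool = True
    weights_numeric: bool = False
    weights_cellmeans: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("sigma_min", "lfc_threshold"):
            if getattr(self, name) <= 0:
                raise LinModError(f"{name} must be positive")
        for name in ("p_control", "p_inter", "p_monotonic"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise LinModError(f"{name} must lie in (0, 1), got {v}")
        if self.stage4_top_n < 1:
            raise LinModError("stage4_top_n must be >= 1")


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: ExpressionDataset
    baseline_fits: GeneFitResults
    baseline_stats: ModeratedStats
    numeric_fits: GeneFitResults
    numeric_stats: ModeratedStats
    cellmeans_fits: GeneFitResults
    cellmeans_stats: ModeratedStats
    control_results: ContrastResult
    inter_results: ContrastResult
    calls: pd.DataFrame
    survivor_counts: pd.DataFrame
    partition_counts: pd.Series
    monotonic_table: pd.DataFrame
    stage_specific: pd.DataFrame
    stage4_pruned: list[str]
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_table(self.baseline_fits, self.baseline_stats).to_csv(
            out / "results_linear_model.tsv", sep="\t"
        )
        self.monotonic_table.to_csv(out / "results_monotonic.tsv", sep="\t")
        self.calls[
            ["bits", "stage", "tie"] + [f"lfc_{s}" for s in STAGES]
        ].to_csv(out / "stage_strings.tsv", sep="\t")
        self.stage_specific.to_csv(out / "stage_specific.tsv", sep="\t")
        self.partition_counts.to_csv(out / "partition_counts.tsv", sep="\t")
        self.survivor_counts.to_csv(out / "survivor_counts.tsv", sep="\t")
        self.control_results.long_frame().to_csv(
            out / "contrasts_control.tsv", sep="\t", index=False
        )
        self.inter_results.long_frame().to_csv(
            out / "contrasts_interstage.tsv", sep="\t", index=False
        )
        with (out / "manifest.json").open("w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _stage_specific_table(
    calls: pd.DataFrame, baseline_stats_frame: pd.DataFrame
) -> pd.DataFrame:
    """Final stage-specific gene table: lfcs, p-values, regulation status."""
    final = calls[calls["stage_specific"]].copy()
    lfc_cols = [f"lfc_{s}" for s in STAGES]
    final["regulation"] = [
        regulation_status(row) for row in final[lfc_cols].to_numpy()
    ]
    final["model_adj_p_F"] = baseline_stats_frame.loc[final.index, "adj_p_F"]
    cols = (
        ["stage", "bits"]
        + lfc_cols
        + ["p_control_adj", "p_inter_1", "p_inter_2", "p_inter_3", "model_adj_p_F", "regulation"]
    )
    final = final[cols]
    order = {s: i for i, s in enumerate(STAGES)}
    final = final.sort_values(
        ["stage", "model_adj_p_F"], key=lambda c: c.map(order) if c.name == "stage" else c,
        kind="stable",
    )
    return final


def run_pipeline(
    dataset: ExpressionDataset | None = None,
    expression: str | Path | pd.DataFrame | None = None,
    clinical: str | Path | pd.DataFrame | None = None,
    sim_config: SimConfig | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full stage-specificity analysis.

    Exactly one input source is used: an already annotated dataset, a
    pair of expression/clinical tables, or a simulation config. Execution
    order mirrors the published protocol: merge, variance filter,
    missing-stage removal, genome-wide baseline scan, numeric-stage
    model, cell-means fit with both contrast families, stage strings and
    the significance cascade, the monotonic screen, and stage-IV pruning.
    """
    config = config or PipelineConfig()
    truth: SyntheticTruth | None = None
    if sum(x is not None for x in (dataset, expression, sim_config)) != 1:
        raise LinModError("provide exactly one of dataset, expression(+clinical), sim_config")
    if sim_config is not None:
        dataset, truth = generate_dataset(sim_config)
    elif expression is not None:
        if clinical is None:
            raise LinModError("clinical table required alongside expression")
        dataset = merge_clinical(expression, clinical)

    n_genes_in, n_samples_in = dataset.n_genes, dataset.n_samples
    dataset = filter_low_variance(dataset, sigma_min=config.sigma_min)
    n_genes_filtered = dataset.n_genes
    dataset = drop_missing_stage(dataset)

    # Eq-style models: genome-wide baseline scan, numeric trend, cell means.
    baseline = build_design(dataset.groups, "baseline")
    w = estimate_meanvar_weights(dataset, baseline) if config.weights_baseline else None
    baseline_fits = fit_gene_models(dataset, baseline, weights=w)
    baseline_stats = ebayes_moderate(baseline_fits)

    numeric = build_design(dataset.groups, "numeric")
    wn = estimate_meanvar_weights(dataset, numeric) if config.weights_numeric else None
    numeric_fits = fit_gene_models(dataset, numeric, weights=wn)
    numeric_stats = ebayes_moderate(numeric_fits)

    cellmeans = build_design(dataset.groups, "cellmeans")
    wc = estimate_meanvar_weights(dataset, cellmeans) if config.weights_cellmeans else None
    cellmeans_fits = fit_gene_models(dataset, cellmeans, weights=wc)
    cellmeans_stats = ebayes_moderate(cellmeans_fits)

    control_results = apply_contrasts(cellmeans_fits, control_contrasts(), cellmeans_stats)
    inter_results = apply_contrasts(cellmeans_fits, interstage_contrasts(), cellmeans_stats)

    calls = build_stage_calls(control_results, threshold=config.lfc_threshold)
    calls, survivors = significance_cascade(
        calls,
        control_results,
        inter_results,
        p_control=config.p_control,
        p_inter=config.p_inter,
    )
    partitions = partition_report(calls)

    monotonic_table = rank_monotonic(
        dataset, numeric_fits, numeric_stats, p_max=config.p_monotonic
    )
    baseline_frame = baseline_stats.frame()
    stage_specific = _stage_specific_table(calls, baseline_frame)

    direction_all = classify_monotonic_frame(group_means(dataset))
    pruned = prune_stage4(
        calls,
        direction_all,
        pd.Series(baseline_stats.adj_p_f, index=baseline_fits.gene_ids),
        top_n=config.stage4_top_n,
    )

    n_assigned = int((calls["stage"] != "").sum())
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "seed": config.seed if sim_config is None else sim_config.seed,
        "n_genes_input": n_genes_in,
        "n_samples_input": n_samples_in,
        "n_genes_after_sigma_filter": n_genes_filtered,
        "n_samples_after_stage_filter": dataset.n_samples,
        "n_genes_analyzed": dataset.n_genes,
        "n_string_0000": int(partitions["0000"]),
        "n_stage_assigned": n_assigned,
        "n_stage_specific": {
            s: int((stage_specific["stage"] == s).sum()) for s in STAGES
        },
        "n_monotonic_significant": int(len(monotonic_table)),
        "n_monotonic_up": int((monotonic_table["direction"] == "UP").sum()),
        "n_monotonic_down": int((monotonic_table["direction"] == "DOWN").sum()),
        "n_stage4_pruned": len(pruned),
        "survivor_counts": {
            s: {k: int(v) for k, v in row.items()} for s, row in survivors.iterrows()
        },
        "variance_prior": {
            "baseline": [baseline_stats.df_prior, baseline_stats.var_prior],
            "numeric": [numeric_stats.df_prior, numeric_stats.var_prior],
            "cellmeans": [cellmeans_stats.df_prior, cellmeans_stats.var_prior],
        },
    }
    if truth is not None:
        manifest["simulated"] = True

    return PipelineResult(
        config=config,
        dataset=dataset,
        baseline_fits=baseline_fits,
        baseline_stats=baseline_stats,
        numeric_fits=numeric_fits,
        numeric_stats=numeric_stats,
        cellmeans_fits=cellmeans_fits,
        cellmeans_stats=cellmeans_stats,
        control_results=control_results,
        inter_results=inter_results,
        calls=calls,
        survivor_counts=survivors,
        partition_counts=partitions,
        monotonic_table=monotonic_table,
        stage_specific=stage_specific,
        stage4_pruned=list(pruned),
        manifest=manifest,
    )
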