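"""Two-pass differential-expression workflow.

Pass 1: normalize counts, fit the power-law error model on the baseline
condition, build the resampled null, and test every protein with the STN
statistic.  Proteins with p < 0.01 are confident calls; proteins in the
borderline band 0.01 ≤ p ≤ 0.05 move on to refinement.

Pass 2: the band proteins' replicate counts are MAI-refined (per
condition), the error model is re-fit on the refined matrix, the null pool
is rebuilt, and the band proteins are re-tested.  Band proteins reaching
p < 0.03 join the confident calls; first-pass calls are frozen and never
re-tested.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import (
    CountMatrix,
    FilterSummary,
    filter_identifications,
    normalize_counts,
    read_counts,
)
from .mai_refine import MaiAdjustment, adjustments_table, refine_protein
from .plgem_model import (
    PlgemFit,
    fit_plgem,
    loglog_regression_summary,
    variance_diagnostics,
)
from .stn_test import null_stn_distribution, stn_pvalues, stratified_pvalue_summary

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_first_pass",
    "run_refinement_pass",
    "merge_calls",
    "run_pipeline",
    "run_report",
]

# offset separating the pass-2 null-resampling stream from pass 1's
_PASS2_SEED_OFFSET = 9973


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the standard two-pass workflow
    (call at p < 0.01, refine the 0.01–0.05 band, re-call at p < 0.03)."""

    p_first: float = 0.01
    band_low: float = 0.01
    band_high: float = 0.05
    p_refined: float = 0.03
    baseline: str | None = None  # default: first condition in the design
    n_iter: int = 500
    seed: int = 0
    normalize: bool = True
    clamp_a: bool = True
    scale_null: bool = True
    null_mode: str = "auto"
    pseudocount: bool = False
    reuse_fit: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_first <= self.band_low <= self.band_high < 1):
            raise ValueError(
                "need 0 < p_first <= band_low <= band_high < 1, got "
                f"{self.p_first}, {self.band_low}, {self.band_high}"
            )
        if not 0 < self.p_refined < 1:
            raise ValueError("p_refined must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class PipelineResult:
    """Everything the two passes produced."""

    config: PipelineConfig
    matrix: CountMatrix  # normalized (or passed-through) pass-1 matrix
    refined_matrix: CountMatrix
    fit1: PlgemFit
    fit2: PlgemFit
    results1: pd.DataFrame
    results2: pd.DataFrame  # band proteins only
    adjustments: list[MaiAdjustment]
    report: pd.DataFrame  # merged per-protein call table
    filter_summary: FilterSummary | None = None

    @property
    def band_ids(self) -> pd.Index:
        return self.results2.index


def partition_first_pass(
    results: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Split first-pass results into (confident, band, rest) protein ids.

    The confident call is strict (p < p_first) while the band is inclusive
    on both ends, so p exactly at p_first falls in the band.
    """
    p = results["p_value"]
    confident = results.index[p < config.p_first]
    band = results.index[
        (p >= config.band_low) & (p <= config.band_high) & ~(p < config.p_first)
    ]
    rest = results.index.difference(confident.union(band))
    return confident, band, rest


def run_first_pass(
    matrix: CountMatrix, config: PipelineConfig
) -> tuple[PlgemFit, pd.DataFrame]:
    """Fit the error model on the baseline and test every protein."""
    baseline = config.baseline or matrix.conditions[0]
    fit = fit_plgem(matrix, baseline)
    null_pool = null_stn_distribution(
        matrix,
        fit,
        baseline,
        n_iter=config.n_iter,
        seed=config.seed,
        mode=config.null_mode,
        scale_to_design=config.scale_null,
    )
    results = stn_pvalues(
        matrix, fit, null_pool,
        pseudocount=config.pseudocount, pass_label="pass1",
    )
    return fit, results


def run_refinement_pass(
    matrix: CountMatrix,
    fit: PlgemFit,
    first_pass_results: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[CountMatrix, pd.DataFrame, list[MaiAdjustment]]:
    """MAI-refine the band proteins and re-test them.

    Only band proteins' counts change; the error model is re-fit on the
    refined matrix (unless ``config.reuse_fit``), the null pool is rebuilt
    from a fresh seeded stream, and p-values are recomputed for the band
    proteins alone.
    """
    _, band, _ = partition_first_pass(first_pass_results, config)
    refined_matrix = matrix.copy()
    records: list[MaiAdjustment] = []
    for pid in band:
        per_cond, recs = refine_protein(matrix, fit, pid, clamp=config.clamp_a)
        for cond, vals in per_cond.items():
            refined_matrix.counts.loc[pid, matrix.runs(cond)] = vals
        records.extend(recs)

    baseline = config.baseline or matrix.conditions[0]
    fit2 = fit if config.reuse_fit else fit_plgem(refined_matrix, baseline)
    null_pool = null_stn_distribution(
        refined_matrix,
        fit2,
        baseline,
        n_iter=config.n_iter,
        seed=config.seed + _PASS2_SEED_OFFSET,
        mode=config.null_mode,
        scale_to_design=config.scale_null,
    )
    results2 = stn_pvalues(
        refined_matrix, fit2, null_pool,
        pseudocount=config.pseudocount, pass_label="pass2",
    ).loc[band]
    return refined_matrix, results2, records


def merge_calls(
    first_pass: pd.DataFrame,
    refined: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Merge the two passes into one per-protein call table.

    call = ``first_pass`` if p₁ < p_first (frozen); else ``mai_refined``
    if the protein was in the band and its recomputed p < p_refined; else
    ``not_significant``.  Fold change and means come from the matrix of
    the protein's deciding pass.  The two call sets are disjoint by
    construction.
    """
    p1 = first_pass["p_value"]
    call = pd.Series("not_significant", index=first_pass.index, name="call")
    call[p1 < config.p_first] = "first_pass"
    rescued = refined.index[refined["p_value"] < config.p_refined]
    call[rescued] = "mai_refined"

    mean_a = first_pass["mean_a"].copy()
    mean_b = first_pass["mean_b"].copy()
    mean_a[refined.index] = refined["mean_a"]
    mean_b[refined.index] = refined["mean_b"]
    # first-pass calls report first-pass means
    firsts = call == "first_pass"
    mean_a[firsts] = first_pass.loc[firsts, "mean_a"]
    mean_b[firsts] = first_pass.loc[firsts, "mean_b"]

    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    p2 = refined["p_value"].reindex(first_pass.index)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_first": p1,
            "p_refined": p2,
            "call": call,
        },
        index=first_pass.index,
    )


def run_pipeline(
    matrix: CountMatrix,
    config: PipelineConfig | None = None,
    apply_filter: bool = False,
) -> PipelineResult:
    """Run the full two-pass workflow on an in-memory matrix."""
    config = config or PipelineConfig()
    summary = None
    if apply_filter:
        matrix, summary = filter_identifications(matrix)
    if config.normalize:
        matrix = normalize_counts(matrix)
    fit1, results1 = run_first_pass(matrix, config)
    refined_matrix, results2, records = run_refinement_pass(
        matrix, fit1, results1, config
    )
    report = merge_calls(results1, results2, config)
    baseline = config.baseline or matrix.conditions[0]
    fit2 = fit1 if config.reuse_fit else fit_plgem(refined_matrix, baseline)
    return PipelineResult(
        config=config,
        matrix=matrix,
        refined_matrix=refined_matrix,
        fit1=fit1,
        fit2=fit2,
        results1=results1,
        results2=results2,
        adjustments=records,
        report=report,
        filter_summary=summary,
    )


def run_files(
    counts_path, design_path, config: PipelineConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Read input files, run the pipeline, optionally write all outputs."""
    matrix = read_counts(counts_path, design_path)
    result = run_pipeline(matrix, config, apply_filter=True)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _dep_subset_r2(result: PipelineResult) -> dict:
    """Log-log regression R² over the called-DEP set, before vs after
    refinement (the variance-collapse diagnostic)."""
    called = result.report.index[result.report["call"] != "not_significant"]
    baseline = result.config.baseline or result.matrix.conditions[0]
    out: dict[str, float | None] = {"n_deps": int(len(called))}
    for label, mat in (("before", result.matrix), ("after", result.refined_matrix)):
        try:
            slope, intercept, r2 = loglog_regression_summary(
                mat, protein_subset=called, condition=baseline
            )
            out[label] = {"slope": slope, "intercept": intercept, "r_squared": r2}
        except ValueError:
            out[label] = None
    return out


def run_report(result: PipelineResult) -> dict:
    """Machine-readable summary of one pipeline run."""
    counts = result.report["call"].value_counts().to_dict()
    report = {
        "config": asdict(result.config),
        "conditions": list(result.matrix.conditions),
        "n_proteins": len(result.matrix),
        "filter_summary": (
            result.filter_summary.as_dict() if result.filter_summary else None
        ),
        "fit_pass1": result.fit1.as_dict(),
        "fit_pass2": result.fit2.as_dict(),
        "n_band": int(len(result.band_ids)),
        "calls": {
            "first_pass": int(counts.get("first_pass", 0)),
            "mai_refined": int(counts.get("mai_refined", 0)),
            "not_significant": int(counts.get("not_significant", 0)),
            "total_dep": int(
                counts.get("first_pass", 0) + counts.get("mai_refined", 0)
            ),
        },
        "stratified_p_pass1": stratified_pvalue_summary(
            result.results1, result.matrix
        ),
        "dep_loglog": _dep_subset_r2(result),
        "log_convention": "natural log for the error-model fit",
    }
    return report


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the TSV tables and JSON summary for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.rename_axis("protein_id").to_csv(
        out / "dep_report.tsv", sep="\t"
    )
    result.results1.rename_axis("protein_id").to_csv(
        out / "stn_pass1.tsv", sep="\t"
    )
    result.results2.rename_axis("protein_id").to_csv(
        out / "stn_pass2.tsv", sep="\t"
    )
    adjustments_table(result.adjustments).to_csv(
        out / "mai_audit.tsv", sep="\t", index=False
    )
    variance_diagnostics(result.matrix, result.fit1).to_csv(
        out / "diagnostics.tsv", sep="\t"
    )
    with open(out / "report.json", "w") as fh:
        json.dump(run_report(result), fh, indent=2)
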