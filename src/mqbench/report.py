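"""Full-study orchestration: design file in, report bundle out.

A study design (YAML or JSON) lists every data set with its three table
paths, run labels and sample matrix (plasma, CSF, ...), plus analysis
options.  :func:`run_pipeline` executes read -> standard filters -> outlier
screen -> per-data-set metric summary -> grouped comparisons and writes:

* ``metrics_summary.tsv`` -- one metric row per data set;
* ``metrics_detail.json`` -- per-replicate counts, completeness profiles
  and precision details;
* ``filter_report.tsv`` -- removal tallies per data set and level;
* ``scaled_comparison_absolute.tsv`` / ``scaled_comparison_relative.tsv``
  -- T1-vs-T2 scaled medians per metric and sample matrix (absolute counts
  and their percentage analogues);
* ``overlap_<matrix>_<tp>.tsv`` -- interlaboratory overlap curves;
* ``biomarkers.tsv`` -- panel presence matrix with LFQ CVs (when a panel
  is given);
* ``report.json`` -- every decision taken (filters, flagged/dropped
  outliers, thresholds), the design-file hash and the tool version.

Comparisons are grouped by sample matrix and never pooled across matrices.
All outputs are deterministic: identical inputs produce byte-identical
files, and nothing is written until the whole analysis has succeeded, so a
failure never leaves a silently partial report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .filtering import (
    DEFAULT_SPIKE_PATTERNS,
    FilterReport,
    OutlierRule,
    apply_standard_filters,
    detect_outlier_replicates,
    drop_replicates,
)
from .inter_comparison import (
    biomarker_matching,
    full_profile_accessions,
    overlap_curve,
    read_panel,
    scaled_median_comparison,
)
from .intra_metrics import (
    LFQ_CV_THRESHOLD,
    RT_CV_THRESHOLD,
    MetricSummary,
    percent_complete_profiles,
    summarize_dataset,
)
from .mq_io import DatasetBundle, load_dataset

__all__ = ["StudyDesign", "DatasetEntry", "AnalysisOptions", "PipelineError",
           "run_pipeline", "load_design"]


class PipelineError(RuntimeError):
    """A data-set failure, annotated with the data set and pipeline stage."""

    def __init__(self, dataset_id: str, stage: str, cause: Exception):
        super().__init__(f"data set {dataset_id!r} failed at stage {stage!r}: {cause}")
        self.dataset_id = dataset_id
        self.stage = stage


class DatasetEntry(BaseModel):
    dataset_id: str
    protein_groups: str
    peptides: str
    evidence: str
    run_labels: list[str]
    sample_matrix: Literal["plasma", "CSF", "other"] = "other"


class AnalysisOptions(BaseModel):
    rt_cv_threshold: float = RT_CV_THRESHOLD
    lfq_cv_threshold: float = LFQ_CV_THRESHOLD
    completeness_threshold: float = 100.0
    spike_patterns: list[str] = list(DEFAULT_SPIKE_PATTERNS)
    outlier_level: Literal["protein_group", "peptide", "precursor"] = "protein_group"
    outlier_min_fraction: float = 0.5
    drop_outliers: bool = False


class StudyDesign(BaseModel):
    datasets: list[DatasetEntry]
    panel: Optional[str] = None
    options: AnalysisOptions = Field(default_factory=AnalysisOptions)

    @field_validator("datasets")
    @classmethod
    def _unique_ids(cls, v: list[DatasetEntry]) -> list[DatasetEntry]:
        ids = [d.dataset_id for d in v]
        if len(set(ids)) != len(ids):
            raise ValueError("dataset_ids must be unique")
        for entry in v:
            paths = {entry.protein_groups, entry.peptides, entry.evidence}
            if len(paths) != 3:
                raise ValueError(
                    f"data set {entry.dataset_id!r} reuses a table path"
                )
        return v


def load_design(path: str | Path) -> StudyDesign:
    text = Path(path).read_text(encoding="utf-8")
    return StudyDesign.model_validate(yaml.safe_load(text))


# Metrics entering the T1-vs-T2 scaled comparison: absolute characteristics
# and, separately, their relative (percentage) analogues.
_ABSOLUTE_METRICS = (
    "median_protein_group_ids",
    "median_peptide_ids",
    "median_precursor_ids",
    "n_mc0",
    "n_full_profiles_protein_group",
    "n_full_profiles_peptide",
    "n_full_profiles_precursor",
    "n_rt_precise_precursors",
    "n_lfq_precise_protein_group",
    "n_lfq_precise_peptide",
)
_RELATIVE_METRICS = (
    "percent_zero_missed_cleavages",
    "percent_full_profiles_protein_group",
    "percent_full_profiles_peptide",
    "percent_full_profiles_precursor",
    "percent_rt_precise_precursors",
    "percent_lfq_precise_protein_group",
    "percent_lfq_precise_peptide",
)


@dataclass
class _DatasetResult:
    entry: DatasetEntry
    bundle: DatasetBundle
    filter_report: FilterReport
    outliers: list
    summary: MetricSummary


def _analyze_dataset(entry: DatasetEntry, options: AnalysisOptions) -> _DatasetResult:
    stage = "read"
    try:
        bundle = load_dataset(
            entry.dataset_id,
            entry.protein_groups,
            entry.peptides,
            entry.evidence,
            entry.run_labels,
        )
        stage = "filter"
        bundle, report = apply_standard_filters(bundle, options.spike_patterns)
        stage = "outlier_screen"
        rule = OutlierRule(
            metric_level=options.outlier_level,
            min_fraction_of_median=options.outlier_min_fraction,
        )
        outliers = (
            detect_outlier_replicates(bundle, rule)
            if bundle.n_replicates >= 3
            else []
        )
        if options.drop_outliers and outliers:
            bundle = drop_replicates(bundle, outliers)
        stage = "summarize"
        summary = summarize_dataset(
            bundle,
            rt_cv_threshold=options.rt_cv_threshold,
            lfq_cv_threshold=options.lfq_cv_threshold,
        )
    except Exception as exc:  # annotate with dataset and stage, then abort
        raise PipelineError(entry.dataset_id, stage, exc) from exc
    return _DatasetResult(entry, bundle, report, outliers, summary)


def _scaled_rows(results: Sequence[_DatasetResult], metrics: Sequence[str]) -> list[dict]:
    rows: list[dict] = []
    for matrix in sorted({r.entry.sample_matrix for r in results}):
        t1 = [r for r in results
              if r.entry.sample_matrix == matrix and r.bundle.time_point == "T1"]
        t2 = [r for r in results
              if r.entry.sample_matrix == matrix and r.bundle.time_point == "T2"]
        if not t1 or not t2:
            continue
        for metric in metrics:
            values_a = [r.summary.to_row()[metric] for r in t1]
            values_b = [r.summary.to_row()[metric] for r in t2]
            if any(v is None for v in values_a + values_b):
                continue
            cmp = scaled_median_comparison(values_a, values_b, metric)
            rows.append(
                {
                    "sample_matrix": matrix,
                    "metric": metric,
                    "median_T1": cmp.median_a,
                    "median_T2": cmp.median_b,
                    "scaled_T1": cmp.scaled_a,
                    "scaled_T2": cmp.scaled_b,
                    "difference_T2_minus_T1": cmp.difference,
                }
            )
    return rows


def run_pipeline(design_path: str | Path, out_dir: str | Path) -> dict:
    """Run the whole study analysis and write the report bundle.

    Returns the report dictionary that is also written to ``report.json``.
    Any data-set failure raises :class:`PipelineError` before anything is
    written.
    """
    design_path = Path(design_path)
    design = load_design(design_path)
    options = design.options

    results = [_analyze_dataset(entry, options) for entry in design.datasets]

    # --- per-data-set tables -------------------------------------------------
    summary_df = pd.DataFrame([r.summary.to_row() for r in results])
    filter_rows = []
    for r in results:
        for level, counts in r.filter_report.to_dict().items():
            filter_rows.append({"dataset_id": r.entry.dataset_id, "level": level,
                                **counts})
    filter_df = pd.DataFrame(filter_rows)

    # --- grouped comparisons -------------------------------------------------
    scaled_abs = pd.DataFrame(_scaled_rows(results, _ABSOLUTE_METRICS))
    scaled_rel = pd.DataFrame(_scaled_rows(results, _RELATIVE_METRICS))

    overlap_tables: dict[str, pd.DataFrame] = {}
    for matrix in sorted({r.entry.sample_matrix for r in results}):
        for tp in sorted({r.bundle.time_point for r in results
                          if r.entry.sample_matrix == matrix}):
            group = [r for r in results
                     if r.entry.sample_matrix == matrix
                     and r.bundle.time_point == tp]
            if len(group) < 2:
                continue
            sets = [
                full_profile_accessions(r.bundle, options.completeness_threshold)
                for r in group
            ]
            curve = overlap_curve(sets, [r.entry.dataset_id for r in group])
            overlap_tables[f"overlap_{matrix}_{tp}"] = pd.DataFrame(
                {
                    "k": range(1, len(group) + 1),
                    "dataset_id": curve.ordering,
                    "intersection": curve.intersection_sizes,
                    "union": curve.union_sizes,
                    "relative_overlap": curve.relative_overlap,
                }
            )

    biomarker_df = None
    biomarker_report = None
    if design.panel is not None:
        panel = read_panel(design.panel)
        match = biomarker_matching([r.bundle for r in results], panel)
        cv_by = {
            (m.dataset_id, m.accession): m.lfq_cv
            for ms in match.matches_by_dataset.values()
            for m in ms
        }
        rows = []
        for acc in match.panel:
            row: dict = {"accession": acc,
                         "presence_overall": match.presence_overall[acc]}
            for tp, by_acc in match.presence_by_time_point.items():
                row[f"presence_{tp}"] = by_acc[acc]
            for ds in match.dataset_ids:
                key = (ds, acc)
                row[f"matched_{ds}"] = int(key in cv_by)
                row[f"lfq_cv_{ds}"] = cv_by.get(key)
            rows.append(row)
        biomarker_df = pd.DataFrame(rows)
        biomarker_report = {
            "panel_size": match.panel_size,
            "matched_per_dataset": {
                ds: match.matched_count(ds) for ds in match.dataset_ids
            },
        }

    report = {
        "tool": "mqbench",
        "version": __version__,
        "design_file": design_path.name,
        "design_sha256": hashlib.sha256(design_path.read_bytes()).hexdigest(),
        "options": options.model_dump(),
        "datasets": [
            {
                "dataset_id": r.entry.dataset_id,
                "sample_matrix": r.entry.sample_matrix,
                "time_point": r.bundle.time_point,
                "n_replicates": r.bundle.n_replicates,
                "quant_column": r.bundle.quant_column,
                "filter_report": r.filter_report.to_dict(),
                "flagged_outliers": [o.render() for o in r.outliers],
                "outliers_dropped": bool(options.drop_outliers and r.outliers),
                "completeness": {
                    level: {
                        "count_by_k": {
                            str(k): v
                            for k, v in sorted(
                                r.summary.completeness[level].count_by_k.items()
                            )
                        },
                        "percent_full": percent_complete_profiles(
                            r.summary.completeness[level]
                        ),
                    }
                    for level in ("protein_group", "peptide", "precursor")
                },
                "per_replicate_ids": {
                    level: {
                        run.render(): n
                        for run, n in r.summary.id_counts[level].per_replicate.items()
                    }
                    for level in ("protein_group", "peptide", "precursor")
                },
            }
            for r in results
        ],
    }
    if biomarker_report is not None:
        report["biomarkers"] = biomarker_report

    # --- write everything at once -------------------------------------------
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_df.to_csv(out / "metrics_summary.tsv", sep="\t", index=False)
    filter_df.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    if not scaled_abs.empty:
        scaled_abs.to_csv(out / "scaled_comparison_absolute.tsv", sep="\t", index=False)
    if not scaled_rel.empty:
        scaled_rel.to_csv(out / "scaled_comparison_relative.tsv", sep="\t", index=False)
    for name, df in overlap_tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if biomarker_df is not None:
        biomarker_df.to_csv(out / "biomarkers.tsv", sep="\t", index=False)
    with open(out / "metrics_detail.json", "w", encoding="utf-8") as fh:
        json.dump(report["datasets"], fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "log.txt", "w", encoding="utf-8") as fh:
        for r in results:
            fh.write(
                f"{r.entry.dataset_id}: filtered "
                f"{sum(c['retained'] for c in r.filter_report.to_dict().values())} "
                f"rows retained; outliers flagged: "
                f"{', '.join(o.render() for o in r.outliers) or 'none'}\n"
            )
    return report
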