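"""Per-data-set performance metrics.

For one data set (ten technical replicates of the same sample on one LC-MS
setup) the metric suite quantifies:

* identification depth -- per-replicate ID counts and their median at the
  protein-group, peptide and precursor levels (a precursor is a modified
  peptide sequence at a specific charge state);
* digestion efficiency -- the fraction of distinct peptides with zero missed
  tryptic cleavage sites;
* data completeness -- for each feature, the number of replicates in which it
  was observed; a feature present in every replicate is a *full profile*
  (100% data completeness), and the headline statistic is the percentage of
  full profiles among all identified features;
* retention-time precision -- the percentage of precursors whose RT
  coefficient of variation across replicates is below 5%;
* quantitative precision -- the percentage of features whose intensity CV
  across replicates is below 20% (label-free quantification values at the
  protein-group level, summed intensities at the peptide level).

All operations expect a standard-filtered bundle (see
:mod:`mqbench.filtering`).  CVs use the sample (n-1) standard deviation, and
threshold comparisons are strict (< 5%, < 20%): a feature sitting exactly on
the threshold does not count as precise.  Features quantified in fewer than
two replicates are excluded from precision denominators rather than counted
as failures.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .mq_io import DatasetBundle, RunLabel

__all__ = [
    "Level",
    "IdCounts",
    "CompletenessProfile",
    "PrecisionResult",
    "MissedCleavageSummary",
    "MetricSummary",
    "count_identifications",
    "missed_cleavage_summary",
    "completeness_profile",
    "percent_complete_profiles",
    "feature_cv",
    "rt_precision",
    "quant_precision",
    "summarize_dataset",
]

Level = Literal["protein_group", "peptide", "precursor"]
LEVELS: tuple[Level, ...] = ("protein_group", "peptide", "precursor")

RT_CV_THRESHOLD = 5.0
LFQ_CV_THRESHOLD = 20.0


# ---------------------------------------------------------------------------
# Presence and per-replicate quantification
# ---------------------------------------------------------------------------

def presence_by_feature(
    bundle: DatasetBundle, level: Level
) -> dict[object, set[RunLabel]]:
    """Map each distinct feature at ``level`` to the replicates observing it.

    Presence means a non-missing quantification (protein group, peptide) or
    at least one evidence row (precursor).  Peptide identity is the distinct
    sequence; precursor identity is (modified sequence, charge).
    """
    presence: dict[object, set[RunLabel]] = {}
    if level == "protein_group":
        for row in bundle.protein_groups:
            if row.lfq_by_run:
                presence.setdefault(row.group_id, set()).update(row.lfq_by_run)
    elif level == "peptide":
        for row in bundle.peptides:
            if row.intensity_by_run:
                presence.setdefault(row.sequence, set()).update(row.intensity_by_run)
    elif level == "precursor":
        for row in bundle.evidence:
            presence.setdefault(row.precursor, set()).add(row.run)
    else:
        raise ValueError(f"unknown level {level!r}")
    return presence


def quant_values_by_feature(
    bundle: DatasetBundle, level: Level
) -> dict[object, dict[RunLabel, float]]:
    """Per-feature, per-replicate quantification values.

    Protein groups use their LFQ mapping; peptides their intensity mapping
    (duplicate sequences, if any, are summed per run); precursors use the
    median of their evidence intensities within each replicate, mirroring the
    RT treatment of multiple evidence rows per precursor per run.
    """
    values: dict[object, dict[RunLabel, float]] = {}
    if level == "protein_group":
        for row in bundle.protein_groups:
            if row.lfq_by_run:
                values[row.group_id] = dict(row.lfq_by_run)
    elif level == "peptide":
        for row in bundle.peptides:
            if not row.intensity_by_run:
                continue
            dest = values.setdefault(row.sequence, {})
            for run, v in row.intensity_by_run.items():
                dest[run] = dest.get(run, 0.0) + v
    elif level == "precursor":
        collected: dict[object, dict[RunLabel, list[float]]] = {}
        for row in bundle.evidence:
            if row.intensity is None:
                continue
            collected.setdefault(row.precursor, {}).setdefault(row.run, []).append(
                row.intensity
            )
        for prec, by_run in collected.items():
            values[prec] = {
                run: float(np.median(vals)) for run, vals in by_run.items()
            }
    else:
        raise ValueError(f"unknown level {level!r}")
    return values


@dataclass(frozen=True)
class IdCounts:
    level: Level
    per_replicate: Mapping[RunLabel, int]
    median: float


def count_identifications(bundle: DatasetBundle, level: Level) -> IdCounts:
    """Per-replicate identification counts and their median."""
    presence = presence_by_feature(bundle, level)
    per_rep = {run: 0 for run in bundle.runs}
    for runs in presence.values():
        for run in runs:
            per_rep[run] += 1
    med = float(statistics.median(per_rep.values())) if per_rep else 0.0
    return IdCounts(level=level, per_replicate=per_rep, median=med)


# ---------------------------------------------------------------------------
# Missed cleavages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissedCleavageSummary:
    counts: tuple[int, int, int]  # peptides with 0 / 1 / 2 missed cleavages
    total: int
    percent_zero: float | None  # None when no peptides were identified

    @property
    def percent_by_class(self) -> tuple[float, ...] | None:
        if self.total == 0:
            return None
        return tuple(100.0 * c / self.total for c in self.counts)


def missed_cleavage_summary(bundle: DatasetBundle) -> MissedCleavageSummary:
    """Digestion efficiency over distinct identified peptide sequences.

    Each distinct sequence contributes once (union over replicates); a
    sequence identified without quantification still counts as identified.
    """
    by_seq: dict[str, int] = {}
    for row in bundle.peptides:
        by_seq[row.sequence] = row.missed_cleavages
    counts = [0, 0, 0]
    for mc in by_seq.values():
        counts[mc] += 1
    total = len(by_seq)
    percent_zero = 100.0 * counts[0] / total if total else None
    return MissedCleavageSummary(
        counts=tuple(counts), total=total, percent_zero=percent_zero
    )


# ---------------------------------------------------------------------------
# Data completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompletenessProfile:
    """Counts of features by the number of replicates observing them."""

    level: Level
    n_replicates: int
    count_by_k: Mapping[int, int]

    @property
    def total_features(self) -> int:
        return sum(self.count_by_k.values())

    @property
    def n_full_profiles(self) -> int:
        return self.count_by_k.get(self.n_replicates, 0)


def completeness_profile(bundle: DatasetBundle, level: Level) -> CompletenessProfile:
    presence = presence_by_feature(bundle, level)
    count_by_k: dict[int, int] = {}
    for runs in presence.values():
        k = len(runs)
        if k:
            count_by_k[k] = count_by_k.get(k, 0) + 1
    return CompletenessProfile(
        level=level, n_replicates=bundle.n_replicates, count_by_k=count_by_k
    )


def percent_complete_profiles(profile: CompletenessProfile) -> float | None:
    """Full profiles divided by all identified features, times 100.

    Returns None for an empty profile (a percentage of nothing is not 0)."""
    total = profile.total_features
    if total == 0:
        return None
    return 100.0 * profile.n_full_profiles / total


# ---------------------------------------------------------------------------
# Precision (CV) metrics
# ---------------------------------------------------------------------------

def feature_cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    Requires at least two values; features with fewer observations are not
    evaluable and must be excluded from precision denominators upstream.
    """
    if len(values) < 2:
        raise ValueError("CV needs >= 2 values")
    mean = statistics.fmean(values)
    return 100.0 * statistics.stdev(values) / mean


@dataclass(frozen=True)
class PrecisionResult:
    level: Level
    dimension: Literal["retention_time", "lfq_intensity"]
    cv_threshold: float
    n_evaluable: int
    n_below_threshold: int

    @property
    def percent_below(self) -> float | None:
        if self.n_evaluable == 0:
            return None
        return 100.0 * self.n_below_threshold / self.n_evaluable


def _precision_from_values(
    per_feature: dict[object, dict[RunLabel, float]],
    level: Level,
    dimension: Literal["retention_time", "lfq_intensity"],
    cv_threshold: float,
) -> PrecisionResult:
    n_evaluable = 0
    n_below = 0
    for by_run in per_feature.values():
        if len(by_run) < 2:
            continue
        n_evaluable += 1
        if feature_cv(list(by_run.values())) < cv_threshold:
            n_below += 1
    return PrecisionResult(
        level=level,
        dimension=dimension,
        cv_threshold=cv_threshold,
        n_evaluable=n_evaluable,
        n_below_threshold=n_below,
    )


def rt_precision(
    bundle: DatasetBundle, cv_threshold: float = RT_CV_THRESHOLD
) -> PrecisionResult:
    """Percentage of precursors with retention-time CV strictly below the
    threshold.

    Each precursor contributes one RT per replicate -- the median over its
    evidence rows in that replicate, which resists split-peak artifacts when
    MaxQuant emits several evidence rows for one precursor in one run.
    """
    rts: dict[object, dict[RunLabel, list[float]]] = {}
    for row in bundle.evidence:
        rts.setdefault(row.precursor, {}).setdefault(row.run, []).append(
            row.retention_time
        )
    per_feature = {
        prec: {run: float(np.median(vals)) for run, vals in by_run.items()}
        for prec, by_run in rts.items()
    }
    return _precision_from_values(
        per_feature, "precursor", "retention_time", cv_threshold
    )


def quant_precision(
    bundle: DatasetBundle, level: Level, cv_threshold: float = LFQ_CV_THRESHOLD
) -> PrecisionResult:
    """Percentage of features whose intensity CV across replicates is
    strictly below the threshold."""
    per_feature = quant_values_by_feature(bundle, level)
    return _precision_from_values(per_feature, level, "lfq_intensity", cv_threshold)


# ---------------------------------------------------------------------------
# Summary row
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSummary:
    """One data set's row of all performance metrics."""

    dataset_id: str
    n_replicates: int
    id_counts: Mapping[Level, IdCounts]
    missed_cleavages: MissedCleavageSummary
    completeness: Mapping[Level, CompletenessProfile]
    rt_precision: PrecisionResult
    quant_precision: Mapping[Level, PrecisionResult]

    def to_row(self) -> dict:
        """Flatten into one TSV-friendly row with stable column names."""
        row: dict[str, object] = {
            "dataset_id": self.dataset_id,
            "n_replicates": self.n_replicates,
        }
        for level in LEVELS:
            row[f"median_{level}_ids"] = self.id_counts[level].median
        mc = self.missed_cleavages
        row["n_peptides"] = mc.total
        row["n_mc0"], row["n_mc1"], row["n_mc2"] = mc.counts
        row["percent_zero_missed_cleavages"] = mc.percent_zero
        for level in LEVELS:
            profile = self.completeness[level]
            row[f"n_full_profiles_{level}"] = profile.n_full_profiles
            row[f"percent_full_profiles_{level}"] = percent_complete_profiles(profile)
        row["n_rt_precise_precursors"] = self.rt_precision.n_below_threshold
        row["percent_rt_precise_precursors"] = self.rt_precision.percent_below
        for level, result in self.quant_precision.items():
            row[f"n_lfq_precise_{level}"] = result.n_below_threshold
            row[f"percent_lfq_precise_{level}"] = result.percent_below
        return row


def summarize_dataset(
    bundle: DatasetBundle,
    rt_cv_threshold: float = RT_CV_THRESHOLD,
    lfq_cv_threshold: float = LFQ_CV_THRESHOLD,
) -> MetricSummary:
    """Aggregate every metric into one deterministic summary row.

    Missing values (e.g. the zero-missed-cleavage percentage of an empty
    peptide table) propagate as None, never as fabricated zeros.
    """
    return MetricSummary(
        dataset_id=bundle.dataset_id,
        n_replicates=bundle.n_replicates,
        id_counts={lvl: count_identifications(bundle, lvl) for lvl in LEVELS},
        missed_cleavages=missed_cleavage_summary(bundle),
        completeness={lvl: completeness_profile(bundle, lvl) for lvl in LEVELS},
        rt_precision=rt_precision(bundle, rt_cv_threshold),
        quant_precision={
            lvl: quant_precision(bundle, lvl, lfq_cv_threshold)
            for lvl in ("protein_group", "peptide")
        },
    )
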