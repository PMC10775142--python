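"""Standard row filters and replicate outlier screening.

Before any performance metric is computed, the result tables are cleaned of
rows that do not represent genuine sample identifications: decoy hits
(reversed sequences), potential contaminants, protein groups only identified
by a modification site, and spiked-in retention-time calibration peptides
(PROCAL iRT).  Each removal is tallied per table level so the report can
account for every input row.

Separately, technical replicates whose identification count collapses far
below the data set's median can be flagged as outliers.  Flagging never
mutates the bundle: dropping a flagged replicate is an explicit second step,
so the decision is always visible in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Literal, Sequence

from .mq_io import DatasetBundle, RunLabel

__all__ = [
    "LevelFilterCounts",
    "FilterReport",
    "OutlierRule",
    "DEFAULT_SPIKE_PATTERNS",
    "apply_standard_filters",
    "detect_outlier_replicates",
    "drop_replicates",
]

DEFAULT_SPIKE_PATTERNS = ("PROCAL",)

Level = Literal["protein_group", "peptide", "precursor"]


@dataclass(frozen=True)
class LevelFilterCounts:
    """Removal tally for one table level; categories are first-match in the
    order reverse -> contaminant -> only-by-site -> spike-in."""

    removed_reverse: int = 0
    removed_contaminant: int = 0
    removed_only_by_site: int = 0
    removed_spike_in: int = 0
    retained: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.removed_reverse
            + self.removed_contaminant
            + self.removed_only_by_site
            + self.removed_spike_in
        )

    @property
    def input_rows(self) -> int:
        return self.total_removed + self.retained


@dataclass(frozen=True)
class FilterReport:
    protein_group: LevelFilterCounts
    peptide: LevelFilterCounts
    precursor: LevelFilterCounts

    def to_dict(self) -> dict:
        return {
            level: vars(getattr(self, level))
            for level in ("protein_group", "peptide", "precursor")
        }


@dataclass(frozen=True)
class OutlierRule:
    """A replicate is an outlier when its ID count at ``metric_level`` falls
    strictly below ``min_fraction_of_median`` of the median count."""

    metric_level: Level = "protein_group"
    min_fraction_of_median: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction_of_median < 1:
            raise ValueError(
                "min_fraction_of_median must lie in (0, 1), got "
                f"{self.min_fraction_of_median}"
            )


def _matches_any(patterns: Sequence[str], *texts: str) -> bool:
    return any(p in t for p in patterns for t in texts)


def apply_standard_filters(
    bundle: DatasetBundle,
    spike_in_patterns: Sequence[str] = DEFAULT_SPIKE_PATTERNS,
) -> tuple[DatasetBundle, FilterReport]:
    """Remove decoy, contaminant, only-by-site and spike-in rows.

    Spike-in patterns are substring-matched against accessions (protein
    level) and sequences (peptide and precursor levels).  The only-by-site
    category exists only at the protein-group level; the other tables carry
    no such flag.  Each removed row is counted once, under the first category
    that matches.
    """
    pg_counts = [0, 0, 0, 0]
    kept_pg = []
    for row in bundle.protein_groups:
        if row.is_reverse:
            pg_counts[0] += 1
        elif row.is_contaminant:
            pg_counts[1] += 1
        elif row.only_by_site:
            pg_counts[2] += 1
        elif _matches_any(spike_in_patterns, *row.majority_accessions):
            pg_counts[3] += 1
        else:
            kept_pg.append(row)

    pep_counts = [0, 0, 0, 0]
    kept_pep = []
    for row in bundle.peptides:
        if row.is_reverse:
            pep_counts[0] += 1
        elif row.is_contaminant:
            pep_counts[1] += 1
        elif _matches_any(spike_in_patterns, row.sequence):
            pep_counts[3] += 1
        else:
            kept_pep.append(row)

    ev_counts = [0, 0, 0, 0]
    kept_ev = []
    for row in bundle.evidence:
        if row.is_reverse:
            ev_counts[0] += 1
        elif row.is_contaminant:
            ev_counts[1] += 1
        elif _matches_any(spike_in_patterns, row.modified_sequence):
            ev_counts[3] += 1
        else:
            kept_ev.append(row)

    filtered = replace(
        bundle,
        protein_groups=tuple(kept_pg),
        peptides=tuple(kept_pep),
        evidence=tuple(kept_ev),
    )
    report = FilterReport(
        protein_group=LevelFilterCounts(*pg_counts, retained=len(kept_pg)),
        peptide=LevelFilterCounts(*pep_counts, retained=len(kept_pep)),
        precursor=LevelFilterCounts(*ev_counts, retained=len(kept_ev)),
    )
    return filtered, report


def detect_outlier_replicates(
    bundle: DatasetBundle, rule: OutlierRule = OutlierRule()
) -> list[RunLabel]:
    """Flag replicates whose ID count collapses below the rule's cutoff.

    The bundle must already be standard-filtered and contain at least three
    replicates (a median over fewer runs is not a meaningful screening
    baseline).  The returned labels are flagged only; removal is the caller's
    explicit decision via :func:`drop_replicates`.
    """
    from .intra_metrics import count_identifications

    if bundle.n_replicates < 3:
        raise ValueError(
            "outlier screening needs >= 3 replicates, got "
            f"{bundle.n_replicates} in {bundle.dataset_id!r}"
        )
    counts = count_identifications(bundle, rule.metric_level).per_replicate
    cutoff = rule.min_fraction_of_median * median(counts.values())
    return [run for run in bundle.runs if counts[run] < cutoff]


def drop_replicates(
    bundle: DatasetBundle, runs_to_drop: Sequence[RunLabel]
) -> DatasetBundle:
    """Remove whole replicates (their columns/rows) from a bundle."""
    drop = set(runs_to_drop)
    stray = drop - set(bundle.runs)
    if stray:
        raise ValueError(
            f"cannot drop runs absent from {bundle.dataset_id!r}: "
            f"{sorted(r.render() for r in stray)}"
        )
    kept_runs = tuple(r for r in bundle.runs if r not in drop)
    new_pg = []
    for row in bundle.protein_groups:
        lfq = {r: v for r, v in row.lfq_by_run.items() if r not in drop}
        new_pg.append(replace(row, lfq_by_run=lfq))
    new_pep = []
    for row in bundle.peptides:
        ints = {r: v for r, v in row.intensity_by_run.items() if r not in drop}
        new_pep.append(replace(row, intensity_by_run=ints))
    new_ev = tuple(row for row in bundle.evidence if row.run not in drop)
    out = replace(
        bundle,
        runs=kept_runs,
        protein_groups=tuple(new_pg),
        peptides=tuple(new_pep),
        evidence=new_ev,
    )
    out.validate()
    return out
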