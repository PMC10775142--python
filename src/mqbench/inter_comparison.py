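"""Cross-data-set comparability analyses.

Three questions about a multicenter study are answered here:

* Did performance change between measurement rounds?  For each metric the
  medians over the T1 and T2 data sets are put on a common percentage scale
  (both divided by the larger of the two, times 100) so that the T2-T1
  difference reads directly in percentage points.
* How consistent are protein detections across laboratories?  Each data
  set's full-profile protein accessions (detected in every technical
  replicate, optionally relaxed to a lower completeness threshold) are
  intersected over an ordered sequence of data sets, yielding the
  declining-overlap / saturating-union curves typical of round-robin
  studies.
* Are clinically relevant proteins reliably covered?  A biomarker panel
  (plain accession list) is matched against each data set's full-profile
  accessions, with the matched protein group's LFQ CV attached and each
  panel member's presence percentage across data sets reported overall and
  per time point.

Interlaboratory identity is compared on *accessions expanded from the
"Majority protein IDs"*: an accession counts as detected when any
full-profile group lists it.  Laboratories group proteins differently, and
accession expansion is the only comparison rule symmetric under regrouping.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intra_metrics import feature_cv, presence_by_feature
from .mq_io import DatasetBundle

__all__ = [
    "ScaledComparison",
    "OverlapCurve",
    "BiomarkerMatch",
    "BiomarkerMatchResult",
    "scaled_median_comparison",
    "full_profile_accessions",
    "overlap_curve",
    "match_accession",
    "biomarker_matching",
    "read_panel",
]


# ---------------------------------------------------------------------------
# Scaled T1-vs-T2 comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaledComparison:
    """Two group medians on a common max=100 percentage scale."""

    metric_name: str
    median_a: float
    median_b: float
    scaled_a: float | None
    scaled_b: float | None

    @property
    def difference(self) -> float | None:
        """scaled_b - scaled_a, in percentage points."""
        if self.scaled_a is None or self.scaled_b is None:
            return None
        return self.scaled_b - self.scaled_a


def scaled_median_comparison(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric_name: str = "",
) -> ScaledComparison:
    """Compare two groups of per-data-set metric values.

    The median of each group is divided by the larger of the two medians and
    multiplied by 100; the difference is reported in percentage points.  When
    both medians are zero the comparison is undefined and the scaled values
    are None.
    """
    if not values_a or not values_b:
        raise ValueError("both value lists must be non-empty")
    if any(v < 0 for v in values_a) or any(v < 0 for v in values_b):
        raise ValueError("metric values must be >= 0")
    med_a = float(statistics.median(values_a))
    med_b = float(statistics.median(values_b))
    top = max(med_a, med_b)
    if top == 0:
        return ScaledComparison(metric_name, med_a, med_b, None, None)
    return ScaledComparison(
        metric_name, med_a, med_b, 100.0 * med_a / top, 100.0 * med_b / top
    )


# ---------------------------------------------------------------------------
# Overlap / saturation analysis
# ---------------------------------------------------------------------------

def full_profile_accessions(
    bundle: DatasetBundle, completeness_threshold: float = 100.0
) -> set[str]:
    """Accessions of protein groups meeting the completeness threshold.

    An accession is included iff some protein group listing it among its
    majority accessions is present in at least ``ceil(threshold/100 * n)``
    of the ``n`` replicates ("at least 80% data completeness" with ten
    replicates means >= 8 of 10).  At the default threshold of 100 this is
    the full-profile set.
    """
    if not 0 < completeness_threshold <= 100:
        raise ValueError(
            f"completeness threshold must lie in (0, 100], got "
            f"{completeness_threshold}"
        )
    n = bundle.n_replicates
    # tiny epsilon so e.g. 80% of 10 gives exactly 8 despite float rounding
    k_min = math.ceil(completeness_threshold * n / 100.0 - 1e-9)
    present_runs = presence_by_feature(bundle, "protein_group")
    by_group = {row.group_id: row for row in bundle.protein_groups}
    accessions: set[str] = set()
    for group_id, runs in present_runs.items():
        if len(runs) >= k_min:
            accessions.update(by_group[group_id].majority_accessions)
    return accessions


@dataclass(frozen=True)
class OverlapCurve:
    """Running intersection/union over an ordered sequence of data sets."""

    ordering: tuple[str, ...]
    intersection_sizes: tuple[int, ...]
    union_sizes: tuple[int, ...]

    @property
    def relative_overlap(self) -> tuple[float, ...]:
        """100 * intersection / union per step (nan where the union is empty)."""
        return tuple(
            100.0 * i / u if u else float("nan")
            for i, u in zip(self.intersection_sizes, self.union_sizes)
        )

    @property
    def terminal_intersection(self) -> int:
        return self.intersection_sizes[-1]

    @property
    def terminal_union(self) -> int:
        return self.union_sizes[-1]


def overlap_curve(
    accession_sets: Sequence[set[str]],
    ordering: Sequence[str] | None = None,
) -> OverlapCurve:
    """Running intersection and union of accession sets, in caller order.

    Absolute overlap declines (or stays) with each added data set while the
    union saturates; the intermediate curve depends on the ordering but the
    terminal values do not.
    """
    if not accession_sets:
        raise ValueError("need at least one accession set")
    if ordering is None:
        ordering = tuple(str(i + 1) for i in range(len(accession_sets)))
    if len(ordering) != len(accession_sets):
        raise ValueError("ordering and accession_sets must align")
    inter = set(accession_sets[0])
    union: set[str] = set()
    inters: list[int] = []
    unions: list[int] = []
    for s in accession_sets:
        inter &= s
        union |= s
        inters.append(len(inter))
        unions.append(len(union))
    return OverlapCurve(
        ordering=tuple(ordering),
        intersection_sizes=tuple(inters),
        union_sizes=tuple(unions),
    )


# ---------------------------------------------------------------------------
# Biomarker panel matching
# ---------------------------------------------------------------------------

def match_accession(majority_accessions: Sequence[str], reference: str) -> bool:
    """Exact string match of a reference accession against a group's list.

    Isoform suffixes are deliberately not stripped: "P02768-2" does not
    match "P02768".
    """
    return any(reference == acc for acc in majority_accessions)


def read_panel(path) -> tuple[str, ...]:
    """Read a biomarker panel: one accession per line, '#' comments allowed."""
    accessions: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                accessions.append(line)
    return tuple(accessions)


@dataclass(frozen=True)
class BiomarkerMatch:
    accession: str
    dataset_id: str
    lfq_cv: float | None  # None when < 2 quantified replicates
    ambiguous: bool  # several full-profile groups list this accession


@dataclass(frozen=True)
class BiomarkerMatchResult:
    panel: tuple[str, ...]
    dataset_ids: tuple[str, ...]
    matches_by_dataset: Mapping[str, tuple[BiomarkerMatch, ...]]
    presence_overall: Mapping[str, float]  # accession -> % of data sets
    presence_by_time_point: Mapping[str, Mapping[str, float]]  # tp -> acc -> %

    @property
    def panel_size(self) -> int:
        return len(self.panel)

    def matched_count(self, dataset_id: str) -> int:
        return len(self.matches_by_dataset[dataset_id])


def _pick_group(candidates, accession):
    """Among several matching groups, prefer the one quantified in the most
    replicates, breaking ties by higher median intensity."""
    def key(row):
        values = list(row.lfq_by_run.values())
        return (len(values), float(np.median(values)) if values else 0.0)
    return max(candidates, key=key)


def biomarker_matching(
    bundles: Sequence[DatasetBundle], panel: Sequence[str]
) -> BiomarkerMatchResult:
    """Match a biomarker panel against each data set's full-profile proteins.

    A panel accession matches a data set when it appears in that data set's
    full-profile accession set (100% completeness).  Each match is annotated
    with the LFQ CV of the matched protein group; when several full-profile
    groups list the accession, the group quantified in the most replicates
    (ties: higher median LFQ) supplies the CV and the match is flagged
    ambiguous.  Presence is the percentage of data sets matching, reported
    over all data sets and per time point; unmatched panel members are
    reported with presence 0, never dropped.
    """
    panel = tuple(panel)
    if not panel:
        raise ValueError("biomarker panel is empty")
    matches_by_dataset: dict[str, tuple[BiomarkerMatch, ...]] = {}
    matched_sets: dict[str, set[str]] = {}
    for bundle in bundles:
        n = bundle.n_replicates
        full_groups = [
            row
            for row in bundle.protein_groups
            if len(row.lfq_by_run) >= n and row.lfq_by_run
        ]
        matches: list[BiomarkerMatch] = []
        hit: set[str] = set()
        for accession in panel:
            candidates = [
                row for row in full_groups
                if match_accession(row.majority_accessions, accession)
            ]
            if not candidates:
                continue
            hit.add(accession)
            group = _pick_group(candidates, accession)
            values = list(group.lfq_by_run.values())
            cv = feature_cv(values) if len(values) >= 2 else None
            matches.append(
                BiomarkerMatch(
                    accession=accession,
                    dataset_id=bundle.dataset_id,
                    lfq_cv=cv,
                    ambiguous=len(candidates) > 1,
                )
            )
        matches_by_dataset[bundle.dataset_id] = tuple(matches)
        matched_sets[bundle.dataset_id] = hit

    dataset_ids = tuple(b.dataset_id for b in bundles)
    presence_overall = {
        acc: 100.0 * sum(acc in matched_sets[d] for d in dataset_ids) / len(bundles)
        for acc in panel
    }
    by_tp: dict[str, dict[str, float]] = {}
    for tp in sorted({b.time_point for b in bundles}):
        tp_ids = [b.dataset_id for b in bundles if b.time_point == tp]
        by_tp[tp] = {
            acc: 100.0 * sum(acc in matched_sets[d] for d in tp_ids) / len(tp_ids)
            for acc in panel
        }
    return BiomarkerMatchResult(
        panel=panel,
        dataset_ids=dataset_ids,
        matches_by_dataset=matches_by_dataset,
        presence_overall=presence_overall,
        presence_by_time_point=by_tp,
    )
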