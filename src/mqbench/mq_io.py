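"""Reading MaxQuant-dialect result tables into per-data-set bundles.

A label-free LC-MS workflow produces three tab-separated result tables per
data set (one data set = one laboratory x LC-MS setup x acquisition mode x
time point, measured in ~10 technical replicates):

* ``proteinGroups.txt`` -- one row per protein group, with semicolon-joined
  "Majority protein IDs" and one quantification column per run
  (``LFQ intensity <label>``, falling back to ``Intensity <label>``);
* ``peptides.txt`` -- one row per peptide sequence, with the
  "Missed cleavages" count and per-run ``Intensity <label>`` columns;
* ``evidence.txt`` -- one row per precursor observation (modified sequence,
  charge, retention time, intensity, raw file).

This module parses those tables into typed rows, resolves run identities from
underscore-delimited labels such as ``T2_LabD_nanoElute_timspro_DIA_R10``, and
assembles validated :class:`DatasetBundle` objects that every downstream
metric consumes.

Conventions of the dialect handled here:

* flag columns ("Reverse", "Potential contaminant", "Only identified by
  site") hold ``+`` when set and are empty otherwise;
* a quantification value of ``0`` (or an empty cell) means *not quantified in
  that run* -- it is stored as a missing value, never as a numeric zero;
* the acquisition segment of a run label is optional and defaults to DDA.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AcquisitionMode",
    "RunLabel",
    "ProteinGroupRow",
    "PeptideRow",
    "EvidenceRow",
    "DatasetBundle",
    "LabelParseError",
    "FormatError",
    "ConsistencyError",
    "parse_run_label",
    "render_run_label",
    "read_protein_groups",
    "read_peptides",
    "read_evidence",
    "assemble_dataset",
]

TIME_POINTS = ("T1", "T2")
ACQUISITIONS = ("DDA", "DIA")

# MaxQuant header drift across adjacent versions: canonical name -> aliases.
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "Potential contaminant": ("Potential contaminant", "Contaminant"),
    "Only identified by site": ("Only identified by site",),
    "Reverse": ("Reverse",),
    "Majority protein IDs": ("Majority protein IDs",),
    "Sequence": ("Sequence",),
    "Missed cleavages": ("Missed cleavages",),
    "Modified sequence": ("Modified sequence",),
    "Charge": ("Charge",),
    "Retention time": ("Retention time",),
    "Intensity": ("Intensity",),
    "Raw file": ("Raw file",),
}

MAX_MISSED_CLEAVAGES = 2


class LabelParseError(ValueError):
    """A run label does not follow <T#>_<Lab>_<LC>_<MS>[_<acq>]_R<n>."""


class FormatError(ValueError):
    """A result table violates the expected MaxQuant dialect."""


class ConsistencyError(ValueError):
    """The three tables of a data set disagree about the replicate set."""


AcquisitionMode = str  # "DDA" | "DIA"


@dataclass(frozen=True, order=True)
class RunLabel:
    """Identity of one technical replicate.

    ``T2_LabD_nanoElute_timspro_DIA_R10`` encodes time point T2, laboratory
    LabD, LC system nanoElute, MS instrument timspro, DIA acquisition,
    replicate 10.  The acquisition segment may be absent in rendered labels,
    in which case DDA is implied.
    """

    time_point: str
    lab: str
    lc_system: str
    ms_instrument: str
    acquisition: AcquisitionMode
    replicate_index: int

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise LabelParseError(f"unknown time point {self.time_point!r}")
        if self.acquisition not in ACQUISITIONS:
            raise LabelParseError(f"unknown acquisition mode {self.acquisition!r}")
        if self.replicate_index < 1:
            raise LabelParseError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )

    @property
    def setup(self) -> str:
        """Laboratory/LC/MS/acquisition identity shared by all replicates."""
        return f"{self.lab}_{self.lc_system}_{self.ms_instrument}_{self.acquisition}"

    def render(self) -> str:
        return render_run_label(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_TP_RE = re.compile(r"^T[0-9]+$")
_REP_RE = re.compile(r"^R([0-9]+)$")


def parse_run_label(text: str) -> RunLabel:
    """Parse an underscore-delimited run label into a :class:`RunLabel`.

    The shape is ``<T#>_<Lab>_<LC>_<MS>[_<acq>]_R<n>``; the acquisition
    segment defaults to ``DDA`` when absent.

    >>> parse_run_label("T2_LabF_ultimate_qexachf_R10").acquisition
    'DDA'
    """
    parts = text.split("_")
    if len(parts) < 5:
        raise LabelParseError(
            f"run label {text!r} has {len(parts)} segments; "
            "expected <T#>_<Lab>_<LC>_<MS>[_<acq>]_R<n>"
        )
    if not _TP_RE.match(parts[0]):
        raise LabelParseError(
            f"run label {text!r}: leading segment {parts[0]!r} is not a "
            "time point (expected T1, T2, ...)"
        )
    rep_match = _REP_RE.match(parts[-1])
    if rep_match is None:
        raise LabelParseError(
            f"run label {text!r}: trailing segment {parts[-1]!r} is not a "
            "replicate token (expected R<n>)"
        )
    middle = parts[1:-1]
    if len(middle) == 4:
        acquisition = middle[3]
        if acquisition not in ACQUISITIONS:
            raise LabelParseError(
                f"run label {text!r}: segment {acquisition!r} is neither an "
                "acquisition mode (DDA/DIA) nor part of a 3-segment setup"
            )
        lab, lc, ms = middle[:3]
    elif len(middle) == 3:
        lab, lc, ms = middle
        acquisition = "DDA"
    else:
        raise LabelParseError(
            f"run label {text!r}: expected 3 setup segments plus an optional "
            f"acquisition segment, found {len(middle)}"
        )
    return RunLabel(
        time_point=parts[0],
        lab=lab,
        lc_system=lc,
        ms_instrument=ms,
        acquisition=acquisition,
        replicate_index=int(rep_match.group(1)),
    )


def render_run_label(label: RunLabel) -> str:
    """Render a label to text; ``parse_run_label`` inverts this exactly.

    The acquisition segment is always written, so DDA labels round-trip even
    though the parser also accepts the abbreviated form without it.
    """
    return (
        f"{label.time_point}_{label.lab}_{label.lc_system}_"
        f"{label.ms_instrument}_{label.acquisition}_R{label.replicate_index}"
    )


@dataclass(frozen=True)
class ProteinGroupRow:
    group_id: str
    majority_accessions: tuple[str, ...]
    is_reverse: bool
    is_contaminant: bool
    only_by_site: bool
    lfq_by_run: Mapping[RunLabel, float]

    def __post_init__(self) -> None:
        if not self.majority_accessions:
            raise FormatError(f"protein group {self.group_id!r} has no accessions")
        for run, value in self.lfq_by_run.items():
            if not value > 0:
                raise FormatError(
                    f"protein group {self.group_id!r}: non-positive intensity "
                    f"{value!r} for run {run.render()}"
                )


@dataclass(frozen=True)
class PeptideRow:
    sequence: str
    missed_cleavages: int
    is_reverse: bool
    is_contaminant: bool
    intensity_by_run: Mapping[RunLabel, float]

    def __post_init__(self) -> None:
        if not 0 <= self.missed_cleavages <= MAX_MISSED_CLEAVAGES:
            raise FormatError(
                f"peptide {self.sequence!r}: missed cleavages "
                f"{self.missed_cleavages} outside 0..{MAX_MISSED_CLEAVAGES}"
            )
        for run, value in self.intensity_by_run.items():
            if not value > 0:
                raise FormatError(
                    f"peptide {self.sequence!r}: non-positive intensity "
                    f"{value!r} for run {run.render()}"
                )


@dataclass(frozen=True)
class EvidenceRow:
    modified_sequence: str
    charge: int
    run: RunLabel
    retention_time: float
    intensity: float | None
    is_reverse: bool
    is_contaminant: bool

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise FormatError(
                f"evidence {self.modified_sequence!r}: charge {self.charge} < 1"
            )
        if self.retention_time < 0:
            raise FormatError(
                f"evidence {self.modified_sequence!r}: negative retention time "
                f"{self.retention_time}"
            )

    @property
    def precursor(self) -> tuple[str, int]:
        """Precursor identity: modified peptide sequence including charge."""
        return (self.modified_sequence, self.charge)


@dataclass(frozen=True)
class DatasetBundle:
    """One workflow's replicate set with all three result tables.

    All runs share the same time point, laboratory, LC-MS setup and
    acquisition mode; ``quant_column`` records whether protein quantification
    came from ``LFQ intensity`` or plain ``Intensity`` columns.
    """

    dataset_id: str
    runs: tuple[RunLabel, ...]
    protein_groups: tuple[ProteinGroupRow, ...]
    peptides: tuple[PeptideRow, ...]
    evidence: tuple[EvidenceRow, ...]
    quant_column: str = "LFQ intensity"

    @property
    def time_point(self) -> str:
        return self.runs[0].time_point

    @property
    def n_replicates(self) -> int:
        return len(self.runs)

    def validate(self) -> None:
        if not self.runs:
            raise ConsistencyError(f"data set {self.dataset_id!r} has no runs")
        if len(set(self.runs)) != len(self.runs):
            raise ConsistencyError(
                f"data set {self.dataset_id!r} has duplicate run labels"
            )
        setups = {(r.time_point, r.lab, r.lc_system, r.ms_instrument, r.acquisition)
                  for r in self.runs}
        if len(setups) > 1:
            raise ConsistencyError(
                f"data set {self.dataset_id!r} mixes setups: {sorted(setups)}"
            )
        known = set(self.runs)
        referenced: set[RunLabel] = set()
        for pg in self.protein_groups:
            referenced.update(pg.lfq_by_run)
        for pep in self.peptides:
            referenced.update(pep.intensity_by_run)
        referenced.update(ev.run for ev in self.evidence)
        stray = referenced - known
        if stray:
            raise ConsistencyError(
                f"data set {self.dataset_id!r}: rows reference runs absent from "
                f"the replicate set: {sorted(r.render() for r in stray)}"
            )


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _resolve_column(df: pd.DataFrame, canonical: str) -> str | None:
    for alias in _COLUMN_ALIASES.get(canonical, (canonical,)):
        if alias in df.columns:
            return alias
    return None


def _require_columns(df: pd.DataFrame, names: Iterable[str], path: str | Path) -> dict[str, str]:
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for name in names:
        col = _resolve_column(df, name)
        if col is None:
            missing.append(name)
        else:
            resolved[name] = col
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    return resolved


def _flag(cell: str) -> bool:
    return cell.strip() == "+"


def _parse_intensity(cell: str) -> float | None:
    """Zero or empty quantification cells mean 'not quantified'."""
    cell = cell.strip()
    if cell in ("", "NaN", "nan"):
        return None
    value = float(cell)
    if value == 0:
        return None
    if math.isnan(value):
        return None
    if value < 0:
        raise FormatError(f"negative intensity {cell!r}")
    return value


def _quant_columns(
    df: pd.DataFrame,
    run_labels: Sequence[RunLabel],
    prefixes: Sequence[str],
    path: str | Path,
) -> tuple[str, dict[RunLabel, str]]:
    """Map each run to its quantification column, preferring the first prefix
    (``LFQ intensity``) over the fallback (``Intensity``)."""
    rendered = {label: label.render() for label in run_labels}
    for prefix in prefixes:
        mapping = {
            label: f"{prefix} {text}"
            for label, text in rendered.items()
            if f"{prefix} {text}" in df.columns
        }
        if mapping:
            if len(mapping) != len(run_labels):
                absent = [rendered[l] for l in run_labels if l not in mapping]
                raise FormatError(
                    f"{path}: '{prefix}' columns present for some runs but "
                    f"missing for {absent}"
                )
            # A per-run column in the file whose label is not in run_labels
            # indicates a design/file mismatch.
            pattern = re.compile(rf"^{re.escape(prefix)} (\S+)$")
            known = set(rendered.values())
            for col in df.columns:
                m = pattern.match(col)
                if m and m.group(1) not in known:
                    try:
                        parse_run_label(m.group(1))
                    except LabelParseError:
                        continue
                    raise FormatError(
                        f"{path}: column {col!r} refers to run {m.group(1)!r} "
                        "not listed in the study design"
                    )
            return prefix, mapping
    raise FormatError(
        f"{path}: no per-run quantification columns found for prefixes "
        f"{list(prefixes)} and runs {[rendered[l] for l in run_labels]}"
    )


def read_protein_groups(
    path: str | Path, run_labels: Sequence[RunLabel]
) -> tuple[tuple[ProteinGroupRow, ...], str]:
    """Read ``proteinGroups.txt``.

    Returns the parsed rows plus the quantification column prefix actually
    used (``"LFQ intensity"`` or ``"Intensity"``), so that reports can state
    which one quantification came from.
    """
    df = _read_table(path)
    cols = _require_columns(
        df,
        ["Majority protein IDs", "Reverse", "Potential contaminant",
         "Only identified by site"],
        path,
    )
    prefix, quant_cols = _quant_columns(
        df, run_labels, ("LFQ intensity", "Intensity"), path
    )
    rows: list[ProteinGroupRow] = []
    id_col = "id" if "id" in df.columns else None
    for idx, rec in enumerate(df.itertuples(index=False)):
        rec_d = dict(zip(df.columns, rec))
        accessions = tuple(
            a for a in rec_d[cols["Majority protein IDs"]].split(";") if a
        )
        lfq = {}
        for label, col in quant_cols.items():
            value = _parse_intensity(rec_d[col])
            if value is not None:
                lfq[label] = value
        rows.append(
            ProteinGroupRow(
                group_id=rec_d[id_col] if id_col else str(idx),
                majority_accessions=accessions,
                is_reverse=_flag(rec_d[cols["Reverse"]]),
                is_contaminant=_flag(rec_d[cols["Potential contaminant"]]),
                only_by_site=_flag(rec_d[cols["Only identified by site"]]),
                lfq_by_run=lfq,
            )
        )
    return tuple(rows), prefix


def read_peptides(
    path: str | Path, run_labels: Sequence[RunLabel]
) -> tuple[PeptideRow, ...]:
    """Read ``peptides.txt``; rows without any quantified run are retained
    (identification without quantification)."""
    df = _read_table(path)
    cols = _require_columns(
        df, ["Sequence", "Missed cleavages", "Reverse", "Potential contaminant"], path
    )
    _, quant_cols = _quant_columns(df, run_labels, ("Intensity",), path)
    rows: list[PeptideRow] = []
    for rec in df.itertuples(index=False):
        rec_d = dict(zip(df.columns, rec))
        mc_cell = rec_d[cols["Missed cleavages"]].strip()
        try:
            mc = int(mc_cell)
        except ValueError as exc:
            raise FormatError(
                f"{path}: unparseable missed-cleavage count {mc_cell!r}"
            ) from exc
        intensities = {}
        for label, col in quant_cols.items():
            value = _parse_intensity(rec_d[col])
            if value is not None:
                intensities[label] = value
        rows.append(
            PeptideRow(
                sequence=rec_d[cols["Sequence"]],
                missed_cleavages=mc,
                is_reverse=_flag(rec_d[cols["Reverse"]]),
                is_contaminant=_flag(rec_d[cols["Potential contaminant"]]),
                intensity_by_run=intensities,
            )
        )
    return tuple(rows)


def read_evidence(path: str | Path) -> tuple[EvidenceRow, ...]:
    """Read ``evidence.txt``; each row's run is resolved from "Raw file"."""
    df = _read_table(path)
    cols = _require_columns(
        df,
        ["Modified sequence", "Charge", "Retention time", "Intensity",
         "Reverse", "Potential contaminant", "Raw file"],
        path,
    )
    label_cache: dict[str, RunLabel] = {}
    rows: list[EvidenceRow] = []
    for rec in df.itertuples(index=False):
        rec_d = dict(zip(df.columns, rec))
        raw = rec_d[cols["Raw file"]].strip()
        if raw not in label_cache:
            try:
                label_cache[raw] = parse_run_label(raw)
            except LabelParseError as exc:
                raise FormatError(
                    f"{path}: unresolvable raw-file label {raw!r}: {exc}"
                ) from exc
        rows.append(
            EvidenceRow(
                modified_sequence=rec_d[cols["Modified sequence"]],
                charge=int(rec_d[cols["Charge"]]),
                run=label_cache[raw],
                retention_time=float(rec_d[cols["Retention time"]]),
                intensity=_parse_intensity(rec_d[cols["Intensity"]]),
                is_reverse=_flag(rec_d[cols["Reverse"]]),
                is_contaminant=_flag(rec_d[cols["Potential contaminant"]]),
            )
        )
    return tuple(rows)


def assemble_dataset(
    dataset_id: str,
    runs: Sequence[RunLabel],
    protein_groups: Sequence[ProteinGroupRow],
    peptides: Sequence[PeptideRow],
    evidence: Sequence[EvidenceRow],
    quant_column: str = "LFQ intensity",
) -> DatasetBundle:
    """Assemble and validate one data set's bundle.

    Runs are sorted by replicate index; any row referencing a run outside the
    declared replicate set raises :class:`ConsistencyError` naming the
    symmetric difference.
    """
    ordered = tuple(sorted(runs, key=lambda r: r.replicate_index))
    bundle = DatasetBundle(
        dataset_id=dataset_id,
        runs=ordered,
        protein_groups=tuple(protein_groups),
        peptides=tuple(peptides),
        evidence=tuple(evidence),
        quant_column=quant_column,
    )
    bundle.validate()
    return bundle


def load_dataset(
    dataset_id: str,
    protein_groups_path: str | Path,
    peptides_path: str | Path,
    evidence_path: str | Path,
    run_labels: Sequence[RunLabel | str],
) -> DatasetBundle:
    """Convenience: read all three tables and assemble the bundle."""
    labels = tuple(
        parse_run_label(l) if isinstance(l, str) else l for l in run_labels
    )
    pg_rows, prefix = read_protein_groups(protein_groups_path, labels)
    pep_rows = read_peptides(peptides_path, labels)
    ev_rows = read_evidence(evidence_path)
    return assemble_dataset(
        dataset_id, labels, pg_rows, pep_rows, ev_rows, quant_column=prefix
    )
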