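"""Synthetic multicenter label-free proteomics studies with known truth.

The generator emulates the statistical structure of a round-robin study:
several laboratories measure the same sample at two time points with ~10
technical replicates each, and their search results are exported as
MaxQuant-dialect tables.  What is modelled:

* a protein inventory split into a *shared core* every laboratory can detect
  and lab-private proteins (this drives the declining interlaboratory
  overlap and saturating union);
* tryptic peptides per protein with configurable missed-cleavage class
  probabilities, and precursors (peptide x charge) with per-feature
  detection probabilities (fixed or Beta-distributed; DIA data sets get a
  tighter, higher law than DDA, and T2 data sets a configurable detection
  multiplier emulating protocol harmonisation gains);
* per-replicate stochastic detection, log-normal intensity noise with a
  configurable target CV (sigma chosen via CV = sqrt(exp(sigma^2) - 1)),
  and homoscedastic retention-time jitter on a uniform elution gradient;
* the bookkeeping rows real searches produce: reversed-decoy and
  contaminant entries, protein groups only identified by site, PROCAL iRT
  spike-ins, and occasional multi-accession majority-ID groups.

Protein and peptide intensities are sums of their detected members'
intensities; no MaxLFQ-style normalisation is attempted, which is adequate
for testing missingness and CV statistics but not normalisation behaviour.
Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "DetectionLaw",
    "SimConfig",
    "GroundTruth",
    "DatasetTables",
    "sample_ground_truth",
    "simulate_measurements",
    "write_maxquant_files",
    "simulate_study",
]

_LC_SYSTEMS = ("nanoElute", "ultimate", "easy1200", "vanquish", "evosep", "acquity")
_MS_INSTRUMENTS = ("timspro", "qexachf", "exploris", "lumos", "tof6600", "astral")
# residues used for synthetic tryptic sequences (cleavage sites added separately)
_AA = "ACDEFGHILMNPQSTVWY"


class DetectionLaw(BaseModel):
    """Per-feature detection probability law: fixed p or Beta(alpha, beta)."""

    kind: Literal["fixed", "beta"] = "beta"
    p: float = Field(default=0.8, ge=0.0, le=1.0)
    alpha: float = Field(default=6.0, gt=0.0)
    beta: float = Field(default=2.0, gt=0.0)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, self.p)
        return rng.beta(self.alpha, self.beta, size=size)


class SimConfig(BaseModel):
    """Parameters of one synthetic round-robin study.

    Defaults describe a desk-scale study: four laboratories (alternating DDA
    and DIA setups), two time points, ten technical replicates, 300 sample
    proteins of which half form the shared core.  Detection probabilities
    follow Beta laws chosen so DDA completeness is broad (~30-75% full
    profiles at the precursor level) and DIA completeness tighter and higher;
    T2 gains a 13% detection multiplier, matching the order of improvement a
    successful protocol-harmonisation round produces.  Intensity noise
    targets a 15% replicate CV and retention-time jitter is 0.25 min on a
    60 min gradient (CV well under the 5% precision threshold, as on real
    platforms).
    """

    n_labs: int = Field(default=4, ge=1)
    time_points: tuple[str, ...] = ("T1", "T2")
    lab_acquisitions: Optional[tuple[str, ...]] = None  # default: alternate DDA/DIA
    n_replicates: int = Field(default=10, ge=1)

    n_proteins: int = Field(default=300, ge=1)
    shared_core_size: int = Field(default=150, ge=0)
    contaminant_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    reverse_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    only_by_site_fraction: float = Field(default=0.02, ge=0.0, le=1.0)
    grouped_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    spike_in_count: int = Field(default=10, ge=0)

    peptides_per_protein_mean: float = Field(default=3.0, ge=1.0)
    missed_cleavage_probabilities: tuple[float, float, float] = (0.85, 0.12, 0.03)
    charge_state_probabilities: Mapping[int, float] = {2: 0.7, 3: 0.25, 4: 0.05}
    second_charge_probability: float = Field(default=0.1, ge=0.0, le=1.0)

    detection: DetectionLaw = DetectionLaw(kind="beta", alpha=6.0, beta=2.0)
    dia_detection: DetectionLaw = DetectionLaw(kind="beta", alpha=16.0, beta=3.0)
    core_detection_probability: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    t2_detection_multiplier: float = Field(default=1.13, gt=0.0)

    log_intensity_mean: float = 13.8  # natural-log scale, exp() ~ 1e6 a.u.
    log_intensity_sd: float = Field(default=1.5, ge=0.0)
    intensity_cv: float = Field(default=0.15, ge=0.0)  # target replicate CV
    gradient_length_min: float = Field(default=60.0, gt=0.0)
    rt_jitter_sd_min: float = Field(default=0.25, ge=0.0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if abs(sum(self.missed_cleavage_probabilities) - 1.0) > 1e-9:
            raise ValueError("missed_cleavage_probabilities must sum to 1")
        if any(p < 0 for p in self.missed_cleavage_probabilities):
            raise ValueError("missed_cleavage_probabilities must be >= 0")
        if abs(sum(self.charge_state_probabilities.values()) - 1.0) > 1e-9:
            raise ValueError("charge_state_probabilities must sum to 1")
        if self.shared_core_size > self.n_proteins:
            raise ValueError("shared_core_size cannot exceed n_proteins")
        if self.lab_acquisitions is not None:
            if len(self.lab_acquisitions) != self.n_labs:
                raise ValueError("lab_acquisitions must list one mode per lab")
            if any(a not in ("DDA", "DIA") for a in self.lab_acquisitions):
                raise ValueError("acquisition modes must be DDA or DIA")
        for tp in self.time_points:
            if tp not in ("T1", "T2"):
                raise ValueError(f"unsupported time point {tp!r}")
        return self

    @property
    def sigma_ln(self) -> float:
        """Log-normal sigma hit by the target CV: CV = sqrt(exp(s^2) - 1)."""
        return math.sqrt(math.log(1.0 + self.intensity_cv**2))

    def lab_names(self) -> tuple[str, ...]:
        return tuple(f"Lab{chr(ord('A') + i)}" for i in range(self.n_labs))

    def acquisition_of(self, lab_index: int) -> str:
        if self.lab_acquisitions is not None:
            return self.lab_acquisitions[lab_index]
        return "DDA" if lab_index % 2 == 0 else "DIA"


@dataclass(frozen=True)
class GroundTruth:
    """Sampled study truth, regenerated bit-identically from (config, seed)."""

    config: SimConfig
    proteins: pd.DataFrame  # accession, majority_ids, kind, lab, only_by_site
    peptides: pd.DataFrame  # sequence, accession, missed_cleavages
    precursors: pd.DataFrame  # modified_sequence, sequence, accession, charge,
    #                           base_rt, log_intensity, p_det_dda, p_det_dia


@dataclass(frozen=True)
class DatasetTables:
    """One data set's tables in the MaxQuant column dialect."""

    dataset_id: str
    run_labels: tuple[str, ...]
    sample_matrix: str
    protein_groups: pd.DataFrame
    peptides: pd.DataFrame
    evidence: pd.DataFrame


def _random_sequence(rng: np.random.Generator, taken: set[str], missed: int) -> str:
    """Random tryptic-looking sequence: internal missed-cleavage K/R sites
    plus a C-terminal K or R."""
    while True:
        length = int(rng.integers(6, 18))
        core = "".join(rng.choice(list(_AA), size=length))
        chars = list(core)
        for _ in range(missed):
            pos = int(rng.integers(1, len(chars)))
            chars.insert(pos, "K" if rng.random() < 0.5 else "R")
        seq = "".join(chars) + ("K" if rng.random() < 0.5 else "R")
        if seq not in taken:
            taken.add(seq)
            return seq


def sample_ground_truth(config: SimConfig) -> GroundTruth:
    """Sample the protein/peptide/precursor inventory of a study.

    Target proteins are partitioned into a shared core visible to every
    laboratory and lab-private remainders (round-robin assignment);
    contaminant, decoy and spike-in entries are appended and visible
    everywhere.  Lab-private proteins may carry a second majority accession
    to exercise grouped-ID handling; core proteins never do, so the core
    contributes exactly ``shared_core_size`` accessions to every laboratory.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    labs = config.lab_names()

    records = []
    for i in range(config.n_proteins):
        accession = f"SIMP{i:05d}"
        if i < config.shared_core_size:
            lab = None
            majority = accession
        else:
            lab = labs[(i - config.shared_core_size) % len(labs)]
            if rng.random() < config.grouped_fraction:
                majority = f"{accession};{accession}B"
            else:
                majority = accession
        records.append((accession, majority, "target", lab, False))
    n_contaminant = round(config.contaminant_fraction * config.n_proteins)
    n_reverse = round(config.reverse_fraction * config.n_proteins)
    n_obs = round(config.only_by_site_fraction * config.n_proteins)
    for i in range(n_contaminant):
        acc = f"CON__SIMC{i:04d}"
        records.append((acc, acc, "contaminant", None, False))
    for i in range(n_reverse):
        acc = f"REV__SIMR{i:04d}"
        records.append((acc, acc, "reverse", None, False))
    for i in range(n_obs):
        acc = f"SIMO{i:04d}"
        records.append((acc, acc, "target", None, True))
    for i in range(config.spike_in_count):
        acc = f"PROCAL{i:03d}"
        records.append((acc, acc, "spike", None, False))
    proteins = pd.DataFrame(
        records, columns=["accession", "majority_ids", "kind", "lab", "only_by_site"]
    )

    taken: set[str] = set()
    mc_p = np.asarray(config.missed_cleavage_probabilities)
    pep_records = []
    for accession, kind in zip(proteins["accession"], proteins["kind"]):
        n_pep = 1 + int(rng.poisson(config.peptides_per_protein_mean - 1.0))
        for _ in range(n_pep):
            mc = int(rng.choice(3, p=mc_p))
            seq = _random_sequence(rng, taken, mc)
            if kind == "spike":
                seq = "PROCAL" + seq  # recognisable by the spike-in filter
            pep_records.append((seq, accession, mc))
    peptides = pd.DataFrame(
        pep_records, columns=["sequence", "accession", "missed_cleavages"]
    )

    charges = np.array(sorted(config.charge_state_probabilities))
    charge_p = np.array(
        [config.charge_state_probabilities[c] for c in charges], dtype=float
    )
    kind_by_acc = dict(zip(proteins["accession"], proteins["kind"]))
    lab_by_acc = dict(zip(proteins["accession"], proteins["lab"]))
    prec_records = []
    for seq, accession in zip(peptides["sequence"], peptides["accession"]):
        z = int(rng.choice(charges, p=charge_p))
        z_list = [z]
        if rng.random() < config.second_charge_probability:
            z_list.append(z + 1)
        for charge in z_list:
            base_rt = float(
                rng.uniform(0.05, 0.95) * config.gradient_length_min
            )
            log_intensity = float(
                rng.normal(config.log_intensity_mean, config.log_intensity_sd)
            )
            p_dda = float(config.detection.sample(rng, 1)[0])
            p_dia = float(config.dia_detection.sample(rng, 1)[0])
            kind = kind_by_acc[accession]
            if kind == "spike":
                p_dda = p_dia = 1.0  # calibration peptides are always seen
            elif (
                config.core_detection_probability is not None
                and kind == "target"
                and lab_by_acc[accession] is None
            ):
                p_dda = p_dia = config.core_detection_probability
            prec_records.append(
                (f"_{seq}_", seq, accession, charge, base_rt, log_intensity,
                 p_dda, p_dia)
            )
    precursors = pd.DataFrame(
        prec_records,
        columns=["modified_sequence", "sequence", "accession", "charge",
                 "base_rt", "log_intensity", "p_det_dda", "p_det_dia"],
    )
    return GroundTruth(
        config=config, proteins=proteins, peptides=peptides, precursors=precursors
    )


def _dataset_plan(config: SimConfig) -> list[tuple[str, str, str, str, str]]:
    """Ordered (time_point, lab, lc, ms, acquisition) per data set."""
    plan = []
    for tp in config.time_points:
        for i, lab in enumerate(config.lab_names()):
            lc = _LC_SYSTEMS[i % len(_LC_SYSTEMS)]
            ms = _MS_INSTRUMENTS[i % len(_MS_INSTRUMENTS)]
            plan.append((tp, lab, lc, ms, config.acquisition_of(i)))
    return plan


def simulate_measurements(
    truth: GroundTruth, sample_matrix: str = "CSF"
) -> dict[str, DatasetTables]:
    """Realise per-replicate detections, intensities and retention times.

    Each precursor is detected independently per replicate with its
    acquisition-specific probability (times the T2 multiplier at T2, clipped
    at 1).  A detected precursor gets RT = base RT + N(0, sigma_rt) and
    intensity = exp(log-intensity + N(0, sigma_ln)); peptide intensities are
    the sums of their detected precursors, protein LFQ values the sums of
    their peptides.  Only features detected in at least one replicate appear
    in a data set's tables, as in real search output.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    sigma_ln = config.sigma_ln
    prec = truth.precursors
    lab_by_acc = dict(zip(truth.proteins["accession"], truth.proteins["lab"]))
    obs_by_acc = dict(
        zip(truth.proteins["accession"], truth.proteins["only_by_site"])
    )
    majority_by_acc = dict(
        zip(truth.proteins["accession"], truth.proteins["majority_ids"])
    )
    kind_by_acc = dict(zip(truth.proteins["accession"], truth.proteins["kind"]))
    mc_by_seq = dict(zip(truth.peptides["sequence"], truth.peptides["missed_cleavages"]))

    out: dict[str, DatasetTables] = {}
    for tp, lab, lc, ms, acq in _dataset_plan(config):
        dataset_id = f"{tp}_{lab}_{lc}_{ms}_{acq}"
        run_labels = tuple(
            f"{tp}_{lab}_{lc}_{ms}_{acq}_R{r + 1}" for r in range(config.n_replicates)
        )
        visible = prec["accession"].map(
            lambda a: lab_by_acc[a] is None or lab_by_acc[a] == lab
        ).to_numpy()
        sub = prec[visible].reset_index(drop=True)
        p = sub["p_det_dda" if acq == "DDA" else "p_det_dia"].to_numpy(copy=True)
        if tp == "T2":
            p = np.clip(p * config.t2_detection_multiplier, 0.0, 1.0)
        n_prec, n_rep = len(sub), config.n_replicates
        detected = rng.random((n_prec, n_rep)) < p[:, None]
        rt = sub["base_rt"].to_numpy()[:, None] + rng.normal(
            0.0, config.rt_jitter_sd_min, (n_prec, n_rep)
        )
        rt = np.clip(rt, 0.0, None)
        intensity = np.exp(
            sub["log_intensity"].to_numpy()[:, None]
            + rng.normal(0.0, 1.0, (n_prec, n_rep)) * sigma_ln
        )

        prec_idx, rep_idx = np.nonzero(detected)
        evidence = pd.DataFrame(
            {
                "Modified sequence": sub["modified_sequence"].to_numpy()[prec_idx],
                "Charge": sub["charge"].to_numpy()[prec_idx],
                "Retention time": rt[prec_idx, rep_idx],
                "Intensity": intensity[prec_idx, rep_idx],
                "Raw file": np.asarray(run_labels, dtype=object)[rep_idx],
                "Reverse": [
                    "+" if kind_by_acc[a] == "reverse" else ""
                    for a in sub["accession"].to_numpy()[prec_idx]
                ],
                "Potential contaminant": [
                    "+" if kind_by_acc[a] == "contaminant" else ""
                    for a in sub["accession"].to_numpy()[prec_idx]
                ],
            }
        )

        # peptide intensities: sum of detected precursors per sequence per run
        quant = intensity * detected
        pep_frame = pd.DataFrame(quant, columns=list(run_labels))
        pep_frame["sequence"] = sub["sequence"]
        pep_sum = pep_frame.groupby("sequence", sort=True).sum()
        pep_sum = pep_sum[pep_sum.sum(axis=1) > 0]
        pep_table = pd.DataFrame({"Sequence": pep_sum.index})
        pep_table["Missed cleavages"] = [mc_by_seq[s] for s in pep_sum.index]
        seq_acc = dict(zip(truth.peptides["sequence"], truth.peptides["accession"]))
        pep_kinds = [kind_by_acc[seq_acc[s]] for s in pep_sum.index]
        pep_table["Reverse"] = ["+" if k == "reverse" else "" for k in pep_kinds]
        pep_table["Potential contaminant"] = [
            "+" if k == "contaminant" else "" for k in pep_kinds
        ]
        for j, label in enumerate(run_labels):
            pep_table[f"Intensity {label}"] = pep_sum.iloc[:, j].to_numpy()

        # protein LFQ: sum of peptide intensities per accession per run
        prot_frame = pd.DataFrame(quant, columns=list(run_labels))
        prot_frame["accession"] = sub["accession"]
        prot_sum = prot_frame.groupby("accession", sort=True).sum()
        prot_sum = prot_sum[prot_sum.sum(axis=1) > 0]
        prot_table = pd.DataFrame(
            {"Majority protein IDs": [majority_by_acc[a] for a in prot_sum.index]}
        )
        prot_table["id"] = np.arange(len(prot_sum))
        prot_kinds = [kind_by_acc[a] for a in prot_sum.index]
        prot_table["Reverse"] = ["+" if k == "reverse" else "" for k in prot_kinds]
        prot_table["Potential contaminant"] = [
            "+" if k == "contaminant" else "" for k in prot_kinds
        ]
        prot_table["Only identified by site"] = [
            "+" if obs_by_acc[a] else "" for a in prot_sum.index
        ]
        for j, label in enumerate(run_labels):
            prot_table[f"LFQ intensity {label}"] = prot_sum.iloc[:, j].to_numpy()

        out[dataset_id] = DatasetTables(
            dataset_id=dataset_id,
            run_labels=run_labels,
            sample_matrix=sample_matrix,
            protein_groups=prot_table,
            peptides=pep_table,
            evidence=evidence,
        )
    return out


def write_maxquant_files(
    tables: Mapping[str, DatasetTables], out_dir: str | Path
) -> dict[str, dict[str, Path]]:
    """Write each data set's three tables under ``out_dir/<dataset_id>/``.

    Undetected features carry 0 in their quantification columns and flags are
    written as "+"/empty, exactly as the readers expect; floats are written
    with full shortest-repr precision so the round trip is value-exact.
    """
    out_dir = Path(out_dir)
    paths: dict[str, dict[str, Path]] = {}
    for dataset_id, t in tables.items():
        d = out_dir / dataset_id
        d.mkdir(parents=True, exist_ok=True)
        files = {
            "protein_groups": d / "proteinGroups.txt",
            "peptides": d / "peptides.txt",
            "evidence": d / "evidence.txt",
        }
        t.protein_groups.to_csv(files["protein_groups"], sep="\t", index=False)
        t.peptides.to_csv(files["peptides"], sep="\t", index=False)
        t.evidence.to_csv(files["evidence"], sep="\t", index=False)
        paths[dataset_id] = files
    return paths


def simulate_study(
    config: SimConfig, sample_matrix: str = "CSF"
) -> tuple[GroundTruth, dict[str, DatasetTables]]:
    """Sample truth and realise all data sets in one call."""
    truth = sample_ground_truth(config)
    return truth, simulate_measurements(truth, sample_matrix=sample_matrix)
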