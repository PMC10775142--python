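import random

import pytest

from mqbench import (
    DatasetBundle,
    EvidenceRow,
    PeptideRow,
    ProteinGroupRow,
    RunLabel,
    SimConfig,
    assemble_dataset,
    simulate_study,
)


def make_runs(n, time_point="T1", lab="LabA", lc="nanoElute", ms="timspro",
              acquisition="DDA"):
    return tuple(
        RunLabel(time_point, lab, lc, ms, acquisition, i + 1) for i in range(n)
    )


def make_bundle(runs, protein_groups=(), peptides=(), evidence=(),
                dataset_id="test"):
    return assemble_dataset(dataset_id, runs, protein_groups, peptides, evidence)


def pg(group_id, accessions, lfq, reverse=False, contaminant=False, obs=False):
    return ProteinGroupRow(
        group_id=group_id,
        majority_accessions=tuple(accessions),
        is_reverse=reverse,
        is_contaminant=contaminant,
        only_by_site=obs,
        lfq_by_run=dict(lfq),
    )


def pep(sequence, mc, intensities, reverse=False, contaminant=False):
    return PeptideRow(
        sequence=sequence,
        missed_cleavages=mc,
        is_reverse=reverse,
        is_contaminant=contaminant,
        intensity_by_run=dict(intensities),
    )


def ev(modseq, charge, run, rt, intensity=1000.0, reverse=False,
       contaminant=False):
    return EvidenceRow(
        modified_sequence=modseq,
        charge=charge,
        run=run,
        retention_time=rt,
        intensity=intensity,
        is_reverse=reverse,
        is_contaminant=contaminant,
    )


def random_bundle(rng: random.Random, max_features=20, max_runs=5) -> DatasetBundle:
    """Small random bundle built directly from row objects (independent of
    the synthetic study generator) for oracle-equivalence checks."""
    n_runs = rng.randint(2, max_runs)
    runs = make_runs(n_runs)
    n_prot = rng.randint(0, max_features)
    groups = []
    for i in range(n_prot):
        lfq = {
            r: rng.uniform(10.0, 1e6)
            for r in runs
            if rng.random() < 0.7
        }
        accs = [f"P{i:04d}"]
        if rng.random() < 0.3:
            accs.append(f"Q{rng.randint(0, max_features):04d}")
        groups.append(pg(str(i), accs, lfq))
    n_pep = rng.randint(0, max_features)
    peptides = []
    for i in range(n_pep):
        ints = {r: rng.uniform(10.0, 1e6) for r in runs if rng.random() < 0.7}
        peptides.append(pep(f"PEPTIDE{i}K", rng.choice([0, 0, 1, 2]), ints))
    n_prec = rng.randint(0, max_features)
    evidence = []
    for i in range(n_prec):
        modseq = f"_PEPTIDE{rng.randint(0, max_features)}K_"
        charge = rng.choice([2, 3])
        for r in runs:
            if rng.random() < 0.7:
                # occasionally several evidence rows per precursor per run
                for _ in range(rng.choice([1, 1, 1, 2])):
                    evidence.append(
                        ev(modseq, charge, r, rng.uniform(1.0, 60.0),
                           rng.uniform(10.0, 1e6))
                    )
    return make_bundle(runs, groups, peptides, evidence)


@pytest.fixture(scope="session")
def small_study():
    """A 2-lab x 2-time-point synthetic study used across test modules."""
    config = SimConfig(
        n_labs=2,
        n_proteins=80,
        shared_core_size=40,
        n_replicates=6,
        seed=20240917,
    )
    truth, tables = simulate_study(config)
    return config, truth, tables
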