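"""Naive brute-force re-implementations of the metric suite.

Written independently of the library code paths: everything here iterates
plainly over rows and runs and uses textbook formulas, so that agreement
with the package is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import math


def naive_presence(bundle, level):
    """feature -> set of runs, from first principles."""
    out = {}
    if level == "protein_group":
        for row in bundle.protein_groups:
            for run in row.lfq_by_run:
                out.setdefault(row.group_id, set()).add(run)
    elif level == "peptide":
        for row in bundle.peptides:
            for run in row.intensity_by_run:
                out.setdefault(row.sequence, set()).add(run)
    elif level == "precursor":
        for row in bundle.evidence:
            out.setdefault((row.modified_sequence, row.charge), set()).add(row.run)
    else:
        raise ValueError(level)
    return out


def naive_id_counts(bundle, level):
    presence = naive_presence(bundle, level)
    counts = {}
    for run in bundle.runs:
        counts[run] = sum(1 for runs in presence.values() if run in runs)
    return counts


def naive_median(values):
    values = sorted(values)
    n = len(values)
    if n == 0:
        return 0.0
    if n % 2:
        return float(values[n // 2])
    return (values[n // 2 - 1] + values[n // 2]) / 2.0


def naive_completeness(bundle, level):
    presence = naive_presence(bundle, level)
    count_by_k = {}
    for runs in presence.values():
        k = len(runs)
        count_by_k[k] = count_by_k.get(k, 0) + 1
    return count_by_k


def naive_percent_full(bundle, level):
    count_by_k = naive_completeness(bundle, level)
    total = sum(count_by_k.values())
    if total == 0:
        return None
    return 100.0 * count_by_k.get(len(bundle.runs), 0) / total


def naive_cv(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return 100.0 * math.sqrt(var) / mean


def naive_rt_precision(bundle, threshold=5.0):
    """(n_evaluable, n_below): precursor RT CVs from raw evidence rows."""
    per_prec = {}
    for row in bundle.evidence:
        per_prec.setdefault((row.modified_sequence, row.charge), {}).setdefault(
            row.run, []
        ).append(row.retention_time)
    n_eval = n_below = 0
    for by_run in per_prec.values():
        rts = [naive_median(v) for v in by_run.values()]
        if len(rts) < 2:
            continue
        n_eval += 1
        if naive_cv(rts) < threshold:
            n_below += 1
    return n_eval, n_below


def naive_quant_precision(bundle, level, threshold=20.0):
    per_feature = {}
    if level == "protein_group":
        for row in bundle.protein_groups:
            if row.lfq_by_run:
                per_feature[row.group_id] = list(row.lfq_by_run.values())
    elif level == "peptide":
        merged = {}
        for row in bundle.peptides:
            dest = merged.setdefault(row.sequence, {})
            for run, v in row.intensity_by_run.items():
                dest[run] = dest.get(run, 0.0) + v
        per_feature = {seq: list(d.values()) for seq, d in merged.items() if d}
    elif level == "precursor":
        collected = {}
        for row in bundle.evidence:
            if row.intensity is None:
                continue
            collected.setdefault((row.modified_sequence, row.charge), {}).setdefault(
                row.run, []
            ).append(row.intensity)
        per_feature = {
            prec: [naive_median(v) for v in by_run.values()]
            for prec, by_run in collected.items()
        }
    else:
        raise ValueError(level)
    n_eval = n_below = 0
    for values in per_feature.values():
        if len(values) < 2:
            continue
        n_eval += 1
        if naive_cv(values) < threshold:
            n_below += 1
    return n_eval, n_below


def naive_missed_cleavage_percent_zero(bundle):
    by_seq = {row.sequence: row.missed_cleavages for row in bundle.peptides}
    if not by_seq:
        return None
    return 100.0 * sum(1 for mc in by_seq.values() if mc == 0) / len(by_seq)


def naive_full_profile_accessions(bundle, threshold=100.0):
    n = len(bundle.runs)
    need = math.ceil(threshold * n / 100.0 - 1e-9)
    presence = naive_presence(bundle, "protein_group")
    accessions = set()
    for row in bundle.protein_groups:
        if len(presence.get(row.group_id, set())) >= need:
            for acc in row.majority_accessions:
                accessions.add(acc)
    return accessions


def naive_overlap(sets):
    """Intersections/unions via from-scratch set algebra per prefix."""
    inters, unions = [], []
    for k in range(1, len(sets) + 1):
        prefix = sets[:k]
        inter = set(prefix[0])
        for s in prefix[1:]:
            inter = {x for x in inter if x in s}
        union = set()
        for s in prefix:
            union = union | s
        inters.append(len(inter))
        unions.append(len(union))
    return inters, unions


def naive_scaled(values_a, values_b):
    med_a, med_b = naive_median(values_a), naive_median(values_b)
    top = max(med_a, med_b)
    if top == 0:
        return None
    return (100.0 * med_a / top, 100.0 * med_b / top)
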