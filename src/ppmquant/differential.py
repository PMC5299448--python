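"""Paired tumor/adjacent differential abundance analysis.

Per protein, group means are taken over all patients with undetected
samples contributing 0 ppm.  Significance uses a two-tailed paired
Student t-test on raw ppm differences; the lowest-abundance proteins —
where the t-test on mostly-zero vectors is meaningless — are routed to a
two-sided Fisher exact test on detectable/undetectable status.  The
tumor/adjacent ratio follows the detection conventions: 1000 when a
protein is identified only in tumors and 0.001 when only in adjacent
tissue.  Proteins detected nowhere are excluded.

Classes and selections:

* class label — <2-fold stable; >=2-fold and p < 0.01 changed; else not
  significant,
* signature — >4-fold (or <0.25) and p < 0.01,
* marker panel — signature proteins abundant enough to assay (mean ppm in
  the relevant condition above a floor), ranked by |log10 ratio|.

P-values are reported raw (significance thresholds apply to them);
Benjamini-Hochberg q-values are attached for transparency only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    AbundanceProfile,
    ClassLabel,
    Condition,
    DifferentialRecord,
    GeneList,
    OverlapSummary,
    TestUsed,
)

RATIO_TUMOR_ONLY = 1000.0
RATIO_ADJACENT_ONLY = 0.001


@dataclass(frozen=True)
class PairedTResult:
    """Outcome of a paired t-test; degenerate when the differences carry no
    usable variance (p is 1.0 for an all-zero difference vector, NaN when the
    differences are identical but nonzero)."""

    statistic: float
    p_value: float
    degenerate: bool


def paired_t_test(
    tumor_ppm: Sequence[float], adjacent_ppm: Sequence[float]
) -> PairedTResult:
    """Two-tailed paired Student t-test on raw ppm differences.

    Values are ordered by patient so element i of both sequences comes from
    the same patient; undetected is encoded as 0.
    """
    t = np.asarray(tumor_ppm, dtype=float)
    a = np.asarray(adjacent_ppm, dtype=float)
    if t.shape != a.shape:
        raise ValueError(f"length mismatch: {t.size} tumor vs {a.size} adjacent values")
    if t.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = t - a
    if np.all(d == 0.0):
        return PairedTResult(statistic=0.0, p_value=1.0, degenerate=True)
    if np.ptp(d) == 0.0:  # identical nonzero differences: zero variance
        return PairedTResult(statistic=math.inf * np.sign(d[0]), p_value=math.nan,
                             degenerate=True)
    res = stats.ttest_rel(t, a)
    return PairedTResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), degenerate=False
    )


def fisher_presence_test(
    n_det_tumor: int, n_tumor: int, n_det_adjacent: int, n_adjacent: int
) -> float:
    """Two-sided Fisher exact p for detection status tumor vs adjacent.

    The 2x2 table is [detected, undetected] x [tumor, adjacent]; the
    two-sided p sums all tables (at fixed margins) whose point probability
    does not exceed the observed table's.
    """
    if not (0 <= n_det_tumor <= n_tumor and 0 <= n_det_adjacent <= n_adjacent):
        raise ValueError(
            f"detections exceed group size: {n_det_tumor}/{n_tumor}, "
            f"{n_det_adjacent}/{n_adjacent}"
        )
    table = [
        [n_det_tumor, n_det_adjacent],
        [n_tumor - n_det_tumor, n_adjacent - n_det_adjacent],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def compute_ratio(
    mean_t: float, mean_a: float, n_det_t: int, n_det_a: int
) -> float | None:
    """Tumor/adjacent ratio with the one-sided detection conventions.

    Returns 1000 for tumor-only detection, 0.001 for adjacent-only, None
    (caller excludes the protein) when detected in neither group.
    """
    if n_det_t == 0 and n_det_a == 0:
        return None
    if n_det_a == 0:
        return RATIO_TUMOR_ONLY
    if n_det_t == 0:
        return RATIO_ADJACENT_ONLY
    return mean_t / mean_a


def _pair_profiles(
    profiles: Sequence[AbundanceProfile],
) -> tuple[list[str], list[AbundanceProfile], list[AbundanceProfile]]:
    """Order profiles into patient-matched (tumor, adjacent) lists."""
    by_patient: dict[str, dict[Condition, AbundanceProfile]] = {}
    for p in profiles:
        slot = by_patient.setdefault(p.patient_id, {})
        if p.condition in slot:
            raise ValueError(
                f"patient {p.patient_id}: duplicate {p.condition.value} profile"
            )
        slot[p.condition] = p
    patients = sorted(by_patient)
    for pid in patients:
        if set(by_patient[pid]) != {Condition.TUMOR, Condition.ADJACENT}:
            raise ValueError(f"patient {pid}: missing tumor or adjacent profile")
    if len(patients) < 2:
        raise ValueError("paired analysis needs at least 2 patients")
    tumors = [by_patient[pid][Condition.TUMOR] for pid in patients]
    adjacents = [by_patient[pid][Condition.ADJACENT] for pid in patients]
    return patients, tumors, adjacents


def run_differential(
    profiles: Sequence[AbundanceProfile],
    low_abundance_ppm: float = 1.0,
    min_detected_for_t: int = 3,
    fold_changed: float = 2.0,
    fold_signature: float = 4.0,
    p_threshold: float = 0.01,
) -> list[DifferentialRecord]:
    """Paired differential analysis over a tumor/adjacent cohort.

    Test routing: a protein goes to the Fisher presence/absence path when
    its mean ppm is below ``low_abundance_ppm`` in both groups, or when it
    is detected in fewer than ``min_detected_for_t`` samples in either
    group; otherwise it gets the paired t-test.  Proteins never detected
    are excluded from the output.
    """
    _, tumors, adjacents = _pair_profiles(profiles)
    n = len(tumors)
    accessions = sorted(
        set().union(*(p.ppm.keys() for p in profiles))
    )
    t_mat = np.array([[p.ppm.get(a, 0.0) for p in tumors] for a in accessions])
    a_mat = np.array([[p.ppm.get(a, 0.0) for p in adjacents] for a in accessions])

    records: list[DifferentialRecord] = []
    for i, acc in enumerate(accessions):
        t_vals, a_vals = t_mat[i], a_mat[i]
        n_det_t = int(np.count_nonzero(t_vals))
        n_det_a = int(np.count_nonzero(a_vals))
        mean_t = float(t_vals.mean())
        mean_a = float(a_vals.mean())
        ratio = compute_ratio(mean_t, mean_a, n_det_t, n_det_a)
        if ratio is None:
            continue

        low_abundance = mean_t < low_abundance_ppm and mean_a < low_abundance_ppm
        sparse = min(n_det_t, n_det_a) < min_detected_for_t
        if low_abundance or sparse:
            p = fisher_presence_test(n_det_t, n, n_det_a, n)
            test = TestUsed.FISHER_PRESENCE
        else:
            res = paired_t_test(t_vals, a_vals)
            p = res.p_value
            test = TestUsed.DEGENERATE if res.degenerate else TestUsed.PAIRED_T

        fold = max(ratio, 1.0 / ratio)
        significant = (not math.isnan(p)) and p < p_threshold
        if fold < fold_changed:
            label = ClassLabel.STABLE_LT2FOLD
        elif significant:
            label = ClassLabel.CHANGED_GE2FOLD
        else:
            label = ClassLabel.NOT_SIGNIFICANT
        signature = fold > fold_signature and significant

        records.append(
            DifferentialRecord(
                accession=acc,
                mean_ppm_tumor=mean_t,
                mean_ppm_adjacent=mean_a,
                ratio=ratio,
                p_value=p,
                test_used=test,
                n_detected_tumor=n_det_t,
                n_detected_adjacent=n_det_a,
                class_label=label,
                signature_flag=signature,
            )
        )

    _attach_q_values(records)
    return records


def _attach_q_values(records: list[DifferentialRecord]) -> None:
    """Benjamini-Hochberg adjusted p-values, informational only."""
    idx = [i for i, r in enumerate(records) if not math.isnan(r.p_value)]
    if not idx:
        return
    q = multipletests([records[i].p_value for i in idx], method="fdr_bh")[1]
    for i, qv in zip(idx, q):
        records[i].q_value = float(qv)


def select_marker_panel(
    records: Sequence[DifferentialRecord], min_mean_ppm: float = 20.0
) -> list[DifferentialRecord]:
    """Select assayable marker candidates from the signature set.

    Keeps signature proteins whose mean ppm exceeds ``min_mean_ppm`` in the
    condition where they are abundant — tumor mean for overexpressed
    markers, adjacent mean for decreased ones (markers lost in tumors are
    abundant in adjacent tissue, not tumor).  Ranked by |log10 ratio|
    descending, ties broken by p-value then accession.
    """
    panel = []
    for r in records:
        if not r.signature_flag:
            continue
        abundant = (
            r.mean_ppm_tumor > min_mean_ppm
            if r.ratio > 1.0
            else r.mean_ppm_adjacent > min_mean_ppm
        )
        if abundant:
            panel.append(r)
    panel.sort(key=lambda r: (-abs(math.log10(r.ratio)), r.p_value, r.accession))
    return panel


def overlap_with_gene_list(
    records: Sequence[DifferentialRecord],
    gene_list: GeneList,
    id_map: Mapping[str, str] | None = None,
    fold_de: float = 1.5,
    p_threshold: float = 0.01,
) -> OverlapSummary:
    """Overlap of a published list with the identified and differential sets.

    ``id_map`` maps record accessions to the list's symbol space; unmapped
    accessions count as non-overlapping.  Counts are nested: members
    identified >= changed >=``fold_de``-fold at p < ``p_threshold`` >=
    overlapping the signature.
    """
    members = set(gene_list.members)
    n_identified = n_de = n_sig = 0
    seen: set[str] = set()
    for r in records:
        symbol = id_map.get(r.accession, r.accession) if id_map else r.accession
        if symbol not in members or symbol in seen:
            continue
        seen.add(symbol)
        n_identified += 1
        fold = max(r.ratio, 1.0 / r.ratio)
        if fold >= fold_de and not math.isnan(r.p_value) and r.p_value < p_threshold:
            n_de += 1
            if r.signature_flag:
                n_sig += 1
    return OverlapSummary(
        list_name=gene_list.name,
        n_listed=len(members),
        n_identified=n_identified,
        n_de_1p5fold=n_de,
        n_overlap_signature=n_sig,
    )
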