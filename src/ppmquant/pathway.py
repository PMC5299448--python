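"""Quantitative pathway analysis via pathway protein ontology chains (POCs).

A POC groups a pathway's proteins by functional role — ligands,
receptors, activating regulators, inhibitory regulators, effectors, or a
named complex — and its activation strength in one profile is the sum of
the member proteins' ppm.  Comparing the per-patient sums between paired
tumor and adjacent profiles gives a percent change per chain; the paired
t-test on the per-sample sums is attached as an informational p-value.
"""

from __future__ import annotations

import math
from typing import Sequence

from .differential import _pair_profiles, paired_t_test
from .models import AbundanceProfile, POCDefinition, POCResult


def sum_poc(profile: AbundanceProfile, poc: POCDefinition) -> float:
    """Summed ppm of the chain's members in one profile (absent members add 0)."""
    return math.fsum(profile.ppm.get(acc, 0.0) for acc in poc.members)


def compare_poc(
    profiles: Sequence[AbundanceProfile], pocs: Sequence[POCDefinition]
) -> list[POCResult]:
    """Per-chain tumor-vs-adjacent comparison over a paired cohort.

    Sums are computed per sample, then averaged per group; percent change
    is 100 x (tumor - adjacent) / adjacent and NaN (flagged, not an error)
    when the adjacent mean sum is zero.
    """
    _, tumors, adjacents = _pair_profiles(profiles)
    results: list[POCResult] = []
    for poc in pocs:
        t_sums = [sum_poc(p, poc) for p in tumors]
        a_sums = [sum_poc(p, poc) for p in adjacents]
        mean_t = math.fsum(t_sums) / len(t_sums)
        mean_a = math.fsum(a_sums) / len(a_sums)
        pct = 100.0 * (mean_t - mean_a) / mean_a if mean_a > 0 else math.nan
        p = paired_t_test(t_sums, a_sums).p_value
        results.append(
            POCResult(
                pathway=poc.pathway,
                chain=poc.chain,
                mean_sum_ppm_tumor=mean_t,
                mean_sum_ppm_adjacent=mean_a,
                percent_change=pct,
                p_value=p,
            )
        )
    return results
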