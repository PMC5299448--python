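#!/usr/bin/env python
"""Profile quality control: housekeeping coverage scores and replicate CV.

Scores each of the 44 profiles against the 444-member housekeeping
reference, then measures the coefficient of variation across technical
(multinomial) replicates of one sample per abundance bin — the CV should
fall steeply with abundance.
"""

from pathlib import Path

import numpy as np

from ppmquant import (
    generate_replicates,
    io_formats,
    quantify_cohort,
    quantify_profile,
    replicate_cv,
    score_profile,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    cohort = ROOT / "cohort"
    proteins, profiles = io_formats.read_count_table(
        cohort / "counts.tsv", cohort / "metadata.tsv"
    )
    reference = io_formats.read_reference_list(cohort / "housekeeping.tsv")
    abundances = quantify_cohort(profiles, proteins)
    reports = [score_profile(a, reference) for a in abundances]
    io_formats.write_qc_reports(reports, ROOT / "qc_scores.tsv")
    io_formats.write_group_coverage(reports, ROOT / "qc_group_coverage.tsv")
    scores = [r.score for r in reports]
    print(f"housekeeping score over {len(reports)} profiles: "
          f"mean {np.mean(scores):.1f}, range {min(scores):.1f} - {max(scores):.1f}")

    # technical replicates of the first sample's underlying abundance
    first = abundances[0]
    rel = {a: v / 1e6 for a, v in first.ppm.items()}
    reps = generate_replicates(proteins, rel, n_replicates=10,
                               depth=first_depth(profiles), seed=SEED)
    report = replicate_cv([quantify_profile(r, proteins) for r in reps])
    print("replicate CV by abundance bin:")
    for (lo, hi), cv, n in zip(report.abundance_bins,
                               report.mean_cv_percent_per_bin,
                               report.n_proteins_per_bin):
        hi_label = f"{hi:g}" if hi != float("inf") else "inf"
        print(f"  {lo:g}-{hi_label} ppm: mean CV {cv:6.1f}%  ({n} proteins)")
    print(f"overall: {report.overall_mean_cv_percent:.1f}% "
          f"+/- {report.overall_sd_cv_percent:.1f}%")


def first_depth(profiles) -> int:
    return profiles[0].total_counts


if __name__ == "__main__":
    main()
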