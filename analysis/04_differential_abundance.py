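#!/usr/bin/env python
"""Paired differential abundance, signature selection and marker panel.

Runs the paired tumor/adjacent comparison over the cohort, classifies
proteins (<2-fold stable / not significant / >=2-fold changed), extracts
the >4-fold p<0.01 signature, ranks the abundance-filtered marker panel,
and checks recovery against the generator's ground truth.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from ppmquant import (
    io_formats,
    overlap_with_gene_list,
    quantify_cohort,
    run_differential,
    select_marker_panel,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = ROOT / "cohort"
    proteins, profiles = io_formats.read_count_table(
        cohort / "counts.tsv", cohort / "metadata.tsv"
    )
    abundances = quantify_cohort(profiles, proteins)
    records = run_differential(abundances)
    io_formats.write_differential_table(records, ROOT / "differential.tsv")

    classes = Counter(r.class_label.value for r in records)
    print(f"{len(records)} proteins compared: "
          + ", ".join(f"{k}={v}" for k, v in sorted(classes.items())))
    signature = [r for r in records if r.signature_flag]
    up = sum(r.ratio > 1 for r in signature)
    print(f"signature (>4-fold, p<0.01): {len(signature)} proteins "
          f"({up} up, {len(signature) - up} down)")
    io_formats.write_differential_table(signature, ROOT / "signature.tsv")

    panel = select_marker_panel(records)
    io_formats.write_differential_table(panel, ROOT / "marker_panel.tsv")
    print(f"marker panel (signature, mean >20 ppm in relevant tissue): "
          f"{len(panel)} candidates; top 5:")
    for r in panel[:5]:
        print(f"  {r.accession}: ratio {r.ratio:.2f}, tumor {r.mean_ppm_tumor:.1f} "
              f"vs adjacent {r.mean_ppm_adjacent:.1f} ppm, p {r.p_value:.2e}")

    truth = pd.read_csv(cohort / "ground_truth.tsv", sep="\t")
    planted = set(truth.loc[truth.planted_class.isin(["up", "down"]), "accession"])
    null = set(truth.loc[(truth.planted_class.isna() | (truth.planted_class == ""))
                         & (truth.poc_chain.isna() | (truth.poc_chain == "")),
                         "accession"])
    flagged = {r.accession for r in signature}
    print(f"recovery vs ground truth: sensitivity "
          f"{100 * len(flagged & planted) / len(planted):.1f}%, "
          f"false-positive rate {100 * len(flagged & null) / len(null):.2f}%")

    gl = io_formats.read_gene_list(cohort / "signature_gene_list.tsv")
    s = overlap_with_gene_list(records, gl)
    print(f"overlap with planted list '{s.list_name}': {s.n_identified} identified, "
          f"{s.n_de_1p5fold} changed >=1.5-fold, {s.n_overlap_signature} in signature")


if __name__ == "__main__":
    main()
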