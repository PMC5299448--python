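#!/usr/bin/env python
"""Generate the reference synthetic cohort and write it in pipeline formats.

22 patients x {tumor, adjacent}, 2,000 proteins, 100,000 spectra per
sample, 5% of proteins planted at 8-fold (4% up, 1% down), one POC chain
planted at +50% (nominal, pre-normalization) plus a null chain, and a
444-member ten-group housekeeping reference.  Outputs go to
results/cohort/ for the downstream analysis steps.
"""

from pathlib import Path

from ppmquant import SyntheticConfig, generate_cohort, io_formats

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    config = SyntheticConfig(seed=SEED)
    proteins, profiles, truth = generate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    io_formats.write_count_table(proteins, profiles, OUT / "counts.tsv", OUT / "metadata.tsv")
    io_formats.write_reference_list(truth.housekeeping, OUT / "housekeeping.tsv")
    io_formats.write_poc_definitions(truth.pocs, OUT / "poc_definitions.tsv")
    truth.table.to_csv(OUT / "ground_truth.tsv", sep="\t", index=False,
                       float_format="%.6g", lineterminator="\n")
    (OUT / "signature_gene_list.tsv").write_text(
        "\n".join(sorted(truth.planted_signature)) + "\n", encoding="utf-8"
    )
    n_planted = len(truth.planted_signature)
    print(f"cohort: {config.n_patients} pairs, {config.n_proteins} proteins, "
          f"depth {config.depth_counts_per_sample:,}")
    print(f"planted: {len(truth.planted_up)} up + {len(truth.planted_down)} down "
          f"= {n_planted} signature proteins ({100 * n_planted / config.n_proteins:.1f}%)")
    for key, pct in truth.poc_true_percent_change.items():
        print(f"POC {key[0]}/{key[1]}: realized change {pct:+.1f}%")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
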