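# Methods

## Quantification model

Spectral counting treats the number of peptide spectra matched to a
protein (`S_N`) as a proxy for its molar amount. Longer proteins yield
more tryptic peptides and therefore more spectra per mole, so counts are
length-corrected before normalization:

```
NSAF_N = (S_N / L_N) / Σ_k (S_k / L_k)
ppm_N  = NSAF_N × 10⁶
```

where `L_N` is the protein length in residues and the sum runs over all
proteins in the profile. Each profile therefore carries exactly
1,000,000 ppm: ppm is a *relative* (compositional) abundance, and any
comparison between profiles is a comparison of proportions, not of
absolute copy numbers. No pseudo-counts or imputation are applied;
a protein with zero spectra has ppm 0 and is carried through explicitly
so detection status remains queryable downstream.

Assumptions: spectrum counts scale linearly with abundance × length over
the quantifiable range; identification is all-or-nothing per protein per
sample (no partial-peptide modeling); fractions of one sample are summed
before quantification.

## Profile quality control

A grouped reference of ubiquitous protein-complex members (ten groups,
444 entries by default — ribosomes, proteasome, COP9 signalosome, Arp2/3,
nuclear pore, histones, TCA enzymes, respiratory chain, V-ATPase and
Na⁺/K⁺-ATPase pumps, mitochondrial ribosome) scores each profile as the
exact percentage of members detected (0–100). The score is reported
unrounded; rounding is a display concern. The bundled member list in the
synthetic cohort is generated (accessions are synthetic), standing in for
a curated list; the group sizes, not the identities, are what the score
exercises. Isoform entries count independently at the accession level.

The abundance distribution summary histograms detected proteins over
log₁₀(ppm) and reports the major (≥ 1 ppm) / minor (< 1 ppm) population
split. Replicate CV is the n−1 (sample) standard deviation over the mean
of a protein's ppm across technical replicates, ×100, with undetected
encoded as 0 ppm; proteins are binned by mean ppm into
<1, 1–10, 10–100, 100–1000, >1000 ppm by default. The n−1 convention
matches the spreadsheet STDEV most labs use for this analysis.

## Paired differential abundance

Per protein, group means are taken over all patients (undetected = 0 ppm).
Significance routing:

* **paired t-test** (two-tailed, on raw ppm differences) when the protein
  is quantifiable in both groups;
* **Fisher exact test** (two-sided, on the 2×2 detected/undetected ×
  tumor/adjacent table) when the protein's mean ppm is below 1 ppm in
  *both* groups or it is detected in fewer than 3 samples in *either*
  group. For such proteins a t-test on mostly-zero vectors is
  uninformative, while presence/absence carries the signal. Both
  thresholds are configurable; 1 ppm is the same boundary that separates
  the major/minor abundance populations.

The t-test runs on raw ppm, not log ppm, because zeros (undetected) are
retained; a log transform would require imputation, which this workflow
deliberately avoids. Degenerate cases: an all-zero difference vector
returns p = 1; a constant nonzero difference (zero variance) is flagged
and its p is NaN, never silently significant.

Ratio conventions: tumor/adjacent mean ratio, with sentinels 1000
(detected only in tumors) and 0.001 (detected only in adjacent tissue).
Proteins detected in neither group are excluded. The sentinels make
one-sided detections sortable and flaggable without dividing by zero.

Classification: fold < 2 → stable; fold ≥ 2 with p < 0.01 → changed;
otherwise not significant. The signature is fold > 4 with p < 0.01.
P-values are used raw at these thresholds; Benjamini–Hochberg q-values
are attached to every record as an informational column only.

The marker panel keeps signature proteins whose mean ppm exceeds 20 in
the condition where they are abundant — the tumor mean for overexpressed
proteins, the adjacent mean for decreased ones (a marker lost in tumors
is by construction scarce there) — ranked by |log₁₀ ratio| descending
with ties broken by p-value then accession.

Gene-list overlap reports nested counts: list members identified, those
changed ≥ 1.5-fold at p < 0.01, and those in the > 4-fold signature, with
an optional accession→symbol map; unmapped accessions count as
non-overlapping.

## Pathway protein ontology chains (POC)

A POC is a functional role-group of a pathway (ligands, receptors,
activating regulators, inhibitory regulators, effectors, or a named
complex). Its activation strength in a profile is the plain sum of member
ppm — bounded by 10⁶ and monotone under member inclusion. Comparison sums
per sample first, then averages per group (the per-sample sums are what a
paired test needs; the group means coincide either way), and reports
percent change 100 × (tumor − adjacent)/adjacent, NaN-flagged when the
adjacent mean sum is 0. The paired t-test p-value on per-patient sums is
informational: the method's output is the percent change.

## Synthetic cohort generator

The generator emulates the paired-cohort design end to end, with defaults
that define the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 22 | paired tumor/adjacent samples |
| `n_proteins` | 2000 | database size |
| `depth_counts_per_sample` | 100,000 | total spectra per sample |
| `abundance_lognormal_sigma` | 2.0 (ln) | ~4–5 decades of dynamic range |
| `fraction_up` / `fraction_down` | 0.04 / 0.01 | 5% planted changes |
| `fold_up_range` / `fold_down_range` | 8 / 0.125 | planted effect size |
| `patient_effect_sd` | 0.3 (ln) | ~30% biological CV per sample |
| `length_range_aa` | 100–2000 | uniform protein lengths |
| `planted_min_baseline_ppm` | 50 | planted proteins are detectable |
| `planted_max_mass_quantile` | 0.85 | top mass tier stays stable |
| `poc_chain_size` / `poc_fold` | 20 / 1.5 | planted +50% chain (+ null chain) |

Counts are multinomial at fixed depth with probability ∝ abundance ×
length, so NSAF is the exact inverse of the sampling model and the
fixed-depth budget of an LC-MS/MS run is respected (per-sample ppm totals
are exact by construction). Detection dropout emerges naturally for
proteins whose expected count falls below ~1 — no separate dropout knob —
which is what exercises the Fisher and 1000/0.001 code paths.

Planted changes are drawn from a mid-abundance band: baseline ≥ 50 ppm
(detectable at the default depth) and below the 85th abundance quantile,
because in tumor proteomes the top mass tier is dominated by stable
housekeeping machinery while regulatory proteins that change are mostly of
low-to-mid abundance. Because ppm is compositional, planting extra tumor
mass rescales every other protein's share; the ground truth therefore
records the **realized** fold (after renormalization) next to the nominal
one, and the planted POC chain's true percent change is likewise the
realized value (≈ +36% for a nominal +50% under the defaults). Recovery
is judged against the realized truth — that is the quantity the data
actually contain.

A single seed drives everything; per-sample streams are spawned
deterministically from it, so cohorts are bit-reproducible.

What the generator does **not** emulate: peptide-level identification and
FDR search artifacts, shared/razor peptides, protein inference ambiguity,
batch effects between runs, chromatographic structure, or
abundance-dependent identification bias beyond counting statistics.
Passing recovery tests therefore demonstrates that the statistical
machinery is correct under the stated sampling model, not that the
thresholds are optimal for any particular real dataset.

## Numerical choices

* Sums over ppm/NSAF use compensated summation (`math.fsum`); profile
  mass is conserved to < 1e-3 ppm in 10⁶.
* NSAF input to the ppm scaler must sum to 1 within 1e-6, else error.
* Panel ranking tie-break: p-value, then accession (lexicographic), so
  output is total-ordered and byte-reproducible.
* TSV is the only dialect (UTF-8, Unix newlines); floats serialize at 6
  significant digits and round-trip losslessly at that precision.
* Degenerate statistics are flagged, never coerced to 0 or 1 except the
  defined all-zero-difference → p = 1 case.

## Problem sizes

The test suite runs the full reference cohort (22 × 2 × 2000 proteins at
depth 10⁵) once for recovery checks and a 6 × 2 × 400 cohort at depth
3 × 10⁴ for shared fixtures; the Fisher oracle sweep enumerates every
2×2 table with group sizes ≤ 12. The analysis scripts under `analysis/`
use the reference cohort throughout. Everything completes in well under a
minute on one CPU.

## Known limitations

* NSAF is a biased estimator at low counts (single-spectrum detections
  quantize ppm); the CV analysis makes this visible rather than hiding it.
* The t-on-raw-ppm choice (with zeros) is faithful to the spreadsheet
  workflow it mirrors but is not the most powerful available test;
  `run_differential` is the single place to swap the routing if desired.
* Ratios of means are reported without shrinkage; with n = 22 pairs the
  sampling noise on low-abundance ratios is substantial (visible in the
  recovery margins).
* The 1000/0.001 sentinels are conventions, not estimates; downstream
  consumers should treat them as "one-sided detection", not as folds.
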