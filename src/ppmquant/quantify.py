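"""Spectrum-count to relative-abundance conversion (NSAF and ppm).

For protein N with spectrum count S_N and length L_N (residues), the
normalized spectral abundance factor is

    NSAF_N = (S_N / L_N) / sum_k (S_k / L_k)

over all proteins in the profile, and the relative concentration in parts
per million is RC_N = NSAF_N x 10^6, so each proteome profile carries a
total of exactly 1,000,000 ppm.  No pseudo-counts or imputation: a protein
with S_N = 0 has NSAF and ppm 0 and is carried, not dropped, so detection
status stays explicit downstream.
"""

from __future__ import annotations

import math

from .models import AbundanceProfile, ProteinEntry, SpectralCountProfile

PPM_TOTAL = 1_000_000.0

_NSAF_SUM_TOL = 1e-6


def compute_nsaf(
    profile: SpectralCountProfile, proteins: list[ProteinEntry]
) -> dict[str, float]:
    """Compute NSAF for every protein in the profile.

    Zero-count proteins receive NSAF 0.  Raises if a counted accession is
    missing from the protein table or if all counts are zero.
    """
    lengths = {p.accession: p.length_aa for p in proteins}
    missing = [a for a in profile.counts if a not in lengths]
    if missing:
        raise KeyError(
            f"sample {profile.sample_id}: accession(s) not in protein table: "
            + ", ".join(sorted(missing)[:10])
        )
    saf = {a: c / lengths[a] for a, c in profile.counts.items()}
    total = math.fsum(saf.values())
    if total <= 0:
        raise ValueError(f"sample {profile.sample_id}: all spectrum counts are zero")
    return {a: v / total for a, v in saf.items()}


def compute_ppm(
    nsaf: dict[str, float],
    sample_id: str = "",
    patient_id: str = "",
    condition: str = "tumor",
) -> AbundanceProfile:
    """Scale an NSAF map to ppm (x 10^6) and wrap it in an AbundanceProfile.

    The NSAF map must sum to 1 (within 1e-6); total ppm mass is conserved.
    """
    total = math.fsum(nsaf.values())
    if abs(total - 1.0) > _NSAF_SUM_TOL:
        raise ValueError(f"NSAF values sum to {total!r}, expected 1 within {_NSAF_SUM_TOL}")
    ppm = {a: v * PPM_TOTAL for a, v in nsaf.items()}
    return AbundanceProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        condition=condition,
        ppm=ppm,
        nsaf=dict(nsaf),
    )


def quantify_profile(
    profile: SpectralCountProfile, proteins: list[ProteinEntry]
) -> AbundanceProfile:
    """Convenience: counts -> NSAF -> ppm for one sample, keeping metadata."""
    nsaf = compute_nsaf(profile, proteins)
    return compute_ppm(
        nsaf,
        sample_id=profile.sample_id,
        patient_id=profile.patient_id,
        condition=profile.condition,
    )


def quantify_cohort(
    profiles: list[SpectralCountProfile], proteins: list[ProteinEntry]
) -> list[AbundanceProfile]:
    return [quantify_profile(p, proteins) for p in profiles]


def merge_fraction_counts(
    fractions: list[SpectralCountProfile],
) -> SpectralCountProfile:
    """Sum per-protein counts across gel/LC fractions of a single sample.

    Mirrors grouping a sample's fraction files into one database search.
    """
    if not fractions:
        raise ValueError("no fractions to merge")
    ids = {f.sample_id for f in fractions}
    if len(ids) > 1:
        raise ValueError(f"fractions belong to different samples: {sorted(ids)}")
    merged: dict[str, int] = {}
    for frac in fractions:
        for acc, c in frac.counts.items():
            merged[acc] = merged.get(acc, 0) + c
    first = fractions[0]
    return SpectralCountProfile(
        sample_id=first.sample_id,
        patient_id=first.patient_id,
        condition=first.condition,
        counts=merged,
    )
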