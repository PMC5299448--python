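"""Proteome-profile quality control.

Three complementary checks:

* **Housekeeping coverage score** — the percentage (0-100) of a grouped
  reference list of ubiquitous protein-complex members identified in a
  profile.  Instruments miss the low-abundance tail, but a complete profile
  should recover essentially all housekeeping complexes, so the score
  measures profile integrity independent of the biology under study.
* **Abundance distribution** — a histogram of detected proteins over
  log10(ppm), splitting the profile into the major (>= 1 ppm) and minor
  (< 1 ppm) abundance populations.
* **Replicate CV** — coefficient of variation of each protein's ppm across
  technical replicates, summarized per abundance bin; low-abundance
  proteins show much larger CV because few spectra sample them.
"""

from __future__ import annotations

import math

import numpy as np

from .models import (
    AbundanceProfile,
    CVReport,
    DistributionSummary,
    HousekeepingReference,
    QCReport,
)

#: Abundance bins used in the workflow's narrative: <1, 1-10, 10-100,
#: 100-1000, >1000 ppm.
DEFAULT_PPM_BINS: list[tuple[float, float]] = [
    (0.0, 1.0),
    (1.0, 10.0),
    (10.0, 100.0),
    (100.0, 1000.0),
    (1000.0, math.inf),
]


def score_profile(
    profile: AbundanceProfile, reference: HousekeepingReference
) -> QCReport:
    """Score a profile 0-100 by the fraction of reference members it detected.

    A member counts as found iff its ppm is > 0 (equivalently, spectrum
    count > 0; no minimum-PSM filter).  The score is the exact percentage,
    not rounded; round only for display.
    """
    n_ref = reference.total_members
    if n_ref == 0:
        raise ValueError("housekeeping reference is empty")
    detected = profile.detected()
    missing: set[str] = set()
    per_group: dict[str, float] = {}
    n_found = 0
    for gname, members in reference.groups.items():
        found = members & detected
        n_found += len(found)
        missing |= members - detected
        per_group[gname] = len(found) / len(members)
    return QCReport(
        sample_id=profile.sample_id,
        score=100.0 * n_found / n_ref,
        n_found=n_found,
        n_reference=n_ref,
        missing=missing,
        per_group_coverage=per_group,
    )


def abundance_distribution(
    profile: AbundanceProfile, bins_per_decade: int = 4
) -> DistributionSummary:
    """Histogram detected proteins over log10(ppm); split at the 1 ppm boundary."""
    ppm = np.array([v for v in profile.ppm.values() if v > 0], dtype=float)
    if ppm.size == 0:
        raise ValueError(f"sample {profile.sample_id}: no detected proteins")
    log = np.log10(ppm)
    lo = math.floor(log.min() * bins_per_decade) / bins_per_decade
    hi = math.ceil(log.max() * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(log, bins=edges)
    frac_above = float(np.mean(ppm >= 1.0))
    return DistributionSummary(
        bin_edges=edges.tolist(),
        counts_per_bin=counts.astype(int).tolist(),
        fraction_above_1ppm=frac_above,
        fraction_below_1ppm=1.0 - frac_above,
    )


def replicate_cv(
    replicates: list[AbundanceProfile],
    bins: list[tuple[float, float]] | None = None,
) -> CVReport:
    """Per-protein CV% across technical replicates, summarized per ppm bin.

    For each protein detected in at least one replicate, CV% = 100 x
    sd / mean of its ppm values across replicates, with undetected
    encoded as 0 ppm and sd the n-1 (sample) standard deviation.  Proteins
    are assigned to bins by their mean ppm; bins follow
    :data:`DEFAULT_PPM_BINS` unless overridden.
    """
    if len(replicates) < 2:
        raise ValueError("replicate_cv needs at least 2 replicate profiles")
    if bins is None:
        bins = DEFAULT_PPM_BINS
    accessions = sorted(set().union(*(r.detected() for r in replicates)))
    mat = np.array(
        [[r.ppm.get(acc, 0.0) for r in replicates] for acc in accessions], dtype=float
    )
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    cvs = 100.0 * sds / means  # means > 0: every row has >=1 detection

    per_bin_cv: list[float] = []
    per_bin_n: list[int] = []
    for lo, hi in bins:
        mask = (means >= lo) & (means < hi)
        per_bin_n.append(int(mask.sum()))
        per_bin_cv.append(float(cvs[mask].mean()) if mask.any() else math.nan)
    return CVReport(
        abundance_bins=list(bins),
        mean_cv_percent_per_bin=per_bin_cv,
        n_proteins_per_bin=per_bin_n,
        overall_mean_cv_percent=float(cvs.mean()),
        overall_sd_cv_percent=float(cvs.std(ddof=1)) if cvs.size > 1 else 0.0,
    )
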