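"""Synthetic paired tumor/adjacent spectral-count cohorts with ground truth.

The generator emulates the statistical structure the analysis assumes:

* per-protein baseline relative abundances are log-normal (wide dynamic
  range spanning several orders of magnitude) and normalized to 1;
* a planted fraction of proteins changes in tumors by configurable folds;
* each sample adds independent log-normal biological noise per protein and
  is renormalized (relative abundance is compositional);
* spectrum counts are drawn multinomially at a fixed per-sample depth with
  probability proportional to abundance x protein length, so NSAF
  (count / length, normalized) is the natural inverse of the generation
  process and detection dropout emerges for proteins whose expected count
  falls below ~1 — no separate dropout knob.

Because ppm is a closed (relative) unit, planting extra mass in tumors
depresses every other protein's share; the ground truth therefore records
both the nominal planted fold and the *realized* fold after
renormalization, and planted POC chains carry their realized percent
change.  Recovery should be judged against the realized values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    Condition,
    HousekeepingReference,
    POCDefinition,
    ProteinEntry,
    SpectralCountProfile,
)

#: Ten housekeeping-complex group sizes summing to 444 entries
#: (synthetic stand-in for the grouped reference; members are generated
#: accessions, not a curated list).
DEFAULT_HOUSEKEEPING_SIZES: tuple[int, ...] = (10, 86, 77, 42, 49, 17, 9, 17, 102, 35)

_HK_GROUP_NAMES = (
    "arp2_3_complex",
    "cytoplasmic_ribosome",
    "mitochondrial_ribosome",
    "nuclear_pore_complex",
    "histones",
    "proteasome",
    "cop9_signalosome",
    "tca_enzymes",
    "respiratory_chain",
    "atpase_pumps",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the paired-cohort design the analysis targets: 22
    patients, 2,000 proteins, 100,000 spectra per sample, 5% of proteins
    planted at 8-fold (4% up, 1% down), and a +50% planted POC chain.
    ``patient_effect_sd`` is the natural-log standard deviation of
    per-sample biological noise (0.3 ~ 30% CV between patients).
    """

    n_patients: int = 22
    n_proteins: int = 2000
    depth_counts_per_sample: int = 100_000
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 2.0
    fraction_up: float = 0.04
    fraction_down: float = 0.01
    fold_up_range: tuple[float, float] = (8.0, 8.0)
    fold_down_range: tuple[float, float] = (0.125, 0.125)
    patient_effect_sd: float = 0.3
    length_range_aa: tuple[int, int] = (100, 2000)
    planted_min_baseline_ppm: float = 50.0
    planted_max_mass_quantile: float = 0.85
    housekeeping_group_sizes: tuple[int, ...] = DEFAULT_HOUSEKEEPING_SIZES
    poc_chain_size: int = 20
    poc_fold: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_patients < 2:
            problems.append("n_patients must be >= 2")
        if self.n_proteins < 1:
            problems.append("n_proteins must be >= 1")
        if self.depth_counts_per_sample < 1:
            problems.append("depth_counts_per_sample must be >= 1")
        if not (0 <= self.fraction_up and 0 <= self.fraction_down):
            problems.append("fractions must be non-negative")
        if self.fraction_up + self.fraction_down >= 1:
            problems.append("fraction_up + fraction_down must be < 1")
        if self.fold_up_range[0] <= 1:
            problems.append("fold_up_range must be > 1")
        if not (0 < self.fold_down_range[1] < 1):
            problems.append("fold_down_range must be in (0, 1)")
        if self.fold_up_range[0] > self.fold_up_range[1]:
            problems.append("fold_up_range must be (low, high)")
        if self.fold_down_range[0] > self.fold_down_range[1]:
            problems.append("fold_down_range must be (low, high)")
        if self.length_range_aa[0] < 1 or self.length_range_aa[0] > self.length_range_aa[1]:
            problems.append("length_range_aa must be a positive (min, max)")
        if self.patient_effect_sd < 0:
            problems.append("patient_effect_sd must be >= 0")
        if any(s < 1 for s in self.housekeeping_group_sizes):
            problems.append("housekeeping group sizes must be >= 1")
        if self.poc_chain_size < 1:
            problems.append("poc_chain_size must be >= 1")
        if self.poc_fold <= 0:
            problems.append("poc_fold must be > 0")
        reserved = (
            self.n_planted_up
            + self.n_planted_down
            + sum(self.housekeeping_group_sizes)
            + 2 * self.poc_chain_size
        )
        if reserved > self.n_proteins:
            problems.append(
                f"n_proteins={self.n_proteins} too small for planted+housekeeping+POC "
                f"assignments ({reserved} needed)"
            )
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    @property
    def n_planted_up(self) -> int:
        return round(self.fraction_up * self.n_proteins)

    @property
    def n_planted_down(self) -> int:
        return round(self.fraction_down * self.n_proteins)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks.

    ``table`` has one row per protein: baseline (adjacent) ppm, nominal and
    realized tumor/adjacent fold, changed flag, housekeeping group and POC
    chain membership.  ``poc_true_percent_change`` maps (pathway, chain) to
    the realized percent change of the chain's expected summed ppm.
    """

    table: pd.DataFrame
    housekeeping: HousekeepingReference
    pocs: list[POCDefinition]
    poc_true_percent_change: dict[tuple[str, str], float]
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def planted_up(self) -> set[str]:
        t = self.table
        return set(t.loc[t["planted_class"] == "up", "accession"])

    @property
    def planted_down(self) -> set[str]:
        t = self.table
        return set(t.loc[t["planted_class"] == "down", "accession"])

    @property
    def planted_signature(self) -> set[str]:
        """Proteins planted as differential (up or down), the recovery target."""
        return self.planted_up | self.planted_down

    @property
    def null_proteins(self) -> set[str]:
        """Proteins with no planted change of any kind (fold exactly 1)."""
        t = self.table
        return set(
            t.loc[(t["planted_class"] == "") & (t["poc_chain"] == ""), "accession"]
        )


def _sample_counts(
    rng: np.random.Generator,
    rel_abundance: np.ndarray,
    lengths: np.ndarray,
    depth: int,
    noise_sd: float,
) -> np.ndarray:
    """One sample's multinomial spectrum counts, probability ~ abundance x length."""
    w = rel_abundance.copy()
    if noise_sd > 0:
        w = w * np.exp(rng.normal(0.0, noise_sd, size=w.size))
    p = w * lengths
    p /= p.sum()
    return rng.multinomial(depth, p)


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[list[ProteinEntry], list[SpectralCountProfile], GroundTruth]:
    """Generate a paired cohort of ``n_patients`` x {tumor, adjacent} samples.

    The same seed reproduces the cohort bit-identically; per-sample draws
    use sub-streams spawned deterministically from the global seed.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    n = config.n_proteins
    ss = np.random.SeedSequence(config.seed)
    struct_seed, sample_root = ss.spawn(2)
    rng = np.random.default_rng(struct_seed)

    accessions = np.array([f"PROT{i:05d}" for i in range(n)])
    lengths = rng.integers(
        config.length_range_aa[0], config.length_range_aa[1] + 1, size=n
    )
    base = rng.lognormal(
        config.abundance_lognormal_mu, config.abundance_lognormal_sigma, size=n
    )
    baseline = base / base.sum()

    # planted (changed) proteins come from a mid-abundance band: detectable
    # (baseline >= planted_min_baseline_ppm) but outside the top abundance
    # tier, which in tumor proteomes is dominated by stable housekeeping
    # mass; POC chains draw from the same band, the planted chain carrying
    # its own modest fold
    n_up, n_down = config.n_planted_up, config.n_planted_down
    rank = np.argsort(baseline)
    cap = int(config.planted_max_mass_quantile * n)
    eligible = np.zeros(n, dtype=bool)
    eligible[rank[:cap]] = True
    eligible &= baseline >= config.planted_min_baseline_ppm / 1e6
    n_assign = n_up + n_down + 2 * config.poc_chain_size
    pool = np.flatnonzero(eligible)
    if pool.size < n_assign:
        raise ValueError(
            f"only {pool.size} proteins in the plantable abundance band "
            f"({config.planted_min_baseline_ppm} ppm to the "
            f"{config.planted_max_mass_quantile:.0%} abundance quantile) "
            f"but {n_assign} planted assignments requested"
        )
    order = rng.permutation(pool)
    idx_up = order[:n_up]
    idx_down = order[n_up : n_up + n_down]
    cursor = n_up + n_down
    idx_poc_changed = order[cursor : cursor + config.poc_chain_size]
    cursor += config.poc_chain_size
    idx_poc_null = order[cursor : cursor + config.poc_chain_size]
    cursor += config.poc_chain_size

    # housekeeping members drawn from abundant unassigned proteins so the
    # reference is mostly detectable, as real housekeeping complexes are
    assigned = set(order[:cursor].tolist())
    remaining = np.array([i for i in range(n) if i not in assigned])
    remaining_sorted = remaining[np.argsort(-baseline[remaining])]
    n_hk = sum(config.housekeeping_group_sizes)
    hk_pool = remaining_sorted[: max(n_hk, int(0.6 * remaining.size))]
    idx_hk = rng.choice(hk_pool, size=n_hk, replace=False)

    nominal_fold = np.ones(n)
    nominal_fold[idx_up] = rng.uniform(*config.fold_up_range, size=n_up)
    nominal_fold[idx_down] = rng.uniform(*config.fold_down_range, size=n_down)
    nominal_fold[idx_poc_changed] = config.poc_fold
    planted_class = np.full(n, "", dtype=object)
    planted_class[idx_up] = "up"
    planted_class[idx_down] = "down"

    tumor_w = baseline * nominal_fold
    tumor_p = tumor_w / tumor_w.sum()
    realized_fold = tumor_p / baseline

    hk_groups: dict[str, set[str]] = {}
    hk_group_of = np.full(n, "", dtype=object)
    pos = 0
    for gname, size in zip(_HK_GROUP_NAMES, config.housekeeping_group_sizes):
        members = idx_hk[pos : pos + size]
        pos += size
        hk_groups[gname] = set(accessions[members])
        hk_group_of[members] = gname
    housekeeping = HousekeepingReference(groups=hk_groups)

    poc_chain_of = np.full(n, "", dtype=object)
    poc_chain_of[idx_poc_changed] = "activated_chain"
    poc_chain_of[idx_poc_null] = "null_chain"
    pocs = [
        POCDefinition(
            pathway="planted_pathway",
            chain="activated_chain",
            members=frozenset(accessions[idx_poc_changed]),
        ),
        POCDefinition(
            pathway="planted_pathway",
            chain="null_chain",
            members=frozenset(accessions[idx_poc_null]),
        ),
    ]
    poc_truth = {}
    for poc, idx in (
        (pocs[0], idx_poc_changed),
        (pocs[1], idx_poc_null),
    ):
        s_t = tumor_p[idx].sum()
        s_a = baseline[idx].sum()
        poc_truth[poc.key] = 100.0 * (s_t - s_a) / s_a

    proteins = [
        ProteinEntry(accession=acc, length_aa=int(L))
        for acc, L in zip(accessions, lengths)
    ]

    profiles: list[SpectralCountProfile] = []
    child_seeds = sample_root.spawn(2 * config.n_patients)
    for i in range(config.n_patients):
        patient = f"P{i + 1:02d}"
        for j, (cond, abund) in enumerate(
            ((Condition.TUMOR, tumor_p), (Condition.ADJACENT, baseline))
        ):
            srng = np.random.default_rng(child_seeds[2 * i + j])
            counts = _sample_counts(
                srng,
                abund,
                lengths.astype(float),
                config.depth_counts_per_sample,
                config.patient_effect_sd,
            )
            suffix = "T" if cond is Condition.TUMOR else "A"
            profiles.append(
                SpectralCountProfile(
                    sample_id=f"{patient}_{suffix}",
                    patient_id=patient,
                    condition=cond,
                    counts={
                        acc: int(c) for acc, c in zip(accessions, counts) if c > 0
                    },
                )
            )

    table = pd.DataFrame(
        {
            "accession": accessions,
            "length_aa": lengths,
            "baseline_ppm": baseline * 1e6,
            "nominal_fold": nominal_fold,
            "realized_fold": realized_fold,
            "changed": nominal_fold != 1.0,
            "planted_class": planted_class,
            "housekeeping_group": hk_group_of,
            "poc_chain": poc_chain_of,
        }
    )
    truth = GroundTruth(
        table=table,
        housekeeping=housekeeping,
        pocs=pocs,
        poc_true_percent_change=poc_truth,
        config=config,
    )
    return proteins, profiles, truth


def generate_replicates(
    proteins: list[ProteinEntry],
    rel_abundance: dict[str, float],
    n_replicates: int,
    depth: int,
    seed: int,
) -> list[SpectralCountProfile]:
    """Independent multinomial technical replicates of one abundance vector.

    Emulates re-injecting the same sample: no biological noise, only
    counting (sampling) noise, which is what replicate CV analysis
    measures.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    accs = [p.accession for p in proteins]
    lengths = np.array([p.length_aa for p in proteins], dtype=float)
    abund = np.array([rel_abundance.get(a, 0.0) for a in accs], dtype=float)
    if abund.sum() <= 0:
        raise ValueError("abundance vector is all zero")
    abund = abund / abund.sum()
    replicates = []
    for k, child in enumerate(np.random.SeedSequence(seed).spawn(n_replicates)):
        rng = np.random.default_rng(child)
        counts = _sample_counts(rng, abund, lengths, depth, noise_sd=0.0)
        replicates.append(
            SpectralCountProfile(
                sample_id=f"rep{k + 1:02d}",
                patient_id="replicate",
                condition=Condition.TUMOR,
                counts={a: int(c) for a, c in zip(accs, counts) if c > 0},
            )
        )
    return replicates
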