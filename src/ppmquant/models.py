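"""Core domain types for spectral-counting proteomics profiles.

A *profile* is the protein-level report for one LC-MS/MS sample: every
identified protein with the number of peptide spectra matched to it
(spectrum count, ``S_N``).  Quantification converts counts to normalized
spectral abundance factors (NSAF) and to parts-per-million of total
profile mass, so that every profile carries exactly 1,000,000 ppm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping


class Condition(str, enum.Enum):
    """Sample condition in the paired design: tumor or adjacent normal tissue."""

    TUMOR = "tumor"
    ADJACENT = "adjacent"

    @classmethod
    def parse(cls, label: str) -> "Condition":
        try:
            return cls(label.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown condition label {label!r}; expected 'tumor' or 'adjacent'"
            ) from None


@dataclass(frozen=True)
class ProteinEntry:
    """One protein in the search database: accession plus length in residues."""

    accession: str
    length_aa: int
    description: str = ""
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError(
                f"protein {self.accession}: length_aa must be >= 1, got {self.length_aa}"
            )


@dataclass
class SpectralCountProfile:
    """Spectrum counts for one sample (``S_N`` per protein).

    ``counts`` maps accession to a non-negative integer; proteins absent from
    the map were not identified in this sample (equivalent to count 0).
    """

    sample_id: str
    patient_id: str
    condition: Condition
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if isinstance(self.condition, str):
            self.condition = Condition.parse(self.condition)
        for acc, c in self.counts.items():
            if c < 0:
                raise ValueError(f"sample {self.sample_id}: negative count for {acc}")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError(f"sample {self.sample_id}: all spectrum counts are zero")

    @property
    def total_counts(self) -> int:
        return sum(self.counts.values())

    def detected(self) -> set[str]:
        """Accessions with at least one matched spectrum."""
        return {a for a, c in self.counts.items() if c > 0}


@dataclass
class AbundanceProfile:
    """NSAF / ppm relative abundances for one sample.

    Invariants: NSAF sums to 1 over detected proteins, ppm sums to
    1,000,000, and ppm > 0 exactly for proteins with a positive spectrum
    count.  Zero-count proteins are carried at 0 ppm rather than dropped so
    downstream detection logic is explicit.
    """

    sample_id: str
    patient_id: str
    condition: Condition
    ppm: dict[str, float]
    nsaf: dict[str, float]

    def __post_init__(self) -> None:
        if isinstance(self.condition, str):
            self.condition = Condition.parse(self.condition)

    def detected(self) -> set[str]:
        return {a for a, v in self.ppm.items() if v > 0}

    @property
    def total_ppm(self) -> float:
        return math.fsum(self.ppm.values())


@dataclass
class HousekeepingReference:
    """Grouped reference list of ubiquitously expressed protein complexes.

    Coverage of these members scores the completeness of a profile 0-100.
    Groups are disjoint at the accession level (isoforms count as distinct
    entries).
    """

    groups: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gname, members in self.groups.items():
            if not members:
                raise ValueError(f"reference group {gname!r} is empty")
            for acc in members:
                if acc in seen:
                    raise ValueError(
                        f"accession {acc} appears in groups {seen[acc]!r} and {gname!r}"
                    )
                seen[acc] = gname

    @property
    def total_members(self) -> int:
        return sum(len(m) for m in self.groups.values())

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for m in self.groups.values():
            out |= m
        return out


@dataclass(frozen=True)
class GeneList:
    """A named published gene/protein list used for overlap analysis."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene list {self.name!r} is empty")


class TestUsed(str, enum.Enum):
    """Which significance test produced a differential record's p-value."""

    PAIRED_T = "paired_t"
    FISHER_PRESENCE = "fisher_presence"
    DEGENERATE = "degenerate"


class ClassLabel(str, enum.Enum):
    """Abundance-change class: <2-fold stable, not significant, or >=2-fold changed."""

    STABLE_LT2FOLD = "stable_lt2fold"
    NOT_SIGNIFICANT = "not_significant"
    CHANGED_GE2FOLD = "changed_ge2fold"


@dataclass
class DifferentialRecord:
    """Paired tumor/adjacent comparison for one protein.

    ``ratio`` follows the detection conventions: 1000 when detected only in
    tumors, 0.001 when detected only in adjacent tissue, otherwise the ratio
    of group mean ppm.  ``signature_flag`` marks the >4-fold, p < 0.01
    signature proteins.
    """

    accession: str
    mean_ppm_tumor: float
    mean_ppm_adjacent: float
    ratio: float
    p_value: float
    test_used: TestUsed
    n_detected_tumor: int
    n_detected_adjacent: int
    class_label: ClassLabel
    signature_flag: bool
    q_value: float = math.nan


@dataclass
class OverlapSummary:
    """Overlap of a published gene list with the identified/differential sets."""

    list_name: str
    n_listed: int
    n_identified: int
    n_de_1p5fold: int
    n_overlap_signature: int

    def __post_init__(self) -> None:
        if not (
            self.n_overlap_signature
            <= self.n_de_1p5fold
            <= self.n_identified
            <= self.n_listed
        ):
            raise ValueError(
                "overlap counts must be nested: "
                f"{self.n_overlap_signature} <= {self.n_de_1p5fold} "
                f"<= {self.n_identified} <= {self.n_listed}"
            )


@dataclass
class QCReport:
    """Housekeeping-coverage quality score for one profile (0-100)."""

    sample_id: str
    score: float
    n_found: int
    n_reference: int
    missing: set[str]
    per_group_coverage: dict[str, float]


@dataclass
class DistributionSummary:
    """Histogram of detected-protein abundances on the log10-ppm scale."""

    bin_edges: list[float]
    counts_per_bin: list[int]
    fraction_above_1ppm: float
    fraction_below_1ppm: float

    @property
    def n_detected(self) -> int:
        return int(sum(self.counts_per_bin))


@dataclass
class CVReport:
    """Replicate coefficient-of-variation summary, binned by mean abundance."""

    abundance_bins: list[tuple[float, float]]
    mean_cv_percent_per_bin: list[float]
    n_proteins_per_bin: list[int]
    overall_mean_cv_percent: float
    overall_sd_cv_percent: float


@dataclass(frozen=True)
class POCDefinition:
    """One pathway protein ontology chain: a functional role-group of a pathway.

    A chain is one of the roles (ligands, receptors, activating regulators,
    inhibitory regulators, effectors) or a named complex; summing member ppm
    measures the chain's activation strength in a profile.
    """

    pathway: str
    chain: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"POC {self.pathway}/{self.chain} has no members")

    @property
    def key(self) -> tuple[str, str]:
        return (self.pathway, self.chain)


@dataclass
class POCResult:
    """Tumor-vs-adjacent comparison of one chain's summed ppm.

    ``percent_change`` is 100 x (tumor - adjacent) / adjacent on the group
    means of the per-sample sums; NaN when the adjacent mean sum is zero.
    """

    pathway: str
    chain: str
    mean_sum_ppm_tumor: float
    mean_sum_ppm_adjacent: float
    percent_change: float
    p_value: float
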