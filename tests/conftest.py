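import numpy as np
import pytest

from ppmquant import (
    AbundanceProfile,
    Condition,
    ProteinEntry,
    SpectralCountProfile,
    SyntheticConfig,
    generate_cohort,
    quantify_cohort,
)


@pytest.fixture
def toy_proteins():
    return [
        ProteinEntry("A", 100),
        ProteinEntry("B", 200),
        ProteinEntry("C", 50, description="carbonic anhydrase"),
    ]


@pytest.fixture
def toy_profile():
    return SpectralCountProfile(
        sample_id="s1",
        patient_id="p1",
        condition=Condition.TUMOR,
        counts={"A": 10, "B": 10, "C": 0},
    )


def make_abundance(sample_id, patient_id, condition, ppm):
    """Build an AbundanceProfile directly from a ppm map (tests only)."""
    total = sum(ppm.values())
    nsaf = {a: v / total for a, v in ppm.items()} if total else {}
    return AbundanceProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        condition=condition,
        ppm=dict(ppm),
        nsaf=nsaf,
    )


@pytest.fixture
def paired_cohort_builder():
    """Build a paired cohort from {accession: (tumor_ppm, adjacent_ppm)} maps.

    Each patient gets the given per-condition ppm values exactly (no noise),
    so record-level expectations are deterministic.
    """

    def build(per_protein: dict[str, tuple[list[float], list[float]]]):
        n = len(next(iter(per_protein.values()))[0])
        profiles = []
        for i in range(n):
            pid = f"p{i + 1}"
            t_ppm = {a: v[0][i] for a, v in per_protein.items()}
            a_ppm = {a: v[1][i] for a, v in per_protein.items()}
            profiles.append(make_abundance(f"{pid}_T", pid, Condition.TUMOR, t_ppm))
            profiles.append(make_abundance(f"{pid}_A", pid, Condition.ADJACENT, a_ppm))
        return profiles

    return build


SMALL_COHORT_CONFIG = SyntheticConfig(
    n_patients=6,
    n_proteins=400,
    depth_counts_per_sample=30_000,
    fraction_up=0.05,
    fraction_down=0.025,
    housekeeping_group_sizes=(5,) * 10,
    poc_chain_size=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic paired cohort shared across tests (6 pairs, 400 proteins)."""
    proteins, profiles, truth = generate_cohort(SMALL_COHORT_CONFIG)
    return proteins, profiles, truth


@pytest.fixture(scope="session")
def small_cohort_abundances(small_cohort):
    proteins, profiles, _ = small_cohort
    return quantify_cohort(profiles, proteins)
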