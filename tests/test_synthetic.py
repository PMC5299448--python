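import numpy as np
import pytest

from ppmquant import (
    PPM_TOTAL,
    ProteinEntry,
    SyntheticConfig,
    generate_cohort,
    generate_replicates,
    quantify_cohort,
)

from .conftest import SMALL_COHORT_CONFIG

SMALL = SMALL_COHORT_CONFIG


class TestConfigValidation:
    def test_defaults_describe_the_reference_cohort(self):
        cfg = SyntheticConfig()
        cfg.validate()
        assert cfg.n_patients == 22
        assert cfg.n_proteins == 2000
        assert cfg.depth_counts_per_sample == 100_000
        assert cfg.n_planted_up + cfg.n_planted_down == 100  # 5% planted

    def test_planted_count_arithmetic(self):
        cfg = SyntheticConfig(fraction_up=0.05, fraction_down=0.0, n_proteins=1000)
        assert cfg.n_planted_up == 50

    def test_invalid_config_lists_all_violations(self):
        cfg = SyntheticConfig(n_patients=1, fraction_up=0.8, fraction_down=0.3,
                              fold_up_range=(0.5, 0.5))
        with pytest.raises(ValueError) as exc:
            cfg.validate()
        msg = str(exc.value)
        assert "n_patients" in msg
        assert "fraction_up + fraction_down" in msg
        assert "fold_up_range" in msg

    def test_too_many_assignments_for_protein_count(self):
        with pytest.raises(ValueError, match="too small"):
            SyntheticConfig(n_proteins=100).validate()


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        p1, prof1, t1 = generate_cohort(SMALL)
        p2, prof2, t2 = generate_cohort(SMALL)
        assert p1 == p2
        assert [pr.counts for pr in prof1] == [pr.counts for pr in prof2]
        assert t1.table.equals(t2.table)

    def test_different_seed_differs(self):
        import dataclasses

        _, prof1, _ = generate_cohort(SMALL)
        _, prof2, _ = generate_cohort(dataclasses.replace(SMALL, seed=SMALL.seed + 1))
        assert [p.counts for p in prof1] != [p.counts for p in prof2]

    def test_cohort_shape_and_pairing(self, small_cohort):
        proteins, profiles, truth = small_cohort
        assert len(proteins) == SMALL.n_proteins
        assert len(profiles) == 2 * SMALL.n_patients
        patients = {p.patient_id for p in profiles}
        assert len(patients) == SMALL.n_patients
        for pid in patients:
            conds = {p.condition.value for p in profiles if p.patient_id == pid}
            assert conds == {"tumor", "adjacent"}
        for p in profiles:
            assert p.total_counts == SMALL.depth_counts_per_sample

    def test_ground_truth_consistent_with_config(self, small_cohort):
        _, _, truth = small_cohort
        assert len(truth.planted_up) == SMALL.n_planted_up
        assert len(truth.planted_down) == SMALL.n_planted_down
        assert truth.housekeeping.total_members == sum(SMALL.housekeeping_group_sizes)
        assert len(truth.housekeeping.groups) == len(SMALL.housekeeping_group_sizes)
        # planted, POC and housekeeping assignments never overlap
        poc_members = set().union(*(p.members for p in truth.pocs))
        hk = truth.housekeeping.all_members()
        planted = truth.planted_signature
        assert not (planted & poc_members)
        assert not (planted & hk)
        assert not (poc_members & hk)

    def test_full_pipeline_conserves_ppm_mass(self, small_cohort):
        proteins, profiles, _ = small_cohort
        for prof in quantify_cohort(profiles, proteins):
            assert prof.total_ppm == pytest.approx(PPM_TOTAL, abs=1e-3)

    def test_dropout_emerges_for_low_abundance_proteins(self, small_cohort):
        """Proteins with expected count < 1 are missed in some samples, so the
        detection-based code paths get exercised without a dropout knob."""
        proteins, profiles, truth = small_cohort
        n_samples = len(profiles)
        det_frac = {
            acc: sum(acc in p.detected() for p in profiles) / n_samples
            for acc in (pr.accession for pr in proteins)
        }
        partial = [f for f in det_frac.values() if 0 < f < 1]
        assert len(partial) > 0

    def test_mean_ppm_converges_to_planted_abundance_with_depth(self):
        """Estimator consistency: deeper sampling shrinks the error between
        mean measured ppm and the planted baseline abundance."""
        import dataclasses

        errors = {}
        for depth in (10_000, 1_000_000):
            cfg = dataclasses.replace(SMALL, depth_counts_per_sample=depth,
                                      patient_effect_sd=0.0, seed=3)
            proteins, profiles, truth = generate_cohort(cfg)
            adj = [p for p in quantify_cohort(profiles, proteins)
                   if p.condition.value == "adjacent"]
            baseline = truth.table.set_index("accession")["baseline_ppm"]
            mean_ppm = {
                acc: np.mean([p.ppm.get(acc, 0.0) for p in adj])
                for acc in baseline.index
            }
            rel_err = [
                abs(mean_ppm[a] - b) / b
                for a, b in baseline.items()
                if b > 50  # quantifiable range
            ]
            errors[depth] = float(np.median(rel_err))
        assert errors[1_000_000] < errors[10_000] / 2


class TestGenerateReplicates:
    @pytest.fixture
    def vector(self):
        rng = np.random.default_rng(2)
        proteins = [ProteinEntry(f"P{i}", int(L)) for i, L in
                    enumerate(rng.integers(100, 1000, size=50))]
        ab = rng.lognormal(0, 1.5, size=50)
        return proteins, dict(zip((p.accession for p in proteins), ab / ab.sum()))

    def test_each_replicate_sums_to_depth(self, vector):
        proteins, ab = vector
        reps = generate_replicates(proteins, ab, n_replicates=3, depth=5000, seed=1)
        assert [r.total_counts for r in reps] == [5000] * 3

    def test_same_seed_reproduces_replicates(self, vector):
        proteins, ab = vector
        r1 = generate_replicates(proteins, ab, 2, 5000, seed=9)
        r2 = generate_replicates(proteins, ab, 2, 5000, seed=9)
        assert [r.counts for r in r1] == [r.counts for r in r2]

    def test_fewer_than_two_rejected(self, vector):
        proteins, ab = vector
        with pytest.raises(ValueError, match=">= 2"):
            generate_replicates(proteins, ab, 1, 5000, seed=1)
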