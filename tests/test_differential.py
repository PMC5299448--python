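import math
from fractions import Fraction

import numpy as np
import pytest

from ppmquant import TestUsed as SigTest
from ppmquant import (
    ClassLabel,
    Condition,
    GeneList,
    compute_ratio,
    fisher_presence_test,
    overlap_with_gene_list,
    paired_t_test,
    run_differential,
    select_marker_panel,
)

from .conftest import make_abundance
from .oracles import fisher_two_sided_enumeration, paired_t_two_sided


class TestPairedT:
    def test_textbook_example(self):
        # pairs (2,1),(4,2),(5,3): d=(1,2,2), t = (5/3)/(sqrt(1/3)/sqrt(3)) = 5
        res = paired_t_test([2, 4, 5], [1, 2, 3])
        assert res.statistic == pytest.approx(5.0)
        assert res.p_value == pytest.approx(paired_t_two_sided([2, 4, 5], [1, 2, 3]))
        assert not res.degenerate

    def test_no_signal_gives_p_one(self):
        res = paired_t_test([3.0, 7.0, 1.0], [3.0, 7.0, 1.0])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_constant_nonzero_shift_is_degenerate(self):
        res = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert math.isnan(res.p_value)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_t_test([1, 2, 3], [1, 2])

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t_test([1.0], [2.0])

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 30))
            t = rng.normal(10, 5, size=n)
            a = rng.normal(9, 5, size=n)
            if np.ptp(t - a) == 0:
                continue
            res = paired_t_test(t, a)
            assert res.p_value == pytest.approx(
                paired_t_two_sided(list(t), list(a)), abs=1e-10
            )


class TestFisherPresence:
    def test_full_separation_22_pairs(self):
        # 22/22 vs 0/22: only the two extreme tables are as improbable,
        # p = 2 / C(44, 22) exactly
        expected = float(2 / Fraction(math.comb(44, 22)))
        assert fisher_presence_test(22, 22, 0, 22) == pytest.approx(expected, rel=1e-9)

    def test_equal_detection_gives_p_one(self):
        assert fisher_presence_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        assert fisher_presence_test(3, 4, 1, 4) == pytest.approx(
            fisher_two_sided_enumeration(3, 1, 1, 3), rel=1e-9
        )

    def test_detections_exceeding_group_size_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fisher_presence_test(5, 4, 0, 4)


class TestComputeRatio:
    def test_plain_division_when_both_detected(self):
        assert compute_ratio(40.0, 10.0, 12, 9) == 4.0

    def test_tumor_only_detection_is_1000(self):
        assert compute_ratio(5.0, 0.0, 3, 0) == 1000.0

    def test_adjacent_only_detection_is_0_001(self):
        assert compute_ratio(0.0, 5.0, 0, 3) == 0.001

    def test_detected_nowhere_is_excluded_not_crash(self):
        assert compute_ratio(0.0, 0.0, 0, 0) is None


class TestRunDifferential:
    def test_tumor_only_protein_routed_to_fisher_with_ratio_1000(
        self, paired_cohort_builder
    ):
        n = 6
        profiles = paired_cohort_builder(
            {
                "ONLY_T": ([50.0] * n, [0.0] * n),
                "STABLE": ([1000.0] * n, [1000.0] * n),
                "FILL": ([500.0] * n, [500.0] * n),
            }
        )
        records = {r.accession: r for r in run_differential(profiles)}
        r = records["ONLY_T"]
        assert r.ratio == 1000.0
        assert r.test_used is SigTest.FISHER_PRESENCE
        assert r.p_value == pytest.approx(fisher_two_sided_enumeration(6, 0, 0, 6))
        assert r.signature_flag

    def test_identical_means_large_n_is_stable(self, paired_cohort_builder):
        rng = np.random.default_rng(3)
        n = 12
        base = rng.uniform(100, 200, size=n)
        profiles = paired_cohort_builder(
            {
                "EQ": (list(base), list(base)),
                "FILL": (list(rng.uniform(50, 60, n)), list(rng.uniform(50, 60, n))),
            }
        )
        records = {r.accession: r for r in run_differential(profiles)}
        assert records["EQ"].class_label is ClassLabel.STABLE_LT2FOLD
        assert not records["EQ"].signature_flag

    def test_protein_detected_nowhere_absent_from_output(self, paired_cohort_builder):
        n = 4
        profiles = paired_cohort_builder(
            {
                "NOWHERE": ([0.0] * n, [0.0] * n),
                "FILL": ([10.0] * n, [12.0] * n),
            }
        )
        accs = {r.accession for r in run_differential(profiles)}
        assert "NOWHERE" not in accs
        assert "FILL" in accs

    def test_unpaired_patient_named_in_error(self, paired_cohort_builder):
        profiles = paired_cohort_builder({"A": ([1.0, 2.0], [1.0, 2.0])})
        with pytest.raises(ValueError, match="p2"):
            run_differential(profiles[:-1])  # drop p2's adjacent profile

    def test_label_swap_antisymmetry(self, small_cohort_abundances):
        """Swapping tumor/adjacent labels inverts ratios (1000 <-> 0.001 for
        one-sided detections) and leaves p-values unchanged."""
        swapped = [
            make_abundance(
                p.sample_id,
                p.patient_id,
                Condition.ADJACENT if p.condition is Condition.TUMOR else Condition.TUMOR,
                p.ppm,
            )
            for p in small_cohort_abundances
        ]
        fwd = {r.accession: r for r in run_differential(small_cohort_abundances)}
        rev = {r.accession: r for r in run_differential(swapped)}
        assert set(fwd) == set(rev)
        for acc, r in fwd.items():
            s = rev[acc]
            if r.ratio == 1000.0:
                assert s.ratio == 0.001
            elif r.ratio == 0.001:
                assert s.ratio == 1000.0
            else:
                assert s.ratio == pytest.approx(1.0 / r.ratio, rel=1e-9)
            if math.isnan(r.p_value):
                assert math.isnan(s.p_value)
            else:
                assert s.p_value == pytest.approx(r.p_value, rel=1e-9)


class TestMarkerPanel:
    def _records(self, paired_cohort_builder):
        n = 6
        profiles = paired_cohort_builder(
            {
                # abundant overexpressed signature protein
                "UP_HI": ([260.0, 250, 240, 255, 245, 250], [50.0, 48, 52, 49, 51, 50]),
                # signature but too scarce for a panel (both means ~5 ppm)
                "UP_LO": ([5.2, 5.0, 4.9, 5.1, 5.0, 5.3], [1.0, 0.9, 1.1, 1.0, 1.05, 0.95]),
                # decreased marker abundant in adjacent tissue
                "DOWN_HI": ([30.0, 31, 29, 30, 32, 28], [400.0, 390, 410, 405, 395, 400]),
                "FILL": ([999000.0] * n, [999000.0] * n),
            }
        )
        return run_differential(profiles)

    def test_abundance_filter_uses_the_relevant_condition(self, paired_cohort_builder):
        records = self._records(paired_cohort_builder)
        by_acc = {r.accession: r for r in records}
        assert by_acc["UP_LO"].signature_flag  # signature, but filtered from panel
        panel = select_marker_panel(records, min_mean_ppm=20.0)
        accs = [r.accession for r in panel]
        assert "UP_HI" in accs
        assert "DOWN_HI" in accs
        assert "UP_LO" not in accs

    def test_ranked_by_log_fold_magnitude(self, paired_cohort_builder):
        panel = select_marker_panel(self._records(paired_cohort_builder))
        folds = [abs(math.log10(r.ratio)) for r in panel]
        assert folds == sorted(folds, reverse=True)

    def test_recovers_planted_markers_exactly(self, paired_cohort_builder):
        """A cohort with 11 abundant planted markers yields exactly those 11."""
        n = 8
        spec = {}
        for i in range(11):
            t = [200.0 + 10 * i + j for j in range(n)]
            a = [(200.0 + 10 * i + j) / 6.0 for j in range(n)]
            spec[f"MARK{i:02d}"] = (t, a)
        for i in range(30):
            base = [80.0 + i + 0.5 * j for j in range(n)]
            spec[f"NULL{i:02d}"] = (base, [b * 1.01 for b in base])
        panel = select_marker_panel(run_differential(paired_cohort_builder(spec)))
        assert sorted(r.accession for r in panel) == [f"MARK{i:02d}" for i in range(11)]


class TestOverlap:
    def _records(self, paired_cohort_builder):
        n = 6
        profiles = paired_cohort_builder(
            {
                "SIG": ([500.0, 510, 490, 505, 495, 500], [50.0, 51, 49, 50, 50, 50]),
                "MILD": ([160.0, 162, 158, 161, 159, 160], [100.0, 101, 99, 100, 100, 100]),
                "FLAT": ([100.0, 101, 99, 100, 100, 100], [100.0, 100, 100, 101, 99, 100]),
            }
        )
        return run_differential(profiles)

    def test_disjoint_list_overlaps_nothing(self, paired_cohort_builder):
        records = self._records(paired_cohort_builder)
        summary = overlap_with_gene_list(records, GeneList("x", frozenset({"ZZZ", "YYY"})))
        assert summary.n_listed == 2
        assert summary.n_identified == 0
        assert summary.n_de_1p5fold == 0
        assert summary.n_overlap_signature == 0

    def test_list_matching_signature_counts_it(self, paired_cohort_builder):
        records = self._records(paired_cohort_builder)
        sig = frozenset(r.accession for r in records if r.signature_flag)
        summary = overlap_with_gene_list(records, GeneList("sig", sig))
        assert summary.n_overlap_signature == len(sig)

    def test_counts_nested_and_match_brute_force_sets(self, paired_cohort_builder):
        records = self._records(paired_cohort_builder)
        rng = np.random.default_rng(9)
        accs = [r.accession for r in records] + ["ABSENT1", "ABSENT2"]
        for _ in range(20):
            members = frozenset(
                a for a in accs if rng.random() < 0.5
            ) or frozenset({accs[0]})
            s = overlap_with_gene_list(records, GeneList("rand", members))
            ident = {r.accession for r in records if r.accession in members}
            de = {
                r.accession
                for r in records
                if r.accession in ident
                and max(r.ratio, 1 / r.ratio) >= 1.5
                and r.p_value < 0.01
            }
            sig = {r.accession for r in records if r.accession in de and r.signature_flag}
            assert (s.n_identified, s.n_de_1p5fold, s.n_overlap_signature) == (
                len(ident), len(de), len(sig),
            )
            assert s.n_overlap_signature <= s.n_de_1p5fold <= s.n_identified <= s.n_listed

    def test_id_map_translates_accessions_to_symbols(self, paired_cohort_builder):
        records = self._records(paired_cohort_builder)
        summary = overlap_with_gene_list(
            records,
            GeneList("sym", frozenset({"GENE_SIG"})),
            id_map={"SIG": "GENE_SIG"},
        )
        assert summary.n_identified == 1
        assert summary.n_overlap_signature == 1

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneList("empty", frozenset())
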