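import pytest
from hypothesis import given, strategies as st

from comigratlas.comigration import (
    CoMigrationGroup,
    coverage_fraction,
    find_slice_partners,
    group_comigrating,
    profile_similarity,
    round_half_up,
    summarize_localization,
    tally_categories,
)
from comigratlas.errors import ValidationError
from comigratlas.profiling import MigrationProfile, Peak
from comigratlas.proteome_io import AnnotationRecord
from comigratlas.quantification import EmpaiResult


def _det(acc, s, n_obs=1):
    return EmpaiResult(acc, s, n_observed=n_obs, n_observable=10, empai=0.3)


def _pk(*slices):
    return [Peak(s, s, s, 1.0) for s in slices]


class TestSlicePartners:
    DETS = [_det("PsaC", 15), _det("PsaD", 15), _det("PsaA", 15, 0), _det("PsbA", 20)]

    def test_shared_slice_partner_found(self):
        assert find_slice_partners(self.DETS, "PsaC", 15) == {"PsaD"}

    def test_lonely_slice_is_empty(self):
        assert find_slice_partners(self.DETS, "PsbA", 20) == set()

    def test_query_absent_from_slice_still_lists_detected(self):
        assert find_slice_partners(self.DETS, "PsbA", 15) == {"PsaC", "PsaD"}


class TestProfileSimilarity:
    def test_identical_profiles(self):
        a = MigrationProfile("A", (0, 1, 3, 1))
        assert profile_similarity(a, a).score == pytest.approx(1.0)

    def test_anticorrelated_indicator_profiles(self):
        a = MigrationProfile("A", (1, 0, 0))
        b = MigrationProfile("B", (0, 0, 1))
        assert profile_similarity(a, b).score == pytest.approx(-0.5)

    def test_perfect_linear_relation(self):
        a = MigrationProfile("A", (1, 2))
        b = MigrationProfile("B", (2, 4))
        assert profile_similarity(a, b).score == pytest.approx(1.0)

    def test_length_mismatch_and_constant_errors(self):
        a = MigrationProfile("A", (1, 2))
        with pytest.raises(ValidationError):
            profile_similarity(a, MigrationProfile("B", (1, 2, 3)))
        with pytest.raises(ValidationError):
            profile_similarity(a, MigrationProfile("B", (2, 2)))

    @given(
        seed=st.integers(0, 100),
        scale=st.floats(0.01, 100),
        shift=st.floats(0, 50),
    )
    def test_symmetric_and_affine_invariant(self, seed, scale, shift):
        import numpy as np

        rng = np.random.default_rng(seed)
        va = rng.random(20)
        vb = rng.random(20)
        a = MigrationProfile("A", tuple(va))
        b = MigrationProfile("B", tuple(vb))
        r_ab = profile_similarity(a, b).score
        assert profile_similarity(b, a).score == pytest.approx(r_ab)
        b2 = MigrationProfile("B", tuple(vb * scale + shift))
        assert profile_similarity(a, b2).score == pytest.approx(r_ab, abs=1e-9)


class TestGroupComigrating:
    def test_same_slice_pair(self):
        groups = group_comigrating({"A": _pk(15), "B": _pk(15), "C": _pk(40)}, 0)
        assert [(g.sorted_members, g.anchor_slice) for g in groups] == [
            (("A", "B"), 15)
        ]

    def test_tolerance_threshold_behavior(self):
        peaks = {"A": _pk(15), "B": _pk(16)}
        assert group_comigrating(peaks, 0) == []
        (g,) = group_comigrating(peaks, 1)
        assert g.sorted_members == ("A", "B")
        assert g.max_apex_spread == 1

    def test_multi_peak_protein_joins_multiple_groups(self):
        groups = group_comigrating(
            {"A": _pk(10, 30), "B": _pk(10), "C": _pk(30)}, 0
        )
        assert [g.sorted_members for g in groups] == [("A", "B"), ("A", "C")]

    def test_distant_subset_group_survives(self):
        # a sub-complex lower in the gel (CF1-like) must not be pruned
        groups = group_comigrating(
            {"A": _pk(19, 28), "B": _pk(19, 28), "C": _pk(19), "D": _pk(19)}, 0
        )
        assert [g.sorted_members for g in groups] == [
            ("A", "B", "C", "D"),
            ("A", "B"),
        ]

    def test_windowing_artifact_subset_pruned(self):
        # apexes {47, 47/49, 47/49}: the pair at 49 is the same apex cluster
        groups = group_comigrating(
            {"A": _pk(47), "B": _pk(47, 49), "C": _pk(47, 49)}, 1
        )
        assert [g.sorted_members for g in groups] == [("A", "B", "C")]

    @given(
        seed=st.integers(0, 60),
        tolerance=st.integers(0, 2),
    )
    def test_tolerance_monotone_coarsening(self, seed, tolerance):
        import numpy as np

        rng = np.random.default_rng(seed)
        peaks = {
            f"P{i}": _pk(*rng.integers(1, 30, size=rng.integers(1, 3)))
            for i in range(8)
        }
        union_t = set().union(
            *[g.members for g in group_comigrating(peaks, tolerance)], set()
        )
        union_t1 = set().union(
            *[g.members for g in group_comigrating(peaks, tolerance + 1)], set()
        )
        assert union_t <= union_t1

    def test_group_invariants(self):
        with pytest.raises(ValidationError):
            CoMigrationGroup(frozenset({"A"}), 10, 0)


class TestSummaries:
    ANN = {
        **{f"T{i}": AnnotationRecord(f"T{i}", "thylakoid", "photosynthesis")
           for i in range(3)},
        "E1": AnnotationRecord("E1", "envelope", "transport"),
    }

    def test_counts_percents_and_mol(self):
        identified = ["T0", "T1", "T2", "E1", "U1"]  # U1 unannotated
        mol = {"T0": 40.0, "T1": 30.0, "T2": 20.0, "E1": 5.0, "U1": 5.0}
        summary = summarize_localization(identified, self.ANN, mol)
        assert summary.counts["thylakoid"] == 3
        assert summary.counts["unknown"] == 1
        assert sum(summary.counts.values()) == len(identified)
        assert summary.percents["thylakoid"] == 60
        assert summary.mol_percent["thylakoid"] == pytest.approx(90.0)
        assert sum(summary.mol_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_class_is_total(self):
        identified = ["T0", "T1"]
        mol = {"T0": 60.0, "T1": 40.0}
        summary = summarize_localization(identified, self.ANN, mol)
        assert summary.percents == {"thylakoid": 100}
        assert summary.mol_percent["thylakoid"] == pytest.approx(100.0)

    def test_empty_identified_set_errors(self):
        with pytest.raises(ValidationError):
            summarize_localization([], self.ANN, {})

    def test_category_tally_with_missing_annotation(self):
        counts = tally_categories(["T0", "E1", "U9"], self.ANN)
        assert counts == {"photosynthesis": 1, "transport": 1, "Unknown": 1}
        assert tally_categories([], self.ANN) == {}


class TestCoverage:
    def test_bounds(self):
        assert coverage_fraction(0, 100).percent == 0.0
        assert coverage_fraction(100, 100) == (100.0, 100)
        with pytest.raises(ValidationError):
            coverage_fraction(5, 0)
        with pytest.raises(ValidationError):
            coverage_fraction(101, 100)

    def test_rounding_is_half_up(self):
        assert round_half_up(47.5) == 48
        assert round_half_up(47.4999) == 47
        assert coverage_fraction(955, 2000).rounded == 48  # 47.75 -> 48
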