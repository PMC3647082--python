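import numpy as np
import pytest
from scipy import stats

from comigratlas.digestion import DigestionParams, count_observable_peptides
from comigratlas.errors import ValidationError
from comigratlas.profiling import build_profiles, detect_peaks_all
from comigratlas.proteome_io import proteome_index
from comigratlas.quantification import empai_table
from comigratlas.synthetic_data import (
    NoiseParams,
    SyntheticComplexSpec,
    default_complex_specs,
    generate_proteome,
    ground_truth_groups,
    simulate_peptide_table,
    true_abundance_profile,
)


class TestGenerateProteome:
    def test_deterministic_under_seed(self):
        assert generate_proteome(5, (50, 60), seed=1) == generate_proteome(
            5, (50, 60), seed=1
        )
        assert generate_proteome(5, (50, 60), seed=1) != generate_proteome(
            5, (50, 60), seed=2
        )

    def test_lengths_within_range(self):
        for rec in generate_proteome(20, (50, 60), seed=3):
            assert 50 <= len(rec.sequence) <= 60

    def test_observable_coverage_of_short_proteins(self):
        """Proteins of length >= 50 almost always have at least one
        observable peptide under default instrument settings."""
        params = DigestionParams()
        total = with_observable = 0
        for seed in range(1, 101):
            for rec in generate_proteome(1, (50, 60), seed=seed):
                total += 1
                if count_observable_peptides(rec, params) >= 1:
                    with_observable += 1
        assert with_observable / total >= 0.95

    def test_bad_args(self):
        with pytest.raises(ValidationError):
            generate_proteome(0)
        with pytest.raises(ValidationError):
            generate_proteome(5, (5, 60))


class TestSimulatePeptideTable:
    def test_same_seed_identical_tables(self, bench_dataset):
        again = simulate_peptide_table(
            bench_dataset["proteome"],
            bench_dataset["specs"],
            bench_dataset["noise"],
            bench_dataset["n_slices"],
        )
        assert again == bench_dataset["table"]

    def test_no_signal_no_background_empty(self):
        proteome = generate_proteome(4, (60, 80), seed=5)
        spec = SyntheticComplexSpec(
            "c", ((proteome[0].accession, 1),), 10, 1.0, abundance=1e-9
        )
        noise = NoiseParams(background_rate=0.0, seed=5)
        # floor removes all slices of a vanishing band
        assert simulate_peptide_table(proteome, [spec], noise, 30) == []

    def test_rows_concentrated_near_apex(self):
        proteome = generate_proteome(4, (100, 150), seed=6)
        spec = SyntheticComplexSpec(
            "c", ((proteome[0].accession, 1),), 15, 1.0, abundance=1.0
        )
        noise = NoiseParams(detection_rate_k=50, background_rate=0.0, seed=6)
        rows = simulate_peptide_table(proteome, [spec], noise, 30)
        assert rows  # strong band produces identifications
        assert all(abs(r.slice_index - 15) <= 3 for r in rows)

    def test_unknown_member_rejected(self):
        proteome = generate_proteome(2, (60, 80), seed=7)
        spec = SyntheticComplexSpec("c", (("NOPE", 1),), 5, 1.0)
        with pytest.raises(ValidationError, match="NOPE"):
            simulate_peptide_table(proteome, [spec], NoiseParams(seed=7), 30)

    def test_peptides_are_true_tryptic_substrings(self, bench_dataset):
        index = bench_dataset["index"]
        for row in bench_dataset["table"][:200]:
            assert row.peptide in index[row.accession].sequence


class TestGroundTruth:
    def test_groups_from_specs(self):
        specs = [
            SyntheticComplexSpec("a", (("A", 1), ("B", 2)), 15, 1.0),
            SyntheticComplexSpec("solo", (("C", 1),), 20, 1.0),
            SyntheticComplexSpec("b", (("D", 1), ("E", 1)), 15, 1.0),
        ]
        groups = ground_truth_groups(specs)
        assert [sorted(g.members) for g in groups] == [["A", "B"], ["D", "E"]]
        assert [g.anchor_slice for g in groups] == [15, 15]  # not merged

    def test_true_abundance_profile_stoichiometry_and_floor(self):
        spec = SyntheticComplexSpec("a", (("A", 2),), 10, 1.0, abundance=1.0)
        prof = true_abundance_profile([spec], "A", n_slices=20)
        assert prof[9] == pytest.approx(2.0)  # apex, stoichiometry-weighted
        assert prof[0] == 0.0  # below the detection floor
        assert true_abundance_profile([spec], "Z", n_slices=20) == [0.0] * 20


class TestEmpaiFaithfulness:
    def test_rank_correlation_with_true_abundance(self):
        """Median Spearman correlation between instrument-visible true
        abundance and computed emPAI stays high under default noise."""
        medians = []
        for seed in range(1, 6):
            proteome = generate_proteome(30, (80, 300), seed=seed)
            specs = default_complex_specs(proteome, seed=seed)
            table = simulate_peptide_table(
                proteome, specs, NoiseParams(seed=seed), 60
            )
            profiles = build_profiles(
                empai_table(table, proteome_index(proteome), strict=False), 60
            )
            cors = []
            for spec in specs:
                for acc, _ in spec.members:
                    truth = true_abundance_profile(specs, acc, 60)
                    observed = (
                        profiles[acc].as_array()
                        if acc in profiles
                        else np.zeros(60)
                    )
                    cors.append(stats.spearmanr(truth, observed).statistic)
            medians.append(float(np.median(cors)))
        assert float(np.median(medians)) >= 0.7

    def test_hydrophobicity_penalty_depresses_empai(self):
        """Raising the hydrophobicity penalty strictly lowers the mean emPAI
        of a hydrophobic protein (reaction-centre-subunit pattern)."""
        from comigratlas.proteome_io import ProteinRecord

        hydrophobic = ProteinRecord(
            "HYD1",
            "MLLVAILGGAVVKLLIVAGFILLLAVKAVILLVAGGIKLLIAVGLLKVAILGAVLKILAVGLLVK" * 3,
            "synthetic hydrophobic membrane protein",
        )
        base = generate_proteome(6, (80, 200), seed=1)
        proteome = base + [hydrophobic]
        spec = SyntheticComplexSpec(
            "c", (("HYD1", 1), (base[0].accession, 1)), 30, 1.5, abundance=0.6
        )
        index = proteome_index(proteome)
        means = []
        for penalty in (0.0, 0.3, 0.6, 0.9):
            noise = NoiseParams(
                background_rate=0.0, hydrophobicity_penalty=penalty, seed=7
            )
            rows = empai_table(
                simulate_peptide_table(proteome, [spec], noise, 60),
                index,
                strict=False,
            )
            values = [r.empai for r in rows if r.accession == "HYD1"]
            means.append(float(np.mean(values)) if values else 0.0)
        assert means == sorted(means, reverse=True)
        assert means[0] > means[-1]


class TestPipelineRecovery:
    def test_five_complex_recovery_single_seed(self, bench_dataset):
        """Full pipeline recovers the planted complexes exactly (one seed;
        the acceptance suite sweeps twenty)."""
        results = empai_table(
            bench_dataset["table"], bench_dataset["index"], strict=False
        )
        profiles = build_profiles(results, bench_dataset["n_slices"])
        from comigratlas.comigration import group_comigrating

        found = {
            g.members
            for g in group_comigrating(detect_peaks_all(profiles), tolerance=1)
        }
        truth = {g.members for g in ground_truth_groups(bench_dataset["specs"])}
        assert found == truth
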