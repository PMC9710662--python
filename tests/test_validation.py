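import math

import numpy as np
import pytest

from concatkit.datamodel import DataMatrix, MarkerBlock, SequenceRecord
from concatkit.errors import (
    EmptyInputError,
    InsufficientDataError,
    NotAlignedError,
)
from concatkit.fixtures import FixtureSpec, generate_matrix
from concatkit.validation import (
    column_entropy,
    detect_outliers,
    find_nonoverlapping_blocks,
    pairwise_cost,
    validation_report,
)
from bruteforce import (
    bf_column_entropy,
    bf_components,
    bf_detect_outliers,
    bf_pairwise_cost,
)
from conftest import block


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", 0.0),
            ("ACGT", 2.0),
            ("AACC", 1.0),
            ("AC-G", 2.0),  # gap is a fifth counted state
            ("A?N?", 0.0),  # ambiguity and missing excluded
            ("????", 0.0),  # all-excluded column is 0 by convention
        ],
    )
    def test_known_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounded_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        column = "".join(rng.choice(list("ACGT-?N"), size=30))
        value = column_entropy(column)
        assert 0.0 <= value <= math.log2(5)
        assert value == pytest.approx(bf_column_entropy(column))


class TestPairwiseCost:
    def test_identical_sequences_cost_zero(self):
        assert pairwise_cost("ACGT", "ACGT", [1.0] * 4) == 0.0

    def test_entropy_weighted_mismatches(self):
        assert pairwise_cost("AC", "AT", [0.5, 1.0]) == pytest.approx(1.0)

    def test_missing_column_skipped(self):
        assert pairwise_cost("A?", "AT", [0.5, 1.0]) == 0.0

    def test_gap_vs_base_is_a_mismatch(self):
        assert pairwise_cost("A-", "AT", [0.5, 1.0]) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(NotAlignedError):
            pairwise_cost("ACG", "AC", [1.0] * 3)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        ent = rng.random(20)
        a = "".join(rng.choice(list("ACGT-?N"), size=20))
        b = "".join(rng.choice(list("ACGT-?N"), size=20))
        assert pairwise_cost(a, b, ent) == pairwise_cost(b, a, ent)


def _random_block(seed: int) -> MarkerBlock:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    length = int(rng.integers(4, 31))
    records = [
        SequenceRecord(
            f"S{i}",
            "".join(
                rng.choice(list("ACGT-?N"), size=length, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.03, 0.03])
            ),
        )
        for i in range(n)
    ]
    return MarkerBlock("M", records)


class TestDetectOutliers:
    def test_identical_sequences_no_outliers(self):
        b = block("M", **{f"S{i}": "ACGTACGT" for i in range(10)})
        calls = detect_outliers(b)
        assert all(c.cost == 0.0 and not c.is_outlier for c in calls)

    def test_fewer_than_four_sequences_rejected(self):
        with pytest.raises(InsufficientDataError):
            detect_outliers(block("M", A="AC", B="AC", C="AC"))

    def test_planted_outlier_recovered_across_replicates(self):
        """A uniformly re-drawn sequence among low-divergence ones is
        always flagged at coefficient 1 and always has the top cost."""
        for seed in range(20):
            spec = FixtureSpec(
                n_samples=20, n_markers=1, marker_lengths=[300],
                divergence=0.02, n_outliers=1, seed=seed,
            )
            matrix, truth = generate_matrix(spec)
            planted = truth.outliers[0][0]
            calls = detect_outliers(matrix.markers[0], iqr_coefficient=1)
            flagged = {c.sample_name for c in calls if c.is_outlier}
            assert planted in flagged
            top = max(calls, key=lambda c: c.cost)
            assert top.sample_name == planted

    @pytest.mark.parametrize("seed", range(10))
    def test_outlier_set_monotone_in_coefficient(self, seed):
        spec = FixtureSpec(
            n_samples=15, n_markers=1, marker_lengths=[120],
            divergence=0.08, n_outliers=2, seed=seed,
        )
        matrix, _ = generate_matrix(spec)
        flags = {}
        for k in (1, 5, 20):
            calls = detect_outliers(matrix.markers[0], iqr_coefficient=k)
            flags[k] = {c.sample_name for c in calls if c.is_outlier}
        assert flags[20] <= flags[5] <= flags[1]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_exactly(self, seed):
        b = _random_block(seed)
        calls = detect_outliers(b, iqr_coefficient=2.5)
        seqs = {r.sample_name: r.residues for r in b.records}
        costs, threshold, flags = bf_detect_outliers(seqs, 2.5)
        for call in calls:
            assert call.cost == pytest.approx(costs[call.sample_name], abs=1e-10)
            assert call.threshold == pytest.approx(threshold, abs=1e-10)
            assert call.is_outlier == flags[call.sample_name]


class TestNonOverlappingBlocks:
    def test_disjoint_marker_membership_splits(self):
        matrix = DataMatrix(
            [block("M1", A="ACGT", B="ACGA"), block("M2", C="GG", D="GC")]
        )
        report = find_nonoverlapping_blocks(matrix)
        assert {frozenset(c) for c in report.components} == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }

    def test_fully_sampled_matrix_is_connected(self, two_marker_matrix):
        report = find_nonoverlapping_blocks(two_marker_matrix)
        assert report.is_connected

    def test_disjoint_column_coverage_inside_one_marker(self):
        matrix = DataMatrix([block("M1", A="AC??", C="??GT")])
        report = find_nonoverlapping_blocks(matrix)
        assert report.n_components == 2

    def test_components_sorted_by_decreasing_size(self):
        matrix = DataMatrix(
            [
                block("M1", A="AC", B="AC", C="AC"),
                block("M2", X="GT", Y="GT"),
            ]
        )
        report = find_nonoverlapping_blocks(matrix)
        assert [len(c) for c in report.components] == [3, 2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(4, 21))
        samples = [f"S{i}" for i in range(n_samples)]
        membership: dict[str, dict[str, str]] = {}
        blocks = []
        for m in range(int(rng.integers(1, 4))):
            length = int(rng.integers(3, 12))
            chosen = [s for s in samples if rng.random() < 0.5]
            seqs = {
                s: "".join(
                    rng.choice(list("ACGT?"), size=length, p=[0.15] * 4 + [0.4])
                )
                for s in chosen
            }
            membership[f"M{m}"] = seqs
            blocks.append(
                MarkerBlock(
                    f"M{m}",
                    [SequenceRecord(s, q) for s, q in seqs.items()],
                )
            )
        if not blocks:
            return
        matrix = DataMatrix(blocks)
        report = find_nonoverlapping_blocks(matrix)
        expected = bf_components(membership)
        assert {frozenset(c) for c in report.components} == {
            frozenset(c) for c in expected
        }


class TestValidationReport:
    def test_clean_fixture(self):
        spec = FixtureSpec(
            n_samples=8, n_markers=2, marker_lengths=[60, 40],
            divergence=0.03, seed=1,
        )
        matrix, _ = generate_matrix(spec)
        report = validation_report(matrix)
        assert not report.has_findings
        assert report.overlap.is_connected
        assert len(report.overview) == 2

    def test_planted_defects_both_reported(self):
        spec = FixtureSpec(
            n_samples=12, n_markers=4, marker_lengths=[200, 50, 50, 50],
            divergence=0.02, n_outliers=1, split_fraction=0.25, seed=4,
        )
        matrix, truth = generate_matrix(spec)
        report = validation_report(matrix, iqr_coefficient=1)
        assert not report.overlap.is_connected
        flagged = {(c.sample_name, c.marker_name) for c in report.outliers}
        assert set(truth.outliers) <= flagged
        kinds = {r["finding"] for r in report.to_records()}
        assert {"outlier_sequence", "nonoverlapping_block"} <= kinds
        assert "WARNING" in report.to_text()

    def test_small_markers_skipped_with_notice(self):
        matrix = DataMatrix([block("tiny", A="AC", B="AC")])
        report = validation_report(matrix)
        assert report.skipped_markers == ["tiny"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyInputError):
            validation_report(DataMatrix([]))
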