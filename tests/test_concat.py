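import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concatkit.concat import (
    apply_display_names,
    codon_subsets,
    concatenate,
    deconcatenate,
)
from concatkit.datamodel import (
    CharSet,
    ConcatenatedAlignment,
    DataMatrix,
    SequenceRecord,
    reorder_markers,
)
from concatkit.errors import (
    EmptyInputError,
    NameCollisionError,
    NotAlignedError,
    PartitionError,
)
from bruteforce import bf_codon_columns
from conftest import block, random_fixture


class TestConcatenate:
    def test_worked_example(self, two_marker_matrix):
        aln = concatenate(two_marker_matrix)
        assert aln.length == 8
        assert aln.sample_names == ["A", "B", "C"]
        by_name = {r.sample_name: r.residues for r in aln.records}
        assert by_name["A"] == "ACGTA???"
        assert by_name["B"] == "AC-TAGGT"
        assert by_name["C"] == "?????GCT"
        assert aln.charsets == [CharSet("M1", 1, 5), CharSet("M2", 6, 8)]

    def test_single_marker_identity(self):
        aln = concatenate(DataMatrix([block("M", A="ACGT", B="AC-T")]))
        assert aln.charsets == [CharSet("M", 1, 4)]
        assert [r.residues for r in aln.records] == ["ACGT", "AC-T"]

    def test_ragged_marker_is_hard_error(self):
        matrix = DataMatrix([block("M", A="A" * 300, B="A" * 299)])
        with pytest.raises(NotAlignedError, match="M"):
            concatenate(matrix)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyInputError):
            concatenate(DataMatrix([]))

    def test_alternate_fill_char(self, two_marker_matrix):
        aln = concatenate(two_marker_matrix, fill_char="N")
        assert aln.records[0].residues == "ACGTANNN"

    def test_sorted_sample_order(self, two_marker_matrix):
        aln = concatenate(
            reorder_markers(two_marker_matrix, ["M2", "M1"]), sort_samples=True
        )
        assert aln.sample_names == ["A", "B", "C"]

    @pytest.mark.parametrize("seed", range(8))
    def test_length_and_padding_conservation(self, seed):
        matrix = random_fixture(seed)
        aln = concatenate(matrix)
        assert aln.length == sum(b.length for b in matrix)
        present = {
            b.marker_name: set(b.sample_names) for b in matrix
        }
        for rec in aln.records:
            expected_fill = sum(
                b.length
                for b in matrix
                if rec.sample_name not in present[b.marker_name]
            )
            assert rec.residues.count("?") == expected_fill

    def test_reorder_permutes_segments_consistently(self):
        matrix = random_fixture(5, missing_fraction=0.3)
        order = list(reversed(matrix.marker_names))
        aln_a = concatenate(matrix)
        aln_b = concatenate(reorder_markers(matrix, order))
        slices_a = {
            cs.name: {
                r.sample_name: r.residues[cs.start - 1 : cs.end]
                for r in aln_a.records
            }
            for cs in aln_a.charsets
        }
        slices_b = {
            cs.name: {
                r.sample_name: r.residues[cs.start - 1 : cs.end]
                for r in aln_b.records
            }
            for cs in aln_b.charsets
        }
        assert slices_a == slices_b


class TestDeconcatenate:
    def test_inverse_of_concatenate(self, two_marker_matrix):
        aln = concatenate(two_marker_matrix)
        assert deconcatenate(aln) == two_marker_matrix

    @pytest.mark.parametrize("seed", range(8))
    def test_inverse_on_sparse_fixtures(self, seed):
        matrix = random_fixture(seed, missing_fraction=0.6)
        assert deconcatenate(concatenate(matrix)) == DataMatrix(matrix.markers)

    def test_keep_empty_rows(self, two_marker_matrix):
        matrix = deconcatenate(concatenate(two_marker_matrix), drop_empty=False)
        assert all(b.sample_names == ["A", "B", "C"] for b in matrix)
        assert matrix.get_marker("M2").get("A").residues == "???"

    def test_non_tiling_charsets_rejected(self):
        records = [SequenceRecord("A", "ACGTACGT")]
        with pytest.raises(PartitionError):
            ConcatenatedAlignment(
                records, [CharSet("M1", 1, 5), CharSet("M2", 7, 8)]
            )


class TestCodonSubsets:
    def test_frame_1_even_length(self):
        sets = codon_subsets("M1", CharSet("M1", 1, 6), 1)
        assert [(c.name, c.start, c.end, c.step) for c in sets] == [
            ("M1_pos1", 1, 6, 3),
            ("M1_pos2", 2, 6, 3),
            ("M1_pos3", 3, 6, 3),
        ]
        assert [c.size for c in sets] == [2, 2, 2]

    def test_frame_2_wraps(self):
        sets = codon_subsets("M1", CharSet("M1", 1, 6), 2)
        starts = {c.name: c.start for c in sets}
        assert starts == {"M1_pos1": 2, "M1_pos2": 3, "M1_pos3": 1}
        oracle = bf_codon_columns(1, 6, 2)
        for k in (1, 2, 3):
            assert set(sets[k - 1].columns) == oracle[k]

    def test_length_not_divisible_by_three(self):
        sets = codon_subsets("M", CharSet("M", 10, 16), 1)
        assert sorted(c.size for c in sets) == [2, 2, 3]
        columns = [set(c.columns) for c in sets]
        assert set.union(*columns) == set(range(10, 17))
        assert sum(len(c) for c in columns) == 7

    def test_marker_narrower_than_a_codon_rejected(self):
        with pytest.raises(PartitionError):
            codon_subsets("M", CharSet("M", 1, 2), 1)

    @settings(derandomize=True, max_examples=200)
    @given(
        start=st.integers(1, 500),
        length=st.integers(3, 90),
        frame=st.integers(1, 3),
    )
    def test_partitions_marker_columns_exactly(self, start, length, frame):
        end = start + length - 1
        sets = codon_subsets("M", CharSet("M", start, end), frame)
        oracle = bf_codon_columns(start, end, frame)
        for k in (1, 2, 3):
            assert set(sets[k - 1].columns) == oracle[k]


class TestDisplayNames:
    def test_mapped_and_unmapped(self, two_marker_matrix):
        aln = apply_display_names(
            concatenate(two_marker_matrix), {"A": "ZSM123_Boophis"}
        )
        assert aln.sample_names == ["ZSM123_Boophis", "B", "C"]

    def test_empty_map_is_identity(self, two_marker_matrix):
        aln = concatenate(two_marker_matrix)
        assert apply_display_names(aln, {}) == aln

    def test_collision_rejected(self, two_marker_matrix):
        aln = concatenate(two_marker_matrix)
        with pytest.raises(NameCollisionError):
            apply_display_names(aln, {"A": "X", "B": "X"})
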