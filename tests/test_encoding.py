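"""Column encoding, alignment projection and coordinate bookkeeping."""

import io
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpseg.encoding import (
    ALPHABET,
    AMBIG,
    GAP,
    AlignmentBlock,
    EncodedSequence,
    ThreeWayAlignment,
    complement_column,
    concatenate,
    encode_alignment,
    encode_column,
    extract_threeway,
    read_fasta_alignment,
    read_maf,
)


class TestEncodeColumn:
    @pytest.mark.parametrize(
        "column, symbol",
        [
            (("G", "A", "T"), "n"),  # the worked example
            (("C", "T", "A"), "n"),  # its strand complement
            (("A", "A", "A"), "a"),
            (("C", "C", "C"), "v"),
            (("T", "T", "T"), "a"),
            (("G", "G", "G"), "v"),
        ],
    )
    def test_known_columns(self, column, symbol):
        assert encode_column(column) == symbol

    def test_case_insensitive(self):
        assert encode_column(("g", "a", "t")) == "n"

    @pytest.mark.parametrize(
        "column", [("A", "-", "A"), ("-", "C", "G"), ("A", "C", "-")]
    )
    def test_gap_columns_excluded(self, column):
        assert encode_column(column) is GAP

    @pytest.mark.parametrize("column", [("N", "A", "A"), ("A", "R", "C")])
    def test_ambiguity_codes(self, column):
        assert encode_column(column) is AMBIG

    def test_invalid_base_raises_with_position(self):
        with pytest.raises(ValueError, match="position 1"):
            encode_column(("A", "?", "C"))

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            encode_column(("A", "C"))

    def test_exhaustive_enumeration(self):
        """All 64 ungapped triples map onto exactly 32 symbols, two each."""
        hits = {}
        for col in product("ACGT", repeat=3):
            hits.setdefault(encode_column(col), []).append(col)
        assert set(hits) == set(ALPHABET)
        assert all(len(cols) == 2 for cols in hits.values())
        for sym, cols in hits.items():
            assert complement_column(cols[0]) == cols[1]

    def test_strand_symmetry(self):
        for col in product("ACGT", repeat=3):
            assert encode_column(col) == encode_column(complement_column(col))


def _simple_alignment(rows, start=0, chrom="chr1"):
    return ThreeWayAlignment(
        blocks=[AlignmentBlock(ref_chrom=chrom, ref_start=start, rows=rows)]
    )


class TestEncodeAlignment:
    def test_continuous_ungapped(self):
        aln = _simple_alignment(("ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAC"))
        seq = encode_alignment(aln)
        assert len(seq.symbols) == 10
        assert "#" not in seq.symbols
        assert seq.gap_before.sum() == 0
        assert list(seq.pos) == list(range(10))

    def test_species_deletion_recorded(self):
        aln = _simple_alignment(("ACGTACGT", "AC---CGT", "ACGTACGT"))
        seq = encode_alignment(aln)
        assert len(seq.symbols) == 5
        # three skipped columns land on the position after the gap run
        assert seq.gap_before[2] == 3
        assert seq.n_columns_accounted == 8
        # deleted columns still consume reference coordinates
        assert list(seq.pos) == [0, 1, 5, 6, 7]

    def test_reference_gap_consumes_no_coordinate(self):
        aln = _simple_alignment(("AC--GT", "ACGTGT", "ACTTGT"))
        seq = encode_alignment(aln)
        assert list(seq.pos) == [0, 1, 2, 3]
        assert seq.gap_before[2] == 2

    def test_discontinuous_blocks_joined_by_hash(self):
        aln = ThreeWayAlignment(
            blocks=[
                AlignmentBlock("chr1", 0, ("ACG", "ACG", "ACG")),
                AlignmentBlock("chr1", 50, ("TTT", "TTT", "TTT")),
            ]
        )
        seq = encode_alignment(aln)
        assert seq.symbols.count("#") == 1
        assert seq.symbols[3] == "#"
        assert list(seq.pos) == [0, 1, 2, -1, 50, 51, 52]

    def test_all_gap_columns_dropped(self):
        aln = _simple_alignment(("AC---GT", "AC---GT", "AC---GT"))
        seq = encode_alignment(aln)
        assert len(seq.symbols) == 4
        assert seq.n_allgap_cols == 3
        assert seq.gap_before.sum() == 0

    def test_round_trip_accounting(self, small_truth):
        seq = encode_alignment(small_truth.alignment)
        assert seq.n_columns_accounted == small_truth.alignment.n_columns

    def test_coord_map_matches_column_walk(self):
        rows = ("AC-TA-GT", "ACGT--GT", "AC---CGT")
        aln = _simple_alignment(rows, start=10)
        seq = encode_alignment(aln)
        # brute-force column walk over the reference row
        expected = []
        refpos = 10
        for k in range(len(rows[0])):
            col = tuple(r[k] for r in rows)
            if "-" not in col:
                expected.append(refpos)
            if col[0] != "-":
                refpos += 1
        assert list(seq.pos) == expected

    def test_soft_mask_exclusion_switch(self):
        aln = _simple_alignment(("ACgT", "ACGT", "ACGT"))
        default = encode_alignment(aln)
        excluded = encode_alignment(aln, exclude_soft_masked=True)
        assert len(default.symbols) == 4
        assert len(excluded.symbols) == 3
        assert excluded.ambig_before.sum() == 1


class TestEncodedSequenceInvariants:
    def test_hash_placement_rules(self):
        with pytest.raises(ValueError):
            EncodedSequence(
                symbols="#ab",
                chrom_names=["c"],
                chrom_idx=np.array([-1, 0, 0], dtype=np.int32),
                pos=np.array([-1, 0, 1]),
                gap_before=np.zeros(3, dtype=np.int32),
                ambig_before=np.zeros(3, dtype=np.int32),
            )

    def test_negative_ledger_rejected(self):
        with pytest.raises(ValueError):
            EncodedSequence(
                symbols="ab",
                chrom_names=["c"],
                chrom_idx=np.zeros(2, dtype=np.int32),
                pos=np.arange(2),
                gap_before=np.array([0, -1], dtype=np.int32),
                ambig_before=np.zeros(2, dtype=np.int32),
            )

    def test_model_input_marks_hash_boundaries(self):
        aln = ThreeWayAlignment(
            blocks=[
                AlignmentBlock("chr1", 0, ("ACG", "ACG", "ACG")),
                AlignmentBlock("chr1", 50, ("TTT", "TTT", "TTT")),
            ]
        )
        sym, fixed, keep = encode_alignment(aln).model_input()
        assert len(sym) == 6
        assert list(np.flatnonzero(fixed)) == [2]


class TestConcatenate:
    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate([])

    def test_identity(self, small_encoded):
        assert concatenate([small_encoded]) is small_encoded

    def test_join_lengths_and_hash(self):
        a = encode_alignment(_simple_alignment(("ACGT", "ACGT", "ACGT"), chrom="g1"))
        b = encode_alignment(_simple_alignment(("TTAA", "TTAA", "TTAA"), chrom="g2"))
        joined = concatenate([a, b])
        assert len(joined.symbols) == 9
        assert joined.symbols[4] == "#"
        # each constituent keeps its own chromosome and coordinates
        assert joined.chrom_names == ["g1", "g2"]
        assert list(joined.pos[:4]) == [0, 1, 2, 3]
        assert list(joined.pos[5:]) == [0, 1, 2, 3]

    def test_accounting_preserved(self):
        a = encode_alignment(_simple_alignment(("AC-T", "ACGT", "ACGT")))
        b = encode_alignment(_simple_alignment(("GGNG", "GGGG", "GGGG")))
        joined = concatenate([a, b])
        assert joined.n_columns_accounted == 8


class TestExtractThreeway:
    def test_projection_and_strand(self, maf_text):
        blocks = read_maf(io.StringIO(maf_text))
        aln = extract_threeway(blocks, ("danRer7", "mm9", "hg19"))
        # block 2 lacks hg19 and is dropped
        assert len(aln.blocks) == 2
        first = aln.blocks[0]
        assert (first.ref_chrom, first.ref_start) == ("chr1", 100)
        # every emitted column has all three species
        assert all(len(b.rows) == 3 for b in aln.blocks)
        # '-'-strand reference block flipped to forward coordinates
        second = aln.blocks[1]
        assert second.ref_start == 1000 - 300 - 4
        assert second.rows[0] == "GGTT"

    def test_unknown_species_errors_with_available(self, maf_text):
        blocks = read_maf(io.StringIO(maf_text))
        with pytest.raises(ValueError, match="danRer7"):
            extract_threeway(blocks, ("danRer7", "mm9", "nosuch"))

    def test_empty_maf_gives_empty_alignment(self):
        aln = extract_threeway([], ("a", "b", "c"))
        assert aln.blocks == []


class TestFastaReader:
    def test_three_records(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(">zf chr9\nAC-GT\n>mm\nACGGT\n>hs\nACTGT\n")
        aln = read_fasta_alignment(str(p))
        assert len(aln.blocks) == 1
        assert aln.blocks[0].rows[0] == "AC-GT"

    def test_wrong_record_count(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nACGT\n>b\nACGT\n")
        with pytest.raises(ValueError, match="3 aligned records"):
            read_fasta_alignment(str(p))


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_round_trip_accounting_property(data):
    """Symbols + ledger entries + ambiguous + all-gap = total columns."""
    n = data.draw(st.integers(5, 40))
    letters = "ACGT-N"
    rows = tuple(
        "".join(data.draw(st.sampled_from(letters)) for _ in range(n))
        for _ in range(3)
    )
    aln = ThreeWayAlignment(blocks=[AlignmentBlock("chr1", 0, rows)])
    seq = encode_alignment(aln)
    assert seq.n_columns_accounted == n
    # coordinates strictly increase within the single block
    kept = seq.pos[seq.pos >= 0]
    assert np.all(np.diff(kept) > 0)
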