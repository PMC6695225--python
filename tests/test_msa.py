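"""Alignment reading, integer encoding, reordering and windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rawmsa.msa import (
    DEFAULT_VOCABULARY,
    EncodedMSA,
    RawAlignment,
    encode_msa,
    extract_windows,
    flatten_a3m,
    read_alignment,
    reorder_sequences,
)

VOCAB_SYMBOLS = "ACDEFGHIKLMNPQRSTVWYBUZX-"


def write_fasta(tmp_path, seqs, name="aln.fasta"):
    path = tmp_path / name
    path.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
    return path


class TestVocabulary:
    def test_bijection_onto_1_to_25(self):
        indices = sorted(DEFAULT_VOCABULARY.symbol_to_index.values())
        assert indices == list(range(1, 26))

    def test_round_trip_over_all_symbols(self):
        encoded = DEFAULT_VOCABULARY.encode(VOCAB_SYMBOLS)
        assert DEFAULT_VOCABULARY.decode(encoded) == VOCAB_SYMBOLS

    def test_zero_never_assigned(self):
        assert 0 not in DEFAULT_VOCABULARY.symbol_to_index.values()

    @pytest.mark.parametrize("letter", ["J", "O", "*"])
    def test_letters_outside_vocabulary_collapse_to_x(self, letter):
        assert DEFAULT_VOCABULARY.index(letter) == DEFAULT_VOCABULARY.symbol_to_index["X"]


class TestReadAlignment:
    def test_flat_fasta_parses_in_file_order(self, tmp_path):
        path = write_fasta(tmp_path, ["ACDEFGHI", "ACDEFGH-", "-CDEFGHI"])
        aln = read_alignment(path)
        assert aln.n_sequences == 3
        assert aln.length == 8
        assert aln.master == "ACDEFGHI"

    def test_ragged_alignment_rejected(self, tmp_path):
        path = write_fasta(tmp_path, ["ACDEFGHI", "ACDEFGH"])
        with pytest.raises(ValueError, match="ragged"):
            read_alignment(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_alignment(path)

    def test_illegal_characters_rejected(self, tmp_path):
        path = write_fasta(tmp_path, ["AC1D"])
        with pytest.raises(ValueError, match="illegal"):
            read_alignment(path)

    def test_lowercase_uppercased_in_flat_fasta(self, tmp_path):
        # flat FASTA is case-insensitive; lowercase only means insertion in a3m
        path = write_fasta(tmp_path, ["acd", "a-d"])
        aln = read_alignment(path)
        assert aln.sequences == ["ACD", "A-D"]

    def test_master_gap_columns_removed(self, tmp_path):
        path = write_fasta(tmp_path, ["AC-D", "AGGD"])
        aln = read_alignment(path)
        assert aln.master == "ACD"
        assert aln.sequences[1] == "AGD"


class TestFlattenA3m:
    def test_lowercase_insertions_deleted(self):
        aln = flatten_a3m(["ACD", "A-Dg"])
        assert aln.sequences == ["ACD", "A-D"]

    def test_no_lowercase_is_identity(self):
        aln = flatten_a3m(["ACD", "AC-"])
        assert aln.sequences == ["ACD", "AC-"]

    def test_length_mismatch_after_flattening_rejected(self):
        with pytest.raises(ValueError, match="length"):
            flatten_a3m(["ACD", "Ag"])


class TestEncodeMsa:
    def test_stated_mapping(self):
        aln = RawAlignment(["ACD", "A-D"])
        msa = encode_msa(aln, depth_cap=2)
        assert msa.values.tolist() == [[1, 2, 3], [1, 25, 3]]

    def test_zero_padding_rows_below_real_sequences(self):
        msa = encode_msa(RawAlignment(["ACD", "A-D"]), depth_cap=4)
        assert msa.values.shape == (4, 3)
        assert (msa.values[2:] == 0).all()
        assert (msa.values[:2] > 0).all()

    def test_unknown_letter_collapses_to_x(self):
        msa = encode_msa(RawAlignment(["AJD"]), depth_cap=1)
        assert msa.values[0].tolist() == [1, 24, 3]

    def test_depth_cap_truncates(self):
        aln = RawAlignment(["AA", "CC", "DD"])
        msa = encode_msa(aln, depth_cap=2)
        assert msa.values.shape == (2, 2)
        assert msa.n_sequences == 3

    def test_invalid_depth_cap(self):
        with pytest.raises(ValueError):
            encode_msa(RawAlignment(["AA"]), depth_cap=0)

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet=VOCAB_SYMBOLS[:-1], min_size=1, max_size=40))
    def test_padding_neutrality(self, seq):
        # residues always encode to integers > 0, never colliding with padding
        assert (DEFAULT_VOCABULARY.encode(seq) > 0).all()


class TestReorderSequences:
    def make_aln(self):
        return RawAlignment(["AAA", "YYY", "AAA"])

    def test_native_is_identity(self):
        aln = self.make_aln()
        assert reorder_sequences(aln, "native") is aln

    def test_blosum62_sort_by_descending_score(self):
        # sum of BLOSUM62 diagonal entries: AAA vs AAA = 3*4 = 12,
        # YYY vs AAA = 3*(-2) = -6, so AAA sorts before YYY
        out = reorder_sequences(self.make_aln(), "blosum62_sort")
        assert out.sequences == ["AAA", "AAA", "YYY"]

    def test_shuffle_deterministic_per_seed(self):
        aln = RawAlignment(["AAA"] + [c * 3 for c in "CDEFGHIK"])
        a = reorder_sequences(aln, "shuffle", seed=7)
        b = reorder_sequences(aln, "shuffle", seed=7)
        assert a.sequences == b.sequences

    def test_master_stays_first_in_all_modes(self):
        aln = RawAlignment(["WWW", "AAA", "YYY", "CCC"])
        for mode in ("native", "blosum62_sort", "shuffle"):
            out = reorder_sequences(aln, mode, seed=3)
            assert out.sequences[0] == "WWW"

    def test_permutation_preserves_multiset(self):
        aln = RawAlignment(["AAA", "CCC", "YYY", "CCC"])
        for mode in ("blosum62_sort", "shuffle"):
            out = reorder_sequences(aln, mode, seed=11)
            assert sorted(out.sequences[1:]) == sorted(aln.sequences[1:])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            reorder_sequences(self.make_aln(), "alphabetical")

    def test_encoded_msa_reorder_keeps_padding_rows(self):
        msa = encode_msa(RawAlignment(["AAA", "CCC", "DDD"]), depth_cap=5)
        out = reorder_sequences(msa, "shuffle", seed=1)
        assert (out.values[3:] == 0).all()
        assert out.values[0].tolist() == msa.values[0].tolist()


class TestExtractWindows:
    def test_one_window_per_master_residue(self, rng):
        for _ in range(50):
            length = int(rng.integers(1, 80))
            depth = int(rng.integers(1, 10))
            values = rng.integers(1, 26, size=(depth, length))
            windows = extract_windows(EncodedMSA(values, depth), width=31)
            assert len(windows) == length

    def test_terminal_windows_zero_padded(self):
        values = np.arange(1, 4).reshape(1, 3)
        windows = extract_windows(EncodedMSA(values, 1), width=31)
        assert (windows[0].values[:, :15] == 0).all()
        assert (windows[-1].values[:, 16:] == 0).all()

    def test_center_column_matches_master(self, rng):
        values = rng.integers(1, 26, size=(4, 37))
        windows = extract_windows(EncodedMSA(values, 4), width=31)
        for i, w in enumerate(windows):
            assert w.values[0, 15] == values[0, i]
            assert w.center == i

    def test_window_tiling_reconstructs_master_row(self, rng):
        values = rng.integers(1, 26, size=(3, 50))
        windows = extract_windows(EncodedMSA(values, 3), width=31)
        centers = [w.values[:, 15] for w in windows]
        assert np.array_equal(np.stack(centers, axis=1), values)

    def test_even_width_rejected(self):
        msa = EncodedMSA(np.ones((2, 5), dtype=int), 2)
        with pytest.raises(ValueError):
            extract_windows(msa, width=30)
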