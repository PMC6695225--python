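"""DSSP parsing, SS reduction, RSA normalization and contact maps."""

import numpy as np
import pytest

from rawmsa.labels import (
    THEORETICAL_MAX_ASA,
    classify_rsa,
    compute_rsa,
    contact_map_from_coords,
    labels_from_dssp,
    long_range_pairs,
    parse_dssp,
    read_rr,
    reduce_ss8_to_ss3,
    representative_atom_coords,
    write_rr,
)


class TestParseDssp:
    def test_basic_rows(self, dssp_file):
        path = dssp_file([(1, "A", "M", "H", 100), (2, "A", "K", "E", 50)])
        records = parse_dssp(path)
        assert len(records) == 2
        assert records[0].ss8 == "H"
        assert records[0].asa == 100
        assert records[1].residue == "K"
        assert records[1].chain == "A"

    def test_chain_break_rows_skipped(self, dssp_file):
        path = dssp_file([(1, "A", "M", "H", 100), (0, " ", "!", " ", 0), (2, "B", "K", "E", 50)])
        records = parse_dssp(path)
        assert [r.residue for r in records] == ["M", "K"]

    def test_blank_structure_reported_as_coil(self, dssp_file):
        path = dssp_file([(1, "A", "G", " ", 30)])
        assert parse_dssp(path)[0].ss8 == "C"

    def test_file_without_header_rejected(self, tmp_path):
        path = tmp_path / "bad.dssp"
        path.write_text("not a dssp file\n")
        with pytest.raises(ValueError, match="data section"):
            parse_dssp(path)


class TestSs8Reduction:
    @pytest.mark.parametrize(
        "ss8,ss3",
        [("H", "H"), ("G", "H"), ("I", "H"), ("E", "E"), ("B", "E"),
         ("S", "C"), ("T", "C"), ("C", "C"), (" ", "C")],
    )
    def test_mapping(self, ss8, ss3):
        assert reduce_ss8_to_ss3(ss8) == ss3

    def test_surjective_onto_hec(self):
        assert {reduce_ss8_to_ss3(s) for s in "GHIEBSTC"} == {"H", "E", "C"}

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            reduce_ss8_to_ss3("Q")


class TestRsa:
    def test_ratio_and_clipping(self):
        assert compute_rsa(THEORETICAL_MAX_ASA["A"], "A") == 1.0
        assert compute_rsa(0.0, "A") == 0.0
        assert compute_rsa(2 * THEORETICAL_MAX_ASA["G"], "G") == 1.0

    def test_unknown_residue_rejected(self):
        with pytest.raises(KeyError):
            compute_rsa(10.0, "Z")

    @pytest.mark.parametrize(
        "rsa,scheme,expected",
        [
            (0.04, "four", "Buried"),              # right-closed first interval
            (0.05, "four", "PartiallyBuried"),
            (0.25, "four", "PartiallyBuried"),
            (0.30, "four", "PartiallyAccessible"),
            (0.50, "four", "PartiallyAccessible"),
            (0.51, "four", "Accessible"),
            (0.25, "two", "Buried"),
            (0.26, "two", "Accessible"),
        ],
    )
    def test_class_boundaries(self, rsa, scheme, expected):
        assert classify_rsa(rsa, scheme) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_rsa(1.5)

    def test_classification_partitions_all_inputs(self, rng):
        # every valid rsa gets exactly one class in each scheme
        for rsa in rng.random(200):
            assert classify_rsa(rsa, "four") in (
                "Buried", "PartiallyBuried", "PartiallyAccessible", "Accessible"
            )
            assert classify_rsa(rsa, "two") in ("Buried", "Accessible")

    def test_labels_from_dssp_consistency(self, dssp_file):
        path = dssp_file([(1, "A", "A", "H", 129), (2, "A", "G", "E", 2), (3, "A", "K", "T", 80)])
        labels = labels_from_dssp(parse_dssp(path))
        assert labels.ss3.tolist() == ["H", "E", "C"]
        assert labels.rsa[0] == 1.0
        assert labels.rsa4[1] == "Buried"
        for frac, c4, c2 in zip(labels.rsa, labels.rsa4, labels.rsa2):
            assert classify_rsa(frac, "four") == c4
            assert classify_rsa(frac, "two") == c2


class TestContactMap:
    def test_strict_8A_boundary(self):
        coords = np.array([[0.0, 0, 0], [7.99, 0, 0], [7.99 + 8.0, 0, 0]])
        cmap = contact_map_from_coords(coords)
        assert cmap.values[0, 1] == 1  # 7.99 Å: contact
        assert cmap.values[1, 2] == 0  # exactly 8.00 Å: non-contact

    def test_symmetric_and_rigid_motion_invariant(self, rng):
        coords = rng.normal(scale=8.0, size=(30, 3))
        cmap = contact_map_from_coords(coords)
        assert np.array_equal(cmap.values, cmap.values.T)
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        moved = coords @ q.T + np.array([5.0, -3.0, 11.0])
        assert np.array_equal(contact_map_from_coords(moved).values, cmap.values)

    def test_missing_coordinates_masked(self):
        coords = np.array([[0.0, 0, 0], [np.nan, np.nan, np.nan], [3.0, 0, 0]])
        cmap = contact_map_from_coords(coords)
        assert not cmap.mask[1]
        assert (cmap.values[1, :] == 0).all()
        assert cmap.values[0, 2] == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            contact_map_from_coords(np.full((3, 3), np.nan))

    def test_gly_uses_ca_as_representative_atom(self, pdb_file):
        # GLY has no CB; its CA must be picked, ALA uses CB
        path = pdb_file(
            [
                ("ALA", "A", 1, {"CA": (0, 0, 0), "CB": (1, 0, 0)}),
                ("GLY", "A", 2, {"CA": (5, 0, 0)}),
            ]
        )
        coords, codes = representative_atom_coords(path)
        assert codes == ["A", "G"]
        assert coords[0].tolist() == [1, 0, 0]  # ALA CB
        assert coords[1].tolist() == [5, 0, 0]  # GLY CA


class TestLongRangePairs:
    def test_boundary_separation(self):
        pairs = long_range_pairs(30)
        assert (1, 25) in pairs   # separation 24: long range
        assert (1, 24) not in pairs  # separation 23: excluded

    def test_count_matches_brute_force(self):
        for length in (24, 25, 30, 41):
            expected = {
                (i, j)
                for i in range(1, length + 1)
                for j in range(1, length + 1)
                if i < j and j - i > 23
            }
            assert long_range_pairs(length) == expected
        assert len(long_range_pairs(30)) == 21
        assert long_range_pairs(24) == set()


class TestRrRoundTrip:
    def test_write_then_read(self, tmp_path, rng):
        probs = rng.random((30, 30))
        probs = (probs + probs.T) / 2
        path = tmp_path / "pred.rr"
        write_rr(probs, path)
        first = path.read_text().splitlines()[0].split()
        assert first[2:4] == ["0", "8"]
        back = read_rr(path, 30)
        off_diag = ~np.eye(30, dtype=bool)
        assert np.allclose(back[off_diag], probs[off_diag], atol=1e-6)
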