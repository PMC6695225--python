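import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dssp_text(rows):
    """Build a DSSP-format text from (resnum, chain, aa, ss8, acc) tuples.

    Only the fixed columns the parser reads are populated: serial [0:5],
    residue number [5:10], chain [11], amino acid [13], structure [16],
    accessible area [34:38].
    """
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE ...",
        "HEADER ...",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N",
    ]
    for serial, (resnum, chain, aa, ss8, acc) in enumerate(rows, start=1):
        line = [" "] * 50
        line[0:5] = f"{serial:5d}"
        if aa != "!":
            line[5:10] = f"{resnum:5d}"
            line[11] = chain
        line[13] = aa
        line[16] = ss8
        line[34:38] = f"{acc:4d}" if aa != "!" else "   0"
        lines.append("".join(line))
    return "\n".join(lines) + "\n"


def make_pdb_text(residues):
    """Build minimal PDB ATOM records from (resname, chain, resseq, atoms)
    where atoms maps atom name -> (x, y, z)."""
    lines = []
    serial = 1
    element = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for resname, chain, resseq, atoms in residues:
        for name, (x, y, z) in atoms.items():
            lines.append(
                f"ATOM  {serial:5d}  {name:<4s}{resname:>3s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{20.0:6.2f}          "
                f"{element.get(name, 'C'):>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def dssp_file(tmp_path):
    def _write(rows, name="test.dssp"):
        path = tmp_path / name
        path.write_text(make_dssp_text(rows))
        return path

    return _write


@pytest.fixture
def pdb_file(tmp_path):
    def _write(residues, name="test.pdb"):
        path = tmp_path / name
        path.write_text(make_pdb_text(residues))
        return path

    return _write
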