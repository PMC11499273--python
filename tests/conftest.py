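import numpy as np
import pytest

from foldspace.genotypes import LibraryDefinition, SubstitutionEffect


@pytest.fixture
def small_library():
    """4-substitution library over a 6-residue wild type, with nt sequence."""
    wt_aa = "MPGKLT"
    #         M  P  G  K  L  T
    wt_nt = "ATGCCTGGTAAACTTACT"
    subs = [
        SubstitutionEffect(position=2, wt_aa="P", mut_aa="A", ddg_f=0.5),
        SubstitutionEffect(position=3, wt_aa="G", mut_aa="C", ddg_f=1.2),
        SubstitutionEffect(position=4, wt_aa="K", mut_aa="N", ddg_f=-0.2),
        SubstitutionEffect(position=6, wt_aa="T", mut_aa="S", ddg_f=0.1),
    ]
    return LibraryDefinition(wt_aa_seq=wt_aa, wt_nt_seq=wt_nt, substitutions=subs)


def _pdb_atom(serial, name, resname, resseq, x, y, z, element):
    return (f"ATOM  {serial:5d} {name:<4s}{resname:<3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def make_pdb(path, residues):
    """Write a minimal single-chain PDB file.

    ``residues``: list of (resname, resseq, [(atom_name, element, (x, y, z)), ...]).
    """
    lines = []
    serial = 1
    for resname, resseq, atoms in residues:
        for name, element, (x, y, z) in atoms:
            lines.append(_pdb_atom(serial, name, resname, resseq, x, y, z, element))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_structure(tmp_path):
    """Three residues with known side-chain coordinates (plus a glycine).

    Residue 1 (ALA): CB at origin. Residue 2 (SER): CB at (3,4,0) and OG at
    (6,0,0). Residue 3 (GLY): backbone only, CA at (0,0,10).
    """
    coords = {
        1: [("N", "N", (-1.0, 0.0, 0.0)), ("CA", "C", (-0.5, 0.0, 0.0)),
            ("C", "C", (-1.5, 1.0, 0.0)), ("O", "O", (-2.5, 1.0, 0.0)),
            ("CB", "C", (0.0, 0.0, 0.0))],
        2: [("N", "N", (2.0, 4.0, 0.0)), ("CA", "C", (2.5, 4.0, 0.0)),
            ("C", "C", (1.5, 5.0, 0.0)), ("O", "O", (0.5, 5.0, 0.0)),
            ("CB", "C", (3.0, 4.0, 0.0)), ("OG", "O", (6.0, 0.0, 0.0))],
        3: [("N", "N", (-1.0, 0.0, 10.0)), ("CA", "C", (0.0, 0.0, 10.0)),
            ("C", "C", (1.0, 0.0, 10.0)), ("O", "O", (2.0, 0.0, 10.0))],
    }
    path = make_pdb(tmp_path / "toy.pdb", [
        ("ALA", 1, coords[1]), ("SER", 2, coords[2]), ("GLY", 3, coords[3])])
    return path, coords
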