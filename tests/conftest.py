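from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles

from oildrop.structure_io import ResidueRecord, StructureModel


def make_residue(chain, seq, xyz, hydro=0.5, aa="ALA", icode="", atoms=None):
    xyz = np.asarray(xyz, dtype=float)
    return ResidueRecord(
        chain_id=chain,
        seq_number=seq,
        insertion_code=icode,
        aa_type=aa,
        effective_atom=xyz,
        intrinsic_hydrophobicity=hydro,
        atom_coords=np.asarray(atoms, dtype=float) if atoms is not None else xyz.reshape(1, 3),
    )


def make_unit(coords, hydro=None, chain="A", start=1):
    coords = np.asarray(coords, dtype=float)
    if hydro is None:
        hydro = np.full(len(coords), 0.5)
    return [
        make_residue(chain, start + i, c, h) for i, (c, h) in enumerate(zip(coords, hydro))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_ala_pdb(tmp_path) -> Path:
    """Three complete alanines at hand-placed coordinates."""
    lines = []
    serial = 1
    atom_sets = [
        # residue 1: atoms around (0,0,0)
        [("N", 0.0, 0.0, 0.0), ("CA", 1.0, 0.0, 0.0), ("C", 1.0, 1.0, 0.0),
         ("O", 0.0, 1.0, 0.0), ("CB", 0.5, 0.5, 1.0)],
        # residue 2: shifted by 5 on x
        [("N", 5.0, 0.0, 0.0), ("CA", 6.0, 0.0, 0.0), ("C", 6.0, 1.0, 0.0),
         ("O", 5.0, 1.0, 0.0), ("CB", 5.5, 0.5, 1.0)],
        # residue 3: shifted by 10 on x
        [("N", 10.0, 0.0, 0.0), ("CA", 11.0, 0.0, 0.0), ("C", 11.0, 1.0, 0.0),
         ("O", 10.0, 1.0, 0.0), ("CB", 10.5, 0.5, 1.0)],
    ]
    for resseq, atoms in enumerate(atom_sets, start=1):
        for name, x, y, z in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]:>2s}\n"
            )
            serial += 1
    lines.append("END\n")
    path = tmp_path / "three_ala.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def gly_tetrahedron_pdb(tmp_path) -> Path:
    """One glycine whose 4 heavy atoms form a regular tetrahedron centered at origin."""
    s = 2.0
    verts = [(s, s, s), (s, -s, -s), (-s, s, -s), (-s, -s, s)]
    lines = []
    for i, (name, (x, y, z)) in enumerate(zip(("N", "CA", "C", "O"), verts), start=1):
        lines.append(
            f"ATOM  {i:5d}  {name:<3s} GLY A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]:>2s}\n"
        )
    lines.append("END\n")
    path = tmp_path / "gly_tet.pdb"
    path.write_text("".join(lines))
    return path
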