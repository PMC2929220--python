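"""Shared fixtures: small synthetic sequences and a toy PDB structure.

All fixtures are generated in code; nothing here is derived from real
database records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from alphafam.seqio import ProteinSequence

REAL_DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "accessions"


def require_real_data(*filenames: str) -> list[Path]:
    """Resolve user-supplied accession-derived input files, or fail.

    The repository ships no sequence or structure data downloaded from
    GenBank/RefSeq/PDB; reproducing the published numbers requires the
    user to place the accession-derived files under ``data/accessions/``
    (see README).  Absent files fail the calling test explicitly rather
    than skipping, so the reproduction status is always visible.
    """
    paths = [REAL_DATA_DIR / name for name in filenames]
    missing = [p.name for p in paths if not p.exists()]
    if missing:
        pytest.fail(
            "accession-derived input(s) not available: "
            + ", ".join(missing)
            + f" (expected under {REAL_DATA_DIR}); these files must be "
            "retrieved from GenBank/RefSeq/PDB by the user — see README, "
            "section 'Reproducing the published numbers'.",
            pytrace=False,
        )
    return paths


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20100811)


@pytest.fixture
def small_family() -> list[ProteinSequence]:
    return [
        ProteinSequence(id="s1", residues="MKVLATGHEWQRN"),
        ProteinSequence(id="s2", residues="MKVLTTGHEWQRN"),
        ProteinSequence(id="s3", residues="MKVATGHQWQRN"),
        ProteinSequence(id="s4", residues="MRVLATGHEWKRN"),
    ]


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z,
              occupancy=1.0, altloc=" ", element=None) -> str:
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def toy_pdb(tmp_path) -> Path:
    """Synthetic two-chain receptor/peptide structure.

    Chain A: three alanines with CB atoms at x = 0, 10, 20.  Chain B: one
    lysine whose CB sits 3.5 A from A/1's CB.  Includes a water and an
    altLoc pair (B conformer has higher occupancy) to exercise filtering.
    """
    lines = [
        _pdb_atom(1, "N", "ALA", "A", 1, 0.0, 1.4, 0.0),
        _pdb_atom(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        _pdb_atom(3, "CB", "ALA", "A", 1, 0.0, 0.0, 1.5),
        _pdb_atom(4, "CA", "ALA", "A", 2, 10.0, 0.0, 0.0),
        _pdb_atom(5, "CB", "ALA", "A", 2, 10.0, 0.0, 1.5, occupancy=0.4, altloc="A"),
        _pdb_atom(6, "CB", "ALA", "A", 2, 10.0, 0.0, 1.6, occupancy=0.6, altloc="B"),
        _pdb_atom(7, "CA", "ALA", "A", 3, 20.0, 0.0, 0.0),
        _pdb_atom(8, "CB", "ALA", "A", 3, 20.0, 0.0, 1.5),
        "TER",
        _pdb_atom(9, "CA", "LYS", "B", 1, 3.5, 0.0, 0.0),
        _pdb_atom(10, "CB", "LYS", "B", 1, 3.5, 0.0, 1.5),
        "TER",
        "HETATM   11  O   HOH A 101      1.000   1.000   1.000  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
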