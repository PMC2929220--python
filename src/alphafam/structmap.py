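"""Structure-contact detection and cross-paralog conservation mapping.

Given a receptor–peptide co-crystal structure (e.g. an importin α bound
to an NLS peptide), receptor residues contacting the peptide are found by
a heavy-atom distance cutoff, mapped through a pairwise alignment onto a
family alignment, and classified per column as identical, conserved
(within one strong similarity group) or different across the paralogs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .align import GAP, Msa, PairwiseAlignment, ScoringScheme, global_align, percent_identity
from .seqio import ProteinSequence, Structure

# Strong residue-similarity groups (as used for ClustalW ':' columns).
STRONG_GROUPS = (
    frozenset("STA"),
    frozenset("NEQK"),
    frozenset("NHQK"),
    frozenset("NDEQ"),
    frozenset("QHRK"),
    frozenset("MILV"),
    frozenset("MILF"),
    frozenset("HY"),
    frozenset("FYW"),
)

DEFAULT_CONTACT_CUTOFF = 4.0  # Å, heavy-atom


@dataclass(frozen=True)
class ContactResidue:
    chain_id: str
    author_number: int
    residue_name: str
    min_distance: float
    n_atom_pairs: int


def _heavy_coords(residues):
    """Coordinates of non-hydrogen atoms with their residue index."""
    coords, owner = [], []
    for k, res in enumerate(residues):
        for atom in res.atoms:
            if atom.element in ("H", "D"):
                continue
            coords.append((atom.x, atom.y, atom.z))
            owner.append(k)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def find_contacts(
    s: Structure,
    receptor_chain: str,
    ligand_chain: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[ContactResidue]:
    """Receptor residues with a heavy atom within ``cutoff`` Å of the ligand.

    Sorted by author residue number; hydrogens (and waters, which the
    structure reader already drops) are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    for chain in (receptor_chain, ligand_chain):
        if chain not in s.chains:
            raise KeyError(f"no chain {chain!r} in structure {s.id}")
    rec = s.chains[receptor_chain]
    rc, rowner = _heavy_coords(rec)
    lc, _ = _heavy_coords(s.chains[ligand_chain])
    if rc.size == 0 or lc.size == 0:
        return []
    # All-pairs distances; structures here are small enough that the
    # O(N·M) scan is cheap and needs no spatial index.
    dists = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2)
    per_atom_min = dists.min(axis=1)
    per_atom_hits = (dists <= cutoff).sum(axis=1)
    out = []
    for k, res in enumerate(rec):
        mask = rowner == k
        if not mask.any():
            continue
        n_pairs = int(per_atom_hits[mask].sum())
        if n_pairs >= 1:
            out.append(
                ContactResidue(
                    chain_id=receptor_chain,
                    author_number=res.author_number,
                    residue_name=res.residue_name,
                    min_distance=float(per_atom_min[mask].min()),
                    n_atom_pairs=n_pairs,
                )
            )
    return sorted(out, key=lambda c: c.author_number)


def detect_chains(s: Structure) -> tuple[str, str]:
    """(receptor, ligand) chain ids as the longest and shortest chains."""
    if len(s.chains) < 2:
        raise ValueError("structure has fewer than 2 chains")
    ordered = sorted(s.chains, key=lambda c: (-len(s.chains[c]), c))
    return ordered[0], ordered[-1]


def read_contact_tsv(path) -> list[tuple[str, int]]:
    """Read an explicit contact list: ``chain<TAB>resnum`` rows."""
    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out.append((row[0], int(row[1])))
    if not out:
        raise ValueError(f"{path}: no contact rows")
    return out


MIN_MAPPING_IDENTITY = 50.0  # percent, structure-vs-member guard


def map_structure_to_family(
    s_seq: ProteinSequence,
    msa: Msa,
    member_id: str,
    scheme: ScoringScheme | None = None,
) -> dict[int, int]:
    """Map structure residue positions (1-based) to family MSA columns.

    The structure chain's sequence is globally aligned to the named family
    member, and that pairwise alignment is composed with the member's
    residue-to-column map.  An identity below 50% aborts: the structure
    does not correspond to that member.
    """
    member_row = msa.row(member_id)
    member_seq = ProteinSequence(id=member_id, residues=member_row.replace(GAP, ""))
    aln = global_align(s_seq, member_seq, scheme)
    identity = percent_identity(aln, "aligned_columns")
    if identity < MIN_MAPPING_IDENTITY:
        raise ValueError(
            f"structure/sequence mismatch: {s_seq.id} vs {member_id} "
            f"identity {identity:.1f}% < {MIN_MAPPING_IDENTITY:.0f}%"
        )
    mapping: dict[int, int] = {}
    pos_s = pos_m = 0
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x != GAP:
            pos_s += 1
        if y != GAP:
            pos_m += 1
        if x != GAP and y != GAP:
            mapping[pos_s] = msa.column_of(member_id, pos_m)
    return mapping


def correspond(msa: Msa, from_id: str, from_pos: int) -> dict[str, tuple[str, int | None]]:
    """Residues of every row at the column holding a reference position.

    Returns ``{row_id: (residue_letter_or_'-', 1-based_position_or_None)}``
    for the column containing residue ``from_pos`` (1-based, ungapped) of
    ``from_id``.
    """
    col = msa.column_of(from_id, from_pos)
    out = {}
    for sid in msa.ids:
        residue = msa.row(sid)[col]
        out[sid] = (residue, msa.position_at(sid, col))
    return out


@dataclass(frozen=True)
class ConservationRecord:
    msa_column: int
    residues: tuple[tuple[str, str, int | None], ...]  # (id, residue, position)
    conservation_class: str  # identical | conserved | different | gapped


@dataclass(frozen=True)
class ConservationSummary:
    n_identical: int
    n_conserved: int
    n_different: int

    @property
    def n_total(self) -> int:
        return self.n_identical + self.n_conserved + self.n_different


def classify_column(column: str) -> str:
    """Conservation class of one alignment column.

    ``identical``: one residue type among the non-gap rows; ``conserved``:
    all non-gap residues fall in one strong similarity group;
    ``different`` otherwise; ``gapped`` when every row is a gap.
    """
    residues = {c for c in column if c != GAP}
    if not residues:
        return "gapped"
    if len(residues) == 1:
        return "identical"
    if any(residues <= group for group in STRONG_GROUPS):
        return "conserved"
    return "different"


def classify_conservation(
    msa: Msa, columns
) -> tuple[list[ConservationRecord], ConservationSummary]:
    """Classify columns and summarise identical/conserved/different counts."""
    cols = sorted(set(columns))
    if not cols:
        raise ValueError("empty column list")
    records = []
    counts = {"identical": 0, "conserved": 0, "different": 0, "gapped": 0}
    for j in cols:
        column = msa.column(j)
        klass = classify_column(column)
        counts[klass] += 1
        records.append(
            ConservationRecord(
                msa_column=j,
                residues=tuple(
                    (sid, msa.row(sid)[j], msa.position_at(sid, j))
                    for sid in msa.ids
                ),
                conservation_class=klass,
            )
        )
    summary = ConservationSummary(
        n_identical=counts["identical"],
        n_conserved=counts["conserved"],
        n_different=counts["different"],
    )
    return records, summary


def majority_identity_mask(msa: Msa, threshold: int) -> list[bool]:
    """Per-column flag: modal residue (gaps excluded) occurs >= threshold times."""
    if threshold > msa.n_rows:
        raise ValueError("threshold exceeds number of rows")
    mask = []
    for j in range(msa.length):
        counts: dict[str, int] = {}
        for c in msa.column(j):
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        mask.append(bool(counts) and max(counts.values()) >= threshold)
    return mask
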