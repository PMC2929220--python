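"""Sequence and structure input/output.

Reading and writing of the external formats the pipeline touches: FASTA
(protein and nucleotide), GenBank flat files (CDS extraction only), and
PDB structures.  Coding sequences are translated with the standard genetic
code.  Residue numbering is 1-based inclusive everywhere user-facing;
internal indices are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
_NT_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence.

    ``numbering_origin`` is the author number of the first residue, so
    residue *k* of the chain carries user-facing number
    ``numbering_origin + k - 1`` (1-based).
    """

    id: str
    residues: str
    description: str = ""
    numbering_origin: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )
        if "X" in self.residues:
            warnings.warn(
                f"sequence {self.id!r} contains ambiguous residues (X)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.residues


@dataclass(frozen=True)
class NucleotideSequence:
    """An ungapped DNA sequence over {A, C, G, T, N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float
    element: str


@dataclass(frozen=True)
class StructResidue:
    author_number: int
    insertion_code: str
    residue_name: str
    atoms: tuple[Atom, ...]


@dataclass
class Structure:
    """A parsed macromolecular structure (polymer ATOM records only)."""

    id: str
    chains: dict[str, list[StructResidue]] = field(default_factory=dict)

    def chain_sequence(self, chain_id: str) -> ProteinSequence:
        """One-letter sequence of a chain, in record order."""
        residues = self.chains[chain_id]
        letters = "".join(
            seq1(r.residue_name, undef_code="X") for r in residues
        )
        return ProteinSequence(
            id=f"{self.id}_{chain_id}",
            residues=letters.upper(),
            numbering_origin=residues[0].author_number,
        )


def _looks_like_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= _NT_ALPHABET


def read_fasta(path, kind: str = "auto"):
    """Read a FASTA file into Protein- or NucleotideSequence records.

    Parameters
    ----------
    path : path-like
    kind : {"auto", "protein", "nucleotide"}
        With "auto", a record whose letters all fall in {A,C,G,T,N} is
        treated as DNA, anything else as protein.

    Order follows the file; duplicate ids raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        desc = rec.description[len(rec.id):].strip()
        if kind == "nucleotide" or (kind == "auto" and _looks_like_dna(seq)):
            out.append(NucleotideSequence(id=rec.id, residues=seq, description=desc))
        else:
            out.append(ProteinSequence(id=rec.id, residues=seq, description=desc))
    return out


def write_fasta(records: Iterable[ProteinSequence | NucleotideSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_genbank_cds(path) -> NucleotideSequence:
    """Extract the (first) CDS feature of a GenBank flat file as DNA.

    Only the CDS interval of the record sequence is returned; all other
    annotation is ignored.
    """
    rec = next(SeqIO.parse(str(path), "genbank"), None)
    if rec is None:
        raise FormatError(f"{path}: no GenBank record found")
    for feature in rec.features:
        if feature.type == "CDS":
            seq = str(feature.extract(rec.seq)).upper()
            return NucleotideSequence(id=rec.id, residues=seq)
    raise FormatError(f"{path}: record {rec.id} has no CDS feature")


_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)


def translate_cds(seq: NucleotideSequence, orf_start: int = 0) -> ProteinSequence:
    """Translate an ATG-initiated open reading frame.

    ``orf_start`` is the 0-based offset of the initiator ATG.  Translation
    uses the standard genetic code and stops at the first in-frame stop
    codon (not included).  A missing ATG or a missing in-frame stop raises
    :class:`FormatError`.
    """
    region = seq.residues[orf_start:]
    if len(region) < 6:
        raise FormatError(f"{seq.id}: ORF at {orf_start} shorter than 6 nt")
    if region[:3] != "ATG":
        raise FormatError(
            f"{seq.id}: no ATG at offset {orf_start} (found {region[:3]!r})"
        )
    protein = []
    for i in range(0, len(region) - 2, 3):
        codon = region[i : i + 3]
        if codon in _STOP_CODONS:
            return ProteinSequence(
                id=seq.id,
                residues="".join(protein),
                description=f"translated ORF at offset {orf_start}",
            )
        protein.append(_CODON_TABLE.get(codon, "X"))
    raise FormatError(f"{seq.id}: ORF at {orf_start} has no in-frame stop codon")


def find_longest_orf(seq: NucleotideSequence) -> int:
    """0-based offset of the longest ATG-initiated, stop-terminated ORF.

    The forward strand only is scanned.  Ties favour the earlier start.
    """
    best_start, best_len = -1, 0
    n = len(seq.residues)
    for start in range(n - 5):
        if seq.residues[start : start + 3] != "ATG":
            continue
        for i in range(start, n - 2, 3):
            if seq.residues[i : i + 3] in _STOP_CODONS:
                orf_len = i - start
                if orf_len > best_len:
                    best_start, best_len = start, orf_len
                break
    if best_start < 0:
        raise FormatError(f"{seq.id}: no complete ATG-initiated ORF found")
    return best_start


def read_structure(path) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only ATOM records of standard amino-acid residues are kept; waters and
    hetero-residues are dropped.  Alternate locations are resolved to the
    highest-occupancy conformer (Biopython's default; ties keep the first).
    """
    parser = PDBParser(QUIET=True)
    try:
        model = next(parser.get_structure(Path(path).stem, str(path)).get_models())
    except (ValueError, StopIteration) as exc:
        raise FormatError(f"{path}: unparseable PDB file ({exc})") from exc
    structure = Structure(id=Path(path).stem)
    for chain in model:
        residues: list[StructResidue] = []
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip() or not is_aa(res, standard=True):
                continue
            atoms = tuple(
                Atom(
                    name=a.get_name(),
                    x=float(a.coord[0]),
                    y=float(a.coord[1]),
                    z=float(a.coord[2]),
                    element=(a.element or "").upper(),
                )
                for a in res.get_atoms()
            )
            residues.append(
                StructResidue(
                    author_number=int(resseq),
                    insertion_code=icode.strip(),
                    residue_name=res.get_resname(),
                    atoms=atoms,
                )
            )
        if residues:
            structure.chains[chain.id] = residues
    if not structure.chains:
        raise FormatError(f"{path}: no standard protein residues found")
    return structure
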