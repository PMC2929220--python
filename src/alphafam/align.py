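"""Global pairwise and progressive multiple protein alignment.

The pairwise stage is a Needleman–Wunsch/Gotoh global aligner with affine
gap penalties (a gap of length L costs ``gap_open + gap_extend * L``).  The
multiple aligner is a classical progressive scheme: all-pairs global
alignments give p-distances, a neighbor-joining guide tree orders
profile–profile merges, and profiles are aligned with the same affine-gap
DP over average substitution scores.  Percent identity supports the three
common denominator conventions, since published identity matrices rarely
state which one was used.

Traceback ties are broken deterministically: residue–residue first, then
gap in the first sequence, then gap in the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqio import AMINO_ACIDS, ProteinSequence

GAP = "-"
IdentityConvention = Literal["aligned_columns", "shorter_seq", "ungapped_columns"]

_EPS = 1e-9


def _blosum62_array() -> tuple[np.ndarray, dict[str, int]]:
    """BLOSUM62 restricted to the 20 canonical residues plus X."""
    bl = substitution_matrices.load("BLOSUM62")
    letters = AMINO_ACIDS + "X"
    idx = {c: i for i, c in enumerate(letters)}
    mat = np.zeros((len(letters), len(letters)))
    for a in letters:
        for b in letters:
            mat[idx[a], idx[b]] = bl[a, b]
    return mat, idx


_B62, _B62_INDEX = _blosum62_array()


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    Defaults emulate ClustalW-style protein settings: BLOSUM62 with gap
    open 10 and gap extension 0.5 (both costs, i.e. subtracted).
    """

    matrix: np.ndarray = field(default_factory=lambda: _B62.copy())
    index: dict[str, int] = field(default_factory=lambda: dict(_B62_INDEX))
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative costs")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def encode(self, residues: str) -> np.ndarray:
        try:
            return np.fromiter(
                (self.index[c] for c in residues), dtype=np.intp, count=len(residues)
            )
        except KeyError as exc:
            raise ValueError(f"non-amino-acid character {exc.args[0]!r}") from None

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])


@dataclass(frozen=True)
class PairwiseAlignment:
    a_id: str
    b_id: str
    a_aligned: str
    b_aligned: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings must have equal length")
        if any(
            x == GAP and y == GAP for x, y in zip(self.a_aligned, self.b_aligned)
        ):
            raise ValueError("alignment contains a column of two gaps")

    def __len__(self) -> int:
        return len(self.a_aligned)


# DP states, in traceback priority order (substitution > gap in a > gap in b).
_M, _GA, _GB = 0, 1, 2


def _gotoh_matrices(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three Gotoh matrices for a precomputed column-score matrix.

    ``S[i, j]`` scores pairing row element i with column element j.  Returns
    (M, X, Y): best score ending in substitution, gap-in-column-seq
    (vertical) and gap-in-row-seq (horizontal) respectively.
    """
    m, n = S.shape
    NEG = -np.inf
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # consumes rows: gap in the second seq
    Y = np.full((m + 1, n + 1), NEG)  # consumes cols: gap in the first seq
    M[0, 0] = 0.0
    X[1:, 0] = -(gap_open + gap_extend * np.arange(1, m + 1))
    Y[0, 1:] = -(gap_open + gap_extend * np.arange(1, n + 1))
    go_ge = gap_open + gap_extend
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Y[i - 1, 1:]) - go_ge,
            X[i - 1, 1:] - gap_extend,
        )
        X[i, 0] = -(gap_open + gap_extend * i)
        # Horizontal pass: Y[i, j] = max_{k<j} (best(M,X)[i, k] - open - ext*(j-k))
        B = np.maximum(M[i, :-1], X[i, :-1]) + gap_extend * np.arange(n)
        run = np.maximum.accumulate(B)
        Y[i, 1:] = run - gap_open - gap_extend * np.arange(1, n + 1)
    return M, X, Y


def _traceback(M, X, Y, gap_open, gap_extend, S):
    """Recover one optimal path as a list of ops: 'M', 'X' (gap col), 'Y' (gap row)."""
    m, n = S.shape
    go_ge = gap_open + gap_extend
    i, j = m, n
    finals = (M[m, n], Y[m, n], X[m, n])  # priority: M, gap-in-a (Y), gap-in-b (X)
    best = max(finals)
    state = "MYX"[int(np.argmax([f >= best - _EPS for f in finals]))]
    # argmax over booleans returns the first True, honouring the priority order
    ops: list[str] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            choices = (M[i, j], Y[i, j], X[i, j])
            state = "MYX"[int(np.argmax([abs(c - target) <= _EPS for c in choices]))]
        elif state == "Y":
            target = Y[i, j]
            j -= 1
            if j >= 0 and abs(M[i, j] - go_ge - target) <= _EPS:
                state = "M"
            elif abs(Y[i, j] - gap_extend - target) <= _EPS:
                state = "Y"
            else:
                state = "X"
        else:  # X
            target = X[i, j]
            i -= 1
            if abs(M[i, j] - go_ge - target) <= _EPS:
                state = "M"
            elif abs(Y[i, j] - go_ge - target) <= _EPS:
                state = "Y"
            else:
                state = "X"
    ops.reverse()
    return ops


def global_align(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences (Gotoh, affine gaps).

    The score is the maximum over all global alignments; terminal gaps are
    penalised like internal ones.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    ea, eb = scheme.encode(a.residues), scheme.encode(b.residues)
    S = scheme.matrix[np.ix_(ea, eb)]
    M, X, Y = _gotoh_matrices(S, scheme.gap_open, scheme.gap_extend)
    score = float(max(M[-1, -1], X[-1, -1], Y[-1, -1]))
    ops = _traceback(M, X, Y, scheme.gap_open, scheme.gap_extend, S)
    a_out, b_out = [], []
    ia = ib = 0
    for op in ops:
        if op == "M":
            a_out.append(a.residues[ia])
            b_out.append(b.residues[ib])
            ia += 1
            ib += 1
        elif op == "X":  # gap in b
            a_out.append(a.residues[ia])
            b_out.append(GAP)
            ia += 1
        else:  # gap in a
            a_out.append(GAP)
            b_out.append(b.residues[ib])
            ib += 1
    return PairwiseAlignment(
        a_id=a.id, b_id=b.id,
        a_aligned="".join(a_out), b_aligned="".join(b_out),
        score=score,
    )


def percent_identity(
    aln: PairwiseAlignment, convention: IdentityConvention = "aligned_columns"
) -> float:
    """Percent identity of a pairwise alignment under a stated convention.

    - ``aligned_columns`` (default): identical columns / columns with at
      least one residue (a gap against a residue counts as a difference).
    - ``shorter_seq``: identical columns / length of the shorter sequence.
    - ``ungapped_columns``: identical columns / columns where both rows
      have residues.
    """
    pairs = list(zip(aln.a_aligned, aln.b_aligned))
    identical = sum(1 for x, y in pairs if x == y and x != GAP)
    if convention == "aligned_columns":
        denom = len(pairs)
    elif convention == "shorter_seq":
        denom = min(
            len(aln.a_aligned.replace(GAP, "")), len(aln.b_aligned.replace(GAP, ""))
        )
    elif convention == "ungapped_columns":
        denom = sum(1 for x, y in pairs if x != GAP and y != GAP)
    else:
        raise ValueError(f"unknown identity convention {convention!r}")
    if denom == 0:
        raise ValueError("identity denominator is zero")
    return 100.0 * identical / denom


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows.

    Provides the column <-> residue coordinate maps used throughout the
    pipeline (1-based residue positions, 0-based columns).
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in MSA")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if self.seqs and any(
            all(s[j] == GAP for s in self.seqs) for j in range(len(self.seqs[0]))
        ):
            raise ValueError("MSA contains an all-gap column")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row(self, seq_id: str) -> str:
        return self.seqs[self.index(seq_id)]

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"no row {seq_id!r} in MSA") from None

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column_of(self, seq_id: str, pos: int) -> int:
        """0-based column holding 1-based ungapped position ``pos`` of a row."""
        row = self.row(seq_id)
        if pos < 1:
            raise IndexError(f"position {pos} out of range (1-based)")
        count = 0
        for j, c in enumerate(row):
            if c != GAP:
                count += 1
                if count == pos:
                    return j
        raise IndexError(
            f"position {pos} out of range for {seq_id!r} "
            f"(ungapped length {count})"
        )

    def position_at(self, seq_id: str, column: int) -> int | None:
        """1-based ungapped position of a row at a column, or None on a gap."""
        row = self.row(seq_id)
        if not 0 <= column < len(row):
            raise IndexError(f"column {column} out of range")
        if row[column] == GAP:
            return None
        return len(row[: column + 1].replace(GAP, ""))

    def to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        )

    @classmethod
    def from_biopython(cls, aln: MultipleSeqAlignment) -> "Msa":
        return cls(ids=[r.id for r in aln], seqs=[str(r.seq).upper() for r in aln])


def read_alignment(path, fmt: str | None = None) -> Msa:
    """Read an alignment in Clustal ``.aln`` or aligned-FASTA format."""
    if fmt is None:
        fmt = "clustal" if str(path).endswith(".aln") else "fasta"
    return Msa.from_biopython(AlignIO.read(str(path), fmt))


def write_alignment(msa: Msa, path, fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "clustal" if str(path).endswith(".aln") else "fasta"
    AlignIO.write(msa.to_biopython(), str(path), fmt)


@dataclass(frozen=True)
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def pair_from_msa(msa: Msa, a_id: str, b_id: str) -> PairwiseAlignment:
    """Project two MSA rows onto the columns where not both are gaps."""
    ra, rb = msa.row(a_id), msa.row(b_id)
    cols = [(x, y) for x, y in zip(ra, rb) if not (x == GAP and y == GAP)]
    if not cols:
        raise ValueError(f"rows {a_id!r}/{b_id!r} share no non-gap columns")
    return PairwiseAlignment(
        a_id=a_id, b_id=b_id,
        a_aligned="".join(x for x, _ in cols),
        b_aligned="".join(y for _, y in cols),
        score=float("nan"),
    )


def identity_matrix(
    msa: Msa, convention: IdentityConvention = "aligned_columns"
) -> IdentityMatrix:
    """All-pairs percent identity of MSA rows (pairwise gap projection)."""
    if msa.n_rows < 2:
        raise ValueError("identity matrix needs at least 2 rows")
    n = msa.n_rows
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(
                pair_from_msa(msa, msa.ids[i], msa.ids[j]), convention
            )
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(labels=list(msa.ids), values=values)


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _pairwise_p_distance(aln: PairwiseAlignment) -> float:
    both = [
        (x, y)
        for x, y in zip(aln.a_aligned, aln.b_aligned)
        if x != GAP and y != GAP
    ]
    if not both:
        return 1.0
    return sum(1 for x, y in both if x != y) / len(both)


class _Profile:
    """A sub-alignment during progressive merging: rows keyed by input index."""

    def __init__(self, rows: dict[int, str], scheme: ScoringScheme):
        self.rows = rows
        self.scheme = scheme

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def frequencies(self) -> np.ndarray:
        """(length, n_symbols) residue frequency matrix; gaps contribute 0."""
        k = self.scheme.matrix.shape[0]
        freq = np.zeros((self.length, k))
        for row in self.rows.values():
            for j, c in enumerate(row):
                if c != GAP:
                    freq[j, self.scheme.index[c]] += 1.0
        return freq / len(self.rows)

    def insert_gaps(self, ops: Sequence[str], consume: str) -> dict[int, str]:
        out = {i: [] for i in self.rows}
        pos = 0
        for op in ops:
            if op == "M" or op == consume:
                for i, row in self.rows.items():
                    out[i].append(row[pos])
                pos += 1
            else:
                for i in out:
                    out[i].append(GAP)
        return {i: "".join(chars) for i, chars in out.items()}


def _merge_profiles(pa: _Profile, pb: _Profile, scheme: ScoringScheme) -> _Profile:
    S = pa.frequencies() @ scheme.matrix @ pb.frequencies().T
    M, X, Y = _gotoh_matrices(S, scheme.gap_open, scheme.gap_extend)
    ops = _traceback(M, X, Y, scheme.gap_open, scheme.gap_extend, S)
    rows = {}
    rows.update(pa.insert_gaps(ops, consume="X"))
    rows.update(pb.insert_gaps(ops, consume="Y"))
    return _Profile(rows, scheme)


def progressive_align(
    seqs: Sequence[ProteinSequence], scheme: ScoringScheme | None = None
) -> Msa:
    """Progressive multiple alignment with an NJ guide tree.

    All-pairs Gotoh alignments give p-distances; a neighbor-joining guide
    tree (midpoint-rooted) orders profile–profile merges in post-order.
    Output rows keep the input order.  Note this is a classical progressive
    scheme, not a reimplementation of any particular aligner's heuristics.
    """
    scheme = scheme or ScoringScheme()
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], scheme)
        return Msa(ids=list(ids), seqs=[aln.a_aligned, aln.b_aligned])

    # Guide tree from NJ on pairwise p-distances (deferred import: phylo
    # depends on evodist which needs Msa from this module).
    from .evodist import DistanceMatrix
    from .phylo import neighbor_joining

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pairwise_p_distance(
                global_align(seqs[i], seqs[j], scheme)
            )
    guide = neighbor_joining(DistanceMatrix(labels=list(ids), values=D))
    # Merge in post-order from the NJ seed trifurcation; children are
    # ordered by smallest input index for determinism.
    tree = guide.tree

    profiles: dict[int, _Profile] = {}
    index_of = {sid: k for k, sid in enumerate(ids)}

    def leaf_key(node):
        return min(lf.taxon.label for lf in node.leaf_iter())

    def build(node) -> _Profile:
        children = node.child_nodes()
        if not children:
            k = index_of[node.taxon.label]
            return _Profile({k: seqs[k].residues}, scheme)
        parts = sorted((build(c) for c in children),
                       key=lambda p: min(p.rows))
        merged = parts[0]
        for nxt in parts[1:]:
            merged = _merge_profiles(merged, nxt, scheme)
        return merged

    profile = build(tree.seed_node)
    rows = profile.rows
    return Msa(ids=list(ids), seqs=[rows[k] for k in range(n)])
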