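"""Domain annotation and per-domain divergence analysis.

Domains (e.g. the importin-β binding domain and the armadillo-repeat
body) are given as 1-based inclusive intervals on an ungapped reference
sequence.  Intervals are projected onto alignment columns, the alignment
is sliced per domain, and divergence from a designated outgroup is
measured as the root-to-leaf path length on a neighbor-joining tree of
that domain slice — so a fast-evolving domain shows a longer path from
the common ancestor than a conserved one.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import pandas as pd

from .align import GAP, Msa
from .evodist import SubstitutionModel, distance_matrix
from .phylo import neighbor_joining, path_length, root_at


@dataclass(frozen=True)
class DomainMap:
    """Named, non-overlapping intervals on an ungapped reference sequence."""

    reference_id: str
    entries: tuple[tuple[str, int, int], ...]  # (name, start, end), 1-based incl.

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate domain names")
        for name, start, end in self.entries:
            if not 1 <= start <= end:
                raise ValueError(f"domain {name!r}: invalid interval ({start}, {end})")
        spans = sorted((s, e, n) for n, s, e in self.entries)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"domains {n1!r} and {n2!r} overlap")

    def interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.entries:
            if n == name:
                return s, e
        raise KeyError(f"no domain named {name!r}")

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.entries]


def read_domain_tsv(path) -> DomainMap:
    """Read ``reference_id<TAB>domain<TAB>start<TAB>end`` rows."""
    entries = []
    reference = None
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            ref, name, start, end = row[:4]
            if reference is None:
                reference = ref
            elif ref != reference:
                raise ValueError(
                    f"{path}: mixed reference ids ({reference!r}, {ref!r})"
                )
            entries.append((name, int(start), int(end)))
    if reference is None:
        raise ValueError(f"{path}: no domain rows")
    return DomainMap(reference_id=reference, entries=tuple(entries))


def write_domain_tsv(dmap: DomainMap, path) -> None:
    with open(path, "w") as fh:
        for name, start, end in dmap.entries:
            fh.write(f"{dmap.reference_id}\t{name}\t{start}\t{end}\n")


def domain_columns(msa: Msa, dmap: DomainMap, name: str) -> list[int]:
    """Alignment columns spanned by a domain interval of the reference row.

    The span runs from the column of the interval's first residue to the
    column of its last; reference-gap columns inside the span belong to
    the region and are included.  Returned sorted ascending.
    """
    start, end = dmap.interval(name)
    first = msa.column_of(dmap.reference_id, start)
    last = msa.column_of(dmap.reference_id, end)
    return list(range(first, last + 1))


def slice_msa(msa: Msa, columns) -> Msa:
    """Restrict an alignment to a set of columns (row order preserved)."""
    cols = sorted(set(columns))
    if not cols:
        raise ValueError("empty column set")
    if cols[0] < 0 or cols[-1] >= msa.length:
        raise IndexError(f"column out of range (length {msa.length})")
    seqs = ["".join(s[j] for j in cols) for s in msa.seqs]
    for sid, s in zip(msa.ids, seqs):
        if set(s) == {GAP}:
            warnings.warn(f"row {sid!r} is all gaps in the slice", stacklevel=2)
    return Msa(ids=list(msa.ids), seqs=seqs)


@dataclass(frozen=True)
class DomainDivergenceTable:
    """Long-format (taxon, domain, divergence-from-outgroup) rows."""

    rows: tuple[tuple[str, str, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["taxon", "domain", "divergence"])

    def value(self, taxon: str, domain: str) -> float:
        for t, d, v in self.rows:
            if t == taxon and d == domain:
                return v
        raise KeyError(f"no row ({taxon!r}, {domain!r})")


MIN_DOMAIN_COLUMNS = 10


def domain_divergence(
    msa: Msa,
    dmap: DomainMap,
    domains: list[str],
    model: SubstitutionModel,
    outgroup: str,
    clamp_negative: bool = True,
) -> DomainDivergenceTable:
    """Per-domain divergence of every taxon from the outgroup.

    For each domain: slice the alignment, estimate ML distances, build an
    NJ tree, root it on the outgroup, and report the outgroup-to-leaf
    path length.  Negative NJ branch lengths are clamped by default so
    divergences are non-negative.
    """
    msa.index(outgroup)
    rows = []
    for name in domains:
        cols = domain_columns(msa, dmap, name)
        if len(cols) < MIN_DOMAIN_COLUMNS:
            raise ValueError(
                f"domain {name!r} yields only {len(cols)} columns "
                f"(minimum {MIN_DOMAIN_COLUMNS})"
            )
        sliced = slice_msa(msa, cols)
        D = distance_matrix(sliced, model)
        tree = root_at(
            neighbor_joining(D, clamp_negative=clamp_negative), outgroup
        )
        for taxon in msa.ids:
            if taxon == outgroup:
                continue
            rows.append((taxon, name, path_length(tree, outgroup, taxon)))
    return DomainDivergenceTable(rows=tuple(rows))
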