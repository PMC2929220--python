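# Methods

This note documents the models, defaults and design choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Pairwise and progressive alignment

Global alignment is Needleman–Wunsch with Gotoh's three-state affine-gap
recursion. A gap of length L costs `gap_open + gap_extend · L`; terminal
gaps are penalised like internal ones. Defaults are BLOSUM62 with
`gap_open = 10`, `gap_extend = 0.5` — ClustalW-like protein settings, but
this is *not* a reimplementation of ClustalW (no Gonnet series, no
position-specific penalties, no iterative refinement). Published identity
values computed with ClustalW are therefore expected to be reproduced
only approximately (±1.5 percentage points is the tolerance used in the
acceptance tests); ingesting a curated Clustal `.aln` file is the exact
path. Traceback ties are resolved deterministically: substitution, then
gap in the first sequence, then gap in the second.

The multiple aligner is classical progressive alignment: all-pairs global
alignments give p-distances, neighbor joining on those distances gives
the guide tree, and profiles are merged in post-order from the NJ seed
node (children ordered by smallest input index, so results are
reproducible). Profile–profile column scores are the frequency-weighted
average substitution score; gap symbols contribute zero. The guide tree
is deliberately not midpoint-rooted: midpoint rooting is ill-defined when
all pairwise distances are zero (identical inputs), while the seed
trifurcation always exists.

Percent identity depends on the denominator, and published matrices
rarely state which one was used, so all three conventions are exposed:
`aligned_columns` (identical columns over all columns with at least one
residue; default), `shorter_seq`, and `ungapped_columns`. For a matrix
from an MSA, each pair is first projected onto the columns where not both
rows are gaps.

## Evolutionary distances

Distances are maximum-likelihood branch lengths under a time-reversible
20-state model, `Q = S · diag(π)` rescaled so `−Σ π_i Q_ii = 1`
(distances are in expected substitutions per site). JTT is the default;
Dayhoff is available. Exchangeabilities and equilibrium frequencies are
the published integer tables as distributed with standard phylogenetics
software. The likelihood `Σ_xy N_xy log(π_x P(d)_xy)` is maximised over
`d ∈ [10⁻⁶, 10]` by bounded Brent search (`xatol = 1e-10`); `P(d)` is
computed from a cached symmetric eigendecomposition, so each evaluation
is two 20×20 products. An estimate at the upper bound raises a
saturation error naming the offending pair — saturated distances are an
error, never an infinity, because NJ downstream cannot use them.

The Poisson model returns the closed-form Poisson correction
`d = −ln(1 − p)` exactly (`p` the pairwise p-distance over comparable
columns, gaps excluded pairwise). Rate heterogeneity across sites (Γ
models) is not implemented.

## Trees

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion.
Pair selection breaks ties lexicographically on the smallest leaf label
under each candidate, so identical inputs always give identical trees.
Negative branch lengths are kept by default (the historical behaviour of
distance programs) and can be clamped to zero; the domain-divergence
stage clamps by default so divergences are non-negative. On an additive
matrix NJ returns the generating tree exactly (checked to 1e-9 in the
tests).

Outgroup rooting places the root at the midpoint of the outgroup's
pendant edge; leaf-to-leaf path lengths are exactly preserved, and
degree-2 nodes left by rerooting are collapsed. Divergence from the
common ancestor is defined operationally as the path length from the
outgroup leaf to the taxon on the rooted tree.

Subfamily classification walks each leaf's ancestors rootward and adopts
the label of the first clade (below the root) containing a reference
leaf; clades containing references with conflicting labels yield
`unassigned`, as does reaching the root.

## Domain partitioning

Domains are 1-based inclusive intervals on an ungapped reference row,
supplied as TSV. An interval maps to the alignment-column span from its
first residue's column to its last residue's column; reference-gap
columns inside the span belong to the region. A packaged annotation for
human KPNA2 (IBB ≈ 1–95, ARM1–10 tiling ≈ 100–519) is an estimate for
convenience, not a curated boundary set. Domains with fewer than 10
columns are rejected. Per-domain divergence is: slice → ML distances →
NJ (clamped) → root on outgroup → outgroup-to-leaf path.

## Structure contacts and conservation

Contacts are receptor residues with at least one heavy atom within a
cutoff (default 4.0 Å, a common interface convention) of any ligand heavy
atom; waters and hydrogens are excluded, and alternate locations resolve
to the highest-occupancy conformer. The receptor and ligand chains
default to the longest and shortest protein chains and can be overridden,
and an explicit contact list (TSV) can replace the cutoff-derived set
when reproducing a published contact enumeration. Structure residue
numbers map to family-alignment columns through a global alignment
against a named family member, guarded by a 50% identity floor.

Conservation classes per column: `identical` (one residue type among
non-gap rows), `conserved` (all within one ClustalW strong group: STA,
NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW), `different`, `gapped`
(all-gap). The summary counts satisfy
`identical + conserved + different = total`.

## Molecular mass

Average (not monoisotopic) residue masses plus one water, because the
prediction is compared against SDS-PAGE-scale kDa estimates. Ambiguous
residues (X) are an error unless the mean residue mass is explicitly
allowed.

## The synthetic family generator

The generator evolves independent sites along a known rooted tree: the
root is drawn from the model's equilibrium frequencies and each branch of
length `t` applies `exp(Q · t · m(s))`, where `m(s)` is the site's domain
rate multiplier. One seeded generator drives everything; the same seed is
bit-reproducible.

The default family emulates the importin-α layout: seven paralogs in
three clades (two α2-like with a long-branch divergent member, three
α1-like, two α3-like), one reference taxon per clade, and a single
outgroup. Branch lengths are sized so sister-paralog identities land in
the mid-80s%, between-subfamily identities in the 40s%, and
outgroup-vs-family identities near 30–35% — the ranges seen in real
α-family comparisons. The fast N-terminal "IBB-like" region is residues
1–95 of a 500-residue root sequence at twice the body rate by default;
the multiplier is kept moderate because a deep outgroup times a large
multiplier pushes the fast-domain distances into saturation, where the
pipeline (correctly) refuses to estimate. The recovery analyses use a
stronger, 3× multiplier on a 950-of-5000-site domain, where the longer
alignment keeps estimates comfortably below saturation.

What the simulator does **not** emulate: insertions and deletions (the
true alignment is gap-free, so aligner gap placement is never exercised
against truth), rate autocorrelation along the sequence, composition
drift, and heterotachy. Passing recovery tests therefore demonstrate
correctness of the distance/tree/partition machinery under the model, not
robustness of the progressive aligner to real indel patterns.

Recovery is scored as: Robinson–Foulds distance between inferred and true
topology, absolute leaf-pair path-length error, and the domain rate
multiplier re-estimated as mean outgroup-to-taxon divergence in the fast
domain over that in the rate-1 background.

## Problem sizes and numerical choices

The test suite and the acceptance script run the enumeration oracle on
sequences of length ≤ 8 (exhaustive over all alignment paths), NJ
inversion on random trees of up to 12 leaves, simulator calibration on a
100,000-site pair, and full-pipeline recovery on an 8-leaf family with
5,000 sites — sizes at which every check is exact or tightly bounded
while the whole suite stays fast. Floating-point ties in traceback and
rooting comparisons use a 1e-9 tolerance; NJ additivity and path
invariance are asserted to 1e-9.

## Known limitations

- No local alignment, no position-specific or terminal-free gap scoring.
- No Γ rate heterogeneity, no ML or Bayesian tree inference, no
  bootstrap supports.
- Identity-to-the-published-table reproduction is tolerance-bounded
  unless the original aligner's output is ingested directly.
- The packaged KPNA2 domain annotation is an estimate; analyses that
  depend on exact IBB/ARM boundaries should supply curated intervals.
- Contact detection ignores water-mediated interactions.
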