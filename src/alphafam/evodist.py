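"""Maximum-likelihood evolutionary distances between aligned proteins.

A reversible amino-acid replacement model is built from published
exchangeabilities and equilibrium frequencies (JTT, Dayhoff) as
``Q = S · diag(pi)`` rescaled to one expected substitution per site.  The
pairwise distance is the branch length maximising the likelihood of the
observed residue pairs, found by bounded 1-D optimisation; the Poisson
model uses its closed form, the Poisson correction ``d = -ln(1 - p)``.
Transition matrices are computed through a cached symmetric
eigendecomposition, so ``P(t)`` costs two small matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ._empirical import (
    DAYHOFF_EXCHANGE,
    DAYHOFF_FREQS,
    JTT_EXCHANGE,
    JTT_FREQS,
    MODEL_ALPHABET,
)
from .align import GAP, Msa

_N = 20
_AA_INDEX = {c: i for i, c in enumerate(MODEL_ALPHABET)}

D_MIN, D_MAX = 1e-6, 10.0


class SaturationError(ValueError):
    """Distance estimate ran into the saturation bound."""


def _exchange_matrix(lower_triangle: Sequence[float]) -> np.ndarray:
    S = np.zeros((_N, _N))
    it = iter(lower_triangle)
    for i in range(1, _N):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    return S


@dataclass
class SubstitutionModel:
    """Time-reversible 20-state replacement model scaled to 1 sub/site."""

    name: str
    Q: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to 0")
        off = self.Q - np.diag(np.diag(self.Q))
        if (off < -1e-12).any():
            raise ValueError("off-diagonal rates must be non-negative")
        # Cached spectral form: pi^1/2 Q pi^-1/2 is symmetric for
        # reversible models, so P(t) = D^-1/2 U e^{L t} U' D^1/2.
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * self.Q) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = lam
        self._left = U / sq[:, None]
        self._right = U.T * sq[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1 for any t >= 0."""
        if t < 0:
            raise ValueError("time must be non-negative")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        return np.clip(P, 0.0, None)


def _scaled(S: np.ndarray, pi: np.ndarray, name: str) -> SubstitutionModel:
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return SubstitutionModel(name=name, Q=Q / rate, pi=pi)


def get_model(name: str) -> SubstitutionModel:
    """Build a model by name: ``jtt`` (default elsewhere), ``dayhoff``, ``poisson``."""
    name = name.lower()
    if name == "jtt":
        return _scaled(_exchange_matrix(JTT_EXCHANGE), np.array(JTT_FREQS), "jtt")
    if name == "dayhoff":
        return _scaled(
            _exchange_matrix(DAYHOFF_EXCHANGE), np.array(DAYHOFF_FREQS), "dayhoff"
        )
    if name == "poisson":
        S = np.ones((_N, _N))
        np.fill_diagonal(S, 0.0)
        pi = np.full(_N, 1.0 / _N)
        return _scaled(S, pi, "poisson")
    raise ValueError(f"unknown substitution model {name!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled matrix of distances in substitutions per site."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be 0")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def _comparable(row_a: str, row_b: str) -> list[tuple[str, str]]:
    pairs = [
        (x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP
    ]
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    if not pairs:
        raise ValueError("no comparable (both-residue) columns")
    return pairs


def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing residues over pairwise-comparable columns."""
    pairs = _comparable(row_a, row_b)
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    counts = np.zeros((_N, _N))
    for x, y in _comparable(row_a, row_b):
        ix, iy = _AA_INDEX.get(x), _AA_INDEX.get(y)
        if ix is None or iy is None:  # ambiguous residues are ignored
            continue
        counts[ix, iy] += 1.0
    if counts.sum() == 0:
        raise ValueError("no comparable unambiguous columns")
    return counts


def ml_distance(row_a: str, row_b: str, model: SubstitutionModel) -> float:
    """ML branch length (subs/site) separating two aligned rows.

    Maximises sum_xy N_xy log(pi_x P_xy(d)) over d in [1e-6, 10].  For the
    Poisson model the closed-form correction -ln(1 - p) is returned.
    """
    if model.name == "poisson":
        p = p_distance(row_a, row_b)
        if p >= 1.0 - 1e-12:
            raise SaturationError("distance saturated (p-distance = 1)")
        return -float(np.log1p(-p))

    counts = _pair_counts(row_a, row_b)
    if np.trace(counts) == counts.sum():
        return 0.0
    log_pi = np.log(model.pi)

    def neg_loglik(d: float) -> float:
        P = model.transition_matrix(d)
        with np.errstate(divide="ignore"):
            logP = np.log(P)
        ll = (counts * (log_pi[:, None] + logP)).sum()
        return -ll if np.isfinite(ll) else np.inf

    res = minimize_scalar(
        neg_loglik, bounds=(D_MIN, D_MAX), method="bounded",
        options={"xatol": 1e-10},
    )
    d_hat = float(res.x)
    if d_hat >= D_MAX - 1e-3:
        raise SaturationError(
            f"distance saturated (estimate at bound {D_MAX})"
        )
    return d_hat


def distance_matrix(msa: Msa, model: SubstitutionModel) -> DistanceMatrix:
    """All-pairs ML distances between MSA rows."""
    if msa.n_rows < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    n = msa.n_rows
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = ml_distance(msa.seqs[i], msa.seqs[j], model)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({msa.ids[i]}, {msa.ids[j]}): {exc}"
                ) from None
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=list(msa.ids), values=values)


# ---------------------------------------------------------------------------
# PHYLIP square matrix format


def write_phylip_matrix(labels: Sequence[str], values: np.ndarray, path) -> None:
    """Write a square matrix in PHYLIP format (names padded to 10 chars)."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels):5d}\n")
        for label, row in zip(labels, np.asarray(values)):
            name = label[:10].ljust(10)
            fh.write(name + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_matrix(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        tokens = fh.readline().split()
        if not tokens:
            raise ValueError(f"{path}: empty PHYLIP matrix")
        n = int(tokens[0])
        labels, rows = [], []
        for _ in range(n):
            line = fh.readline()
            if len(line) < 10:
                raise ValueError(f"{path}: truncated PHYLIP matrix")
            labels.append(line[:10].strip())
            rows.append([float(v) for v in line[10:].split()])
    return labels, np.array(rows)
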