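"""Shared codon substitution core.

The Goldman-Yang style 61-state Markov model on sense codons underlies both
the branch-model likelihood and the sequence simulator, guaranteeing that
simulation and inference agree on the process.  Instantaneous rates allow
single-nucleotide changes only; transitions are weighted by kappa and
nonsynonymous changes by omega; target-codon frequencies enter
multiplicatively, so the chain is reversible with stationary distribution
pi.  Matrices are scaled to one expected substitution per codon per unit
branch length.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard genetic code, lexicographic order
CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _STANDARD_TABLE.forward_table if set(c) <= set("ACGT"))
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)
AMINO_ACIDS: tuple[str, ...] = tuple(_STANDARD_TABLE.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES) == (b in _PURINES) and a != b


def _pair_classification() -> tuple[np.ndarray, np.ndarray]:
    """(is_single_diff & transition flag, is_single_diff & nonsyn flag).

    Returns two 61x61 int8 matrices: ts[i, j] = 1 if codons i, j differ at
    exactly one position by a transition (0 transversion, -1 not a single
    change); nonsyn[i, j] = 1 if a single change alters the amino acid.
    """
    n = len(CODONS)
    ts = -np.ones((n, n), dtype=np.int8)
    nonsyn = -np.ones((n, n), dtype=np.int8)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ts[i, j] = 1 if is_transition(ci[k], cj[k]) else 0
            nonsyn[i, j] = 1 if AMINO_ACIDS[i] != AMINO_ACIDS[j] else 0
    return ts, nonsyn


_TS, _NONSYN = _pair_classification()
_SINGLE = _TS >= 0


def uniform_frequencies() -> np.ndarray:
    """Uniform distribution over the 61 sense codons."""
    return np.full(len(CODONS), 1.0 / len(CODONS))


def f1x4_frequencies(sequences: list[str]) -> np.ndarray:
    """F1x4 codon frequencies: products of empirical nucleotide frequencies,
    renormalized over sense codons."""
    counts = {b: 1.0 for b in "ACGT"}  # +1 pseudocount avoids zeros
    for seq in sequences:
        for b in seq:
            if b in counts:
                counts[b] += 1.0
    total = sum(counts.values())
    p = {b: c / total for b, c in counts.items()}
    freqs = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in CODONS])
    return freqs / freqs.sum()


def rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, scale: bool = True
) -> np.ndarray:
    """61x61 instantaneous rate matrix Q.

    Q[i, j] = pi_j * kappa^{ts} * omega^{nonsyn} for single-nucleotide
    changes, 0 otherwise; diagonal set so rows sum to zero.  When ``scale``
    the matrix is normalized so -sum_i pi_i Q[i, i] = 1, i.e. branch lengths
    are expected substitutions per codon.
    """
    q = np.where(_SINGLE, freqs[np.newaxis, :], 0.0)
    q = q * np.where(_TS == 1, kappa, 1.0) * np.where(_NONSYN == 1, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -float(freqs @ np.diag(q))
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        q = q / rate
    return q


def synonymous_flow_fraction(kappa: float, omega: float, freqs: np.ndarray) -> float:
    """Fraction of the stationary substitution flow that is synonymous.

    At omega = 1 this is the model-based proportion of synonymous sites
    (rho_S); at the branch's fitted omega it apportions the branch length
    into synonymous and nonsynonymous substitutions, codeml-style.
    """
    q = rate_matrix(kappa, omega, freqs, scale=False)
    syn_flow = float(freqs @ np.where((_NONSYN == 0) & _SINGLE, q, 0.0).sum(axis=1))
    total_flow = float(freqs @ np.where(_SINGLE, q, 0.0).sum(axis=1))
    return syn_flow / total_flow


class CodonRateModel:
    """Eigendecomposition-backed transition probabilities P(t) = exp(Qt).

    The chain is reversible, so D^{1/2} Q D^{-1/2} is symmetric (D = diag pi)
    and a single `eigh` serves every branch length.  Decompositions are
    cached per (kappa, omega, frequency vector).
    """

    def __init__(self, kappa: float, omega: float, freqs: np.ndarray):
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.freqs = np.asarray(freqs, dtype=float)
        q = rate_matrix(self.kappa, self.omega, self.freqs)
        sqrt_pi = np.sqrt(self.freqs)
        sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]  # D^{-1/2} U
        self._right = (evecs * sqrt_pi[:, None]).T  # U^T D^{1/2}
        self.q = q

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t); rows index the ancestral codon, columns the descendant."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


@lru_cache(maxsize=64)
def _cached_model(kappa: float, omega: float, freqs_key: bytes) -> CodonRateModel:
    return CodonRateModel(kappa, omega, np.frombuffer(freqs_key, dtype=float))


def get_rate_model(kappa: float, omega: float, freqs: np.ndarray) -> CodonRateModel:
    """Cached CodonRateModel; reuses the eigendecomposition across calls."""
    return _cached_model(float(kappa), float(omega), np.ascontiguousarray(freqs, dtype=float).tobytes())
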