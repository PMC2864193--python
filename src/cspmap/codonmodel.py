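"""Codon substitution model machinery (Goldman-Yang style, 61 sense codons).

The substitution process is a reversible continuous-time Markov chain on the
61 sense codons of the universal genetic code.  Instantaneous rates between
codons differing at exactly one nucleotide position are

    q_ij = pi_j            synonymous transversion
    q_ij = kappa * pi_j    synonymous transition
    q_ij = omega * pi_j    nonsynonymous transversion
    q_ij = omega * kappa * pi_j   nonsynonymous transition

and zero between codons differing at more than one position.  kappa is the
transition/transversion rate ratio, omega the nonsynonymous/synonymous rate
ratio (dN/dS), and pi the stationary codon frequencies (F3x4 by default).
The generator is rescaled so one unit of branch length equals one expected
substitution per codon at stationarity.  Transition probabilities P(t) =
exp(Qt) are computed through the symmetrized eigendecomposition that
reversibility affords.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "N_CODONS",
    "CodonAlignment",
    "PhyloTree",
    "build_rate_matrix",
    "rate_coefficients",
    "CodonQ",
    "transition_probs",
    "f3x4_frequencies",
    "observed_frequencies",
    "uniform_frequencies",
    "encode_codons",
    "star_site_likelihoods",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_NUCS = "ACGT"

SENSE_CODONS: Tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: Tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)           # 61 for the universal code
_AA = np.array([_TABLE.forward_table[c] for c in SENSE_CODONS])

_PURINES = {"A", "G"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _pair_masks() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            transition[i, j] = _is_transition(*diffs[0])
            nonsyn[i, j] = _AA[i] != _AA[j]
    return single, transition, nonsyn

_SINGLE, _TRANSITION, _NONSYN = _pair_masks()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Scaled 61x61 generator Q for given kappa, omega and codon frequencies.

    Rows sum to zero and the expected substitution rate at stationarity,
    -sum_i pi_i q_ii, is normalised to 1, so branch lengths are expected
    substitutions per codon.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, float)
    if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must be a 61-vector summing to 1")
    mult = np.where(_TRANSITION, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    Q = np.where(_SINGLE, mult * pi[None, :], 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(pi @ np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return Q / rate


def rate_coefficients(kappa: float, pi: np.ndarray) -> Tuple[float, float]:
    """Synonymous and nonsynonymous parts of the unscaled substitution rate.

    The flow rate of the unnormalised generator is linear in omega:
    rate(omega) = A + B * omega.  Site-class mixtures are scaled by the
    mixture-average rate A + B * mean(omega), so a class with omega above
    the branch average evolves proportionally faster -- the convention of
    standard branch-site implementations, and the source of their power.
    """
    pi = np.asarray(pi, float)
    R = np.where(_SINGLE, np.where(_TRANSITION, kappa, 1.0) * pi[None, :], 0.0)
    A = float(pi @ (R * ~_NONSYN).sum(axis=1))
    B = float(pi @ (R * _NONSYN).sum(axis=1))
    return A, B


class CodonQ:
    """A generator with its symmetric eigendecomposition cached.

    Reversibility (pi_i q_ij = pi_j q_ji) means D^{1/2} Q D^{-1/2} is
    symmetric for D = diag(pi), so P(t) = D^{-1/2} V exp(L t) V' D^{1/2}
    from one `eigh` call, after which each branch length costs only two
    matrix products.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        self.kappa = kappa
        self.omega = omega
        self.pi = np.asarray(pi, float)
        self.Q = build_rate_matrix(kappa, omega, self.pi)
        sqrt_pi = np.sqrt(self.pi)
        S = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((S + S.T) / 2.0)
        self._lam = lam
        self._left = V / sqrt_pi[:, None]       # D^{-1/2} V
        self._right = (V * sqrt_pi[:, None]).T  # V' D^{1/2}

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); a proper stochastic matrix for t >= 0."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probs(Q_or_model, t: float) -> np.ndarray:
    """Convenience wrapper: P(t) from a :class:`CodonQ` or a raw generator."""
    if isinstance(Q_or_model, CodonQ):
        return Q_or_model.transition_probs(t)
    from scipy.linalg import expm
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return expm(np.asarray(Q_or_model, float) * t)


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------

_FREQ_FLOOR = 1e-8


def _normalise(pi: np.ndarray) -> np.ndarray:
    pi = np.maximum(pi, _FREQ_FLOOR)   # keep every sense codon reachable
    return pi / pi.sum()


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(codon_idx: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies: products of the observed nucleotide
    frequencies at each codon position, renormalised over sense codons."""
    codons = np.asarray(codon_idx).ravel()
    pos_freq = np.zeros((3, 4))
    for idx in codons:
        for pos, nuc in enumerate(SENSE_CODONS[int(idx)]):
            pos_freq[pos, _NUCS.index(nuc)] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array([pos_freq[0, _NUCS.index(c[0])]
                   * pos_freq[1, _NUCS.index(c[1])]
                   * pos_freq[2, _NUCS.index(c[2])] for c in SENSE_CODONS])
    return _normalise(pi)


def observed_frequencies(codon_idx: np.ndarray) -> np.ndarray:
    """Empirical sense-codon frequencies from the alignment."""
    counts = np.bincount(np.asarray(codon_idx).ravel(), minlength=N_CODONS)
    return _normalise(counts.astype(float))


def encode_codons(sequence: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as sense-codon indices."""
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    idx = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide {i + 1}")
        if codon not in CODON_INDEX:
            raise ValueError(f"unrecognised codon {codon!r} at nucleotide {i + 1}")
        idx.append(CODON_INDEX[codon])
    return np.array(idx, dtype=np.int64)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Three aligned in-frame coding sequences as codon-index rows."""

    taxa: List[str]
    codons: np.ndarray               # shape (3, n_codons), int indices
    removed_columns: int = 0         # gap/ambiguity codon columns dropped

    @property
    def n_codons(self) -> int:
        return int(self.codons.shape[1])

    def sequences(self) -> List[str]:
        return ["".join(SENSE_CODONS[i] for i in row) for row in self.codons]

    def patterns(self) -> Tuple[np.ndarray, np.ndarray]:
        """Distinct site patterns and their counts (likelihood compression)."""
        cols, counts = np.unique(self.codons, axis=1, return_counts=True)
        return cols, counts


@dataclass
class PhyloTree:
    """Unrooted 3-taxon tree: one internal node, three terminal branches."""

    taxa: List[str]
    branch_lengths: np.ndarray       # shape (3,), expected subst. per codon
    foreground: Optional[str] = None

    def __post_init__(self) -> None:
        self.branch_lengths = np.asarray(self.branch_lengths, float)
        if len(self.taxa) != 3 or self.branch_lengths.shape != (3,):
            raise ValueError("tree must have exactly 3 taxa and branch lengths")
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        if self.foreground is not None and self.foreground not in self.taxa:
            raise ValueError(f"foreground taxon {self.foreground!r} not in tree")

    @property
    def foreground_index(self) -> int:
        if self.foreground is None:
            raise ValueError("no foreground branch designated")
        return self.taxa.index(self.foreground)

    def to_newick(self) -> str:
        parts = ",".join(f"{t}:{bl:.6g}" for t, bl in zip(self.taxa, self.branch_lengths))
        return f"({parts});"


def star_site_likelihoods(pmats: Sequence[np.ndarray], pi: np.ndarray,
                          leaf_idx: np.ndarray) -> np.ndarray:
    """Per-site likelihoods on the 3-taxon star tree (pruning collapses to a
    single sum over the internal node's 61 states).

    ``pmats`` are the three branch transition matrices, ``leaf_idx`` the
    (3, n_sites) observed codon indices.  Returns the site likelihoods
    sum_x pi_x P0[x,s0] P1[x,s1] P2[x,s2].
    """
    partial = pi[:, None] * pmats[0][:, leaf_idx[0]]
    partial = partial * pmats[1][:, leaf_idx[1]]
    partial = partial * pmats[2][:, leaf_idx[2]]
    return partial.sum(axis=0)
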