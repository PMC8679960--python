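"""Transition models and log-space Viterbi decoding over ancestry windows.

Two transition parameterizations are supported: a single switching penalty x
giving off-diagonal probabilities 1/(K + x) (x = 0 is a uniform matrix; large
x strongly discourages ancestry switches), and a distance-based model where
the probability of switching from population i to j is inversely proportional
to a supplied between-population distance.  Decoding is the standard Viterbi
dynamic program run entirely in log-space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .emission import EmissionMatrix


@dataclass
class TransitionModel:
    """Row-stochastic K x K transition matrix plus initial distribution."""

    A: np.ndarray
    pi: np.ndarray
    penalty: float | None = None
    source: str = "penalty"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        K = self.A.shape[0]
        if self.A.shape != (K, K):
            raise ValueError("transition matrix must be square")
        if (self.A < 0).any() or (self.pi < 0).any():
            raise ValueError("probabilities must be >= 0")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def log_A(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.A)

    def log_pi(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.pi)


@dataclass
class ViterbiTrace:
    """Dynamic-programming trace: best log scores, back-pointers, decoded path."""

    delta: np.ndarray  # (T, K) best log path score ending in state j at t
    backptr: np.ndarray  # (T, K) argmax predecessor (row 0 unused)
    path: np.ndarray  # (T,) decoded state indices

    @property
    def log_prob(self) -> float:
        """Log-probability of the decoded (maximum-probability) path."""
        return float(self.delta[-1, self.path[-1]])

    @property
    def n_switches(self) -> int:
        return int((np.diff(self.path) != 0).sum())


def build_transition_penalty(K: int, x: float,
                             pi: np.ndarray | None = None) -> TransitionModel:
    """Penalty-parameterized transitions: a_ij = 1/(K+x) off the diagonal.

    The diagonal takes the remaining mass, a_ii = 1 - (K-1)/(K+x), so each
    row sums to exactly 1.  x = 0 gives the uniform matrix; large x makes
    ancestry switches between adjacent windows expensive.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if x < 0:
        raise ValueError("penalty must be >= 0")
    off = 1.0 / (K + x)
    A = np.full((K, K), off)
    np.fill_diagonal(A, 1.0 - (K - 1) * off)
    if pi is None:
        pi = np.full(K, 1.0 / K)
    return TransitionModel(A=A, pi=np.asarray(pi, dtype=float),
                           penalty=x, source="penalty")


def build_transition_distance(
    D: np.ndarray,
    self_weight: float | None = None,
    penalty: float = 10000.0,
    pi: np.ndarray | None = None,
) -> TransitionModel:
    """Distance-based transitions: switching to j is proportional to 1/D_ij.

    Off-diagonal entries of each row i are proportional to the inverse
    distance 1/D_ij, normalized so they share the total switching mass
    1 - self_weight.  When ``self_weight`` is not given it defaults to
    1 - (K-1)/(K+penalty), which makes the model reduce exactly to the
    penalty model when all off-diagonal distances are equal.
    """
    D = np.asarray(D, dtype=float)
    K = D.shape[0]
    if D.shape != (K, K):
        raise ValueError("distance matrix must be square")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    off_mask = ~np.eye(K, dtype=bool)
    if (D[off_mask] < 0).any():
        raise ValueError("distances must be nonnegative")
    if (D[off_mask] == 0).any():
        raise ValueError("zero off-diagonal distance implies an infinite "
                         "switching rate")
    if not np.allclose(D, D.T):
        import warnings

        warnings.warn("asymmetric distance matrix: symmetrizing by averaging")
        D = 0.5 * (D + D.T)
    if self_weight is None:
        self_weight = 1.0 - (K - 1) / (K + penalty)
    if not 0.0 < self_weight <= 1.0:
        raise ValueError("self_weight must lie in (0, 1]")
    inv = np.zeros_like(D)
    inv[off_mask] = 1.0 / D[off_mask]
    row = inv.sum(axis=1, keepdims=True)
    A = np.where(off_mask, inv / row * (1.0 - self_weight), 0.0)
    np.fill_diagonal(A, self_weight)
    if pi is None:
        pi = np.full(K, 1.0 / K)
    return TransitionModel(A=A, pi=np.asarray(pi, dtype=float),
                           source="distance")


def read_distance_matrix(path: str | Path,
                         populations: list[str] | None = None) -> np.ndarray:
    """Square TSV with population labels as header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    if populations is not None:
        missing = set(populations) - set(df.index)
        if missing:
            raise ValueError(f"distance matrix lacks populations: {sorted(missing)}")
        df = df.loc[populations, populations]
    return df.to_numpy(dtype=float)


def viterbi_decode(
    emissions: EmissionMatrix | np.ndarray,
    model: TransitionModel,
) -> ViterbiTrace:
    """Maximum-probability state path through window-level log emissions.

    Initialization: delta_j(1) = log pi_j + e[1, j].  Recursion:
    delta_j(t+1) = max_i [delta_i(t) + log a_ij] + e[t+1, j], with the argmax
    predecessor stored for the backtrace.  Ties break toward the lowest state
    index.  All arithmetic is in log-space.
    """
    e = emissions.logpost if isinstance(emissions, EmissionMatrix) else np.asarray(emissions, dtype=float)
    T, K = e.shape
    if K != model.n_states:
        raise ValueError("emission and transition dimensions disagree")
    if T < 1:
        raise ValueError("need at least one window")
    logA = model.log_A()
    delta = np.empty((T, K))
    backptr = np.zeros((T, K), dtype=int)
    delta[0] = model.log_pi() + e[0]
    if not np.isfinite(delta[0]).any():
        raise ValueError("no admissible path: all initial scores are -inf")
    for t in range(1, T):
        # scores[i, j] = delta_{t-1}(i) + log a_ij
        scores = delta[t - 1][:, None] + logA
        backptr[t] = np.argmax(scores, axis=0)  # first max = lowest index
        delta[t] = scores[backptr[t], np.arange(K)] + e[t]
        if not np.isfinite(delta[t]).any():
            raise ValueError(f"no admissible path at window {t}")
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return ViterbiTrace(delta=delta, backptr=backptr, path=path)


def viterbi_decode_blocks(
    logpost: np.ndarray,
    model: TransitionModel,
    block_chroms: list[str],
) -> np.ndarray:
    """Decode each chromosome independently, restarting from pi at each block.

    ``block_chroms`` gives the chromosome label of each window row; contiguous
    runs of the same label form blocks that are decoded separately so no
    transition spans a chromosome boundary.
    """
    logpost = np.asarray(logpost, dtype=float)
    if len(block_chroms) != logpost.shape[0]:
        raise ValueError("chromosome labels must match window count")
    path = np.empty(logpost.shape[0], dtype=int)
    start = 0
    for t in range(1, len(block_chroms) + 1):
        if t == len(block_chroms) or block_chroms[t] != block_chroms[start]:
            path[start:t] = viterbi_decode(logpost[start:t], model).path
            start = t
    return path
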