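"""Basic singular spectrum analysis (SSA) for trend extraction.

SSA decomposes a one-dimensional series into additive components without
any parametric model.  The series y_1..y_N is embedded into an L x K Hankel
trajectory matrix (K = N - L + 1) whose columns are the L-lagged vectors;
the SVD of that matrix splits it into rank-one elementary matrices; a group
of elementary matrices is mapped back to a series by diagonal averaging
(hankelization).  For a morphogen gradient — a smooth, nearly exponential
trend plus structureless noise — the first eigentriple carries the trend,
so the default extraction keeps component 1 as signal and calls the rest
noise.

A noiseless exponential A * r^i has Hankel rank exactly 1, so SSA recovers
it perfectly from the first eigentriple; this exactness is what the tests
pin down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .profiles import ExpressionProfile, SignalExtraction

#: singular values below this fraction of the largest are treated as zero
RANK_TOL = 1e-11


@dataclass(frozen=True)
class TrajectoryMatrix:
    """L x K Hankel matrix of L-lagged vectors of a length-N series."""

    values: np.ndarray
    window_length_L: int
    series_length_N: int

    @property
    def K(self) -> int:
        return self.series_length_N - self.window_length_L + 1


@dataclass(frozen=True)
class SSADecomposition:
    """Thin SVD of a trajectory matrix.

    ``singular_values[i]`` is sqrt(lambda_i) where lambda_i are the
    eigenvalues of X X^T in decreasing order; ``left_vectors`` (L x m) and
    ``right_vectors`` (K x m) hold the orthonormal U_i and V_i = X^T U_i /
    sqrt(lambda_i).  ``rank_d`` counts singular values above tolerance.
    """

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    rank_d: int


def embed(series: Sequence[float] | np.ndarray, window_length_L: int) -> TrajectoryMatrix:
    """Embed a series into its L x K trajectory matrix.

    Column j (0-based) is ``(y_j, ..., y_{j+L-1})``; the result is Hankel:
    entry (i, j) depends only on i + j.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    L = int(window_length_L)
    if not 2 <= L <= n - 1:
        raise ValueError(f"window length must satisfy 2 <= L <= N-1 = {n - 1}, got {L}")
    X = sliding_window_view(y, L).T.copy()  # L x K
    return TrajectoryMatrix(X, L, n)


def decompose(X: TrajectoryMatrix) -> SSADecomposition:
    """Thin SVD of the trajectory matrix; eigenvalues of X X^T are the squares."""
    if not np.all(np.isfinite(X.values)):
        raise ValueError("trajectory matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(X.values, full_matrices=False)
    if s.size and s[0] > 0:
        rank_d = int(np.sum(s > RANK_TOL * s[0]))
    else:
        rank_d = 0
    return SSADecomposition(s, U, Vt.T, rank_d)


def diagonal_average(M: np.ndarray) -> np.ndarray:
    """Average the anti-diagonals of an L x K matrix into a length L+K-1 series."""
    M = np.asarray(M, dtype=float)
    L, K = M.shape
    n = L + K - 1
    idx = np.add.outer(np.arange(L), np.arange(K))
    sums = np.bincount(idx.ravel(), weights=M.ravel(), minlength=n)
    counts = np.bincount(idx.ravel(), minlength=n)
    return sums / counts


def reconstruct_group(
    decomp: SSADecomposition, X: TrajectoryMatrix, group: Iterable[int]
) -> np.ndarray:
    """Reconstruct the series component carried by a group of eigentriples.

    ``group`` holds 1-based eigentriple indices (1 = leading).  The grouped
    elementary matrices are summed and hankelized by diagonal averaging.
    """
    idx = sorted(set(int(g) for g in group))
    if not idx:
        raise ValueError("group must be non-empty")
    if idx[0] < 1 or idx[-1] > decomp.rank_d:
        raise ValueError(f"group indices must lie in 1..{decomp.rank_d}")
    sel = np.array(idx) - 1
    Xg = (decomp.left_vectors[:, sel] * decomp.singular_values[sel]) @ decomp.right_vectors[:, sel].T
    return diagonal_average(Xg)


def default_window_length(n: int) -> int:
    """L = floor(N/2), the standard separability-maximizing choice."""
    return max(2, min(n - 1, n // 2))


def extract_signal_ssa(
    profile: ExpressionProfile,
    window_length_L: int | None = None,
    n_components: int = 1,
) -> SignalExtraction:
    """Extract the trend of a profile as the leading SSA component(s).

    The default keeps the first eigentriple alone as signal and treats the
    remainder as noise; ``n_components`` widens the trend group.
    """
    y = profile.intensities
    L = default_window_length(len(profile)) if window_length_L is None else int(window_length_L)
    X = embed(y, L)
    dec = decompose(X)
    k = min(int(n_components), dec.rank_d)
    if k < 1:
        raise ValueError("n_components must be >= 1 (and the series must be nonzero)")
    signal = reconstruct_group(dec, X, range(1, k + 1))
    return SignalExtraction(
        method="ssa",
        positions=profile.positions,
        observed=y,
        signal=signal,
        residual=y - signal,
        meta={"window_length_L": L, "n_components": k, "rank_d": dec.rank_d},
    )


def w_correlation(
    series_a: Sequence[float] | np.ndarray,
    series_b: Sequence[float] | np.ndarray,
    window_length_L: int,
) -> float:
    """Weighted correlation between two series of equal length N.

    The weight of point i (1-based) is its anti-diagonal multiplicity in the
    L x K trajectory matrix, ``w_i = min(i, L, K, N - i + 1)``.  Components
    with |w-correlation| near zero are well separated (w-orthogonal).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must have equal length")
    n = a.size
    L = int(window_length_L)
    if not 2 <= L <= n - 1:
        raise ValueError(f"window length must satisfy 2 <= L <= N-1 = {n - 1}, got {L}")
    w = w_correlation_weights(n, L)
    na = np.dot(w * a, a)
    nb = np.dot(w * b, b)
    if na <= 0 or nb <= 0:
        raise ValueError("zero weighted norm")
    return float(np.dot(w * a, b) / np.sqrt(na * nb))


def w_correlation_weights(n: int, L: int) -> np.ndarray:
    """Anti-diagonal multiplicities min(i, L, K, N-i+1) for i = 1..N."""
    K = n - L + 1
    i = np.arange(1, n + 1)
    return np.minimum.reduce([i, np.full(n, L), np.full(n, K), n - i + 1]).astype(float)
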