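"""Toroidal temporal smoothing of typing activity via graph-regularized SVD.

A participant's day x hour grid is treated as a sampling of a trajectory on
a torus: hour 23 of one day wraps into hour 0 of the next, and the same hour
couples across nearby days (the biological clock is assumed stable within a
one-week window). The grid cells become graph nodes with

* hour edges between adjacent hours of a day (including the 23 -> 0
  midnight wrap into the next day), weighted by the mean keystroke count of
  the two cells, and
* day edges between the same hour on days up to three apart, weighted by
  the median keystroke count of that hour over a centered seven-day window
  (symmetrized as the mean of the two endpoint-centered medians).

The smoothed trajectory solves

    min_{H, W}  ||X - H W||_F^2 + alpha * Tr(W B W^T)   s.t.  H^T H = I_r

where X stacks the normalized-count and typing-speed rows (2 x n, day-major
node order) and B is the combinatorial graph Laplacian of the weighted
adjacency, so I + alpha*B is positive-definite. With D the lower Cholesky
factor of I + alpha*B, the solution is read off the thin SVD of X D^{-T}:
H* = E_r and W* = S_r F_r^T D^{-1}. If every entry of W* is negative both
factors are negated; remaining negative entries are clamped to zero before
sleep binarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .matrices import ActivityMatrix, normalize_counts

DAY_EDGE_REACH = 3  # day edges span 1..3 rows, i.e. a one-week median window


class NumericalError(RuntimeError):
    pass


class SmoothingConfigError(ValueError):
    pass


@dataclass
class SmoothingConfig:
    """Regularization scale, factorization rank, and numeric switches."""

    alpha: float = 100.0
    rank: int = 1
    #: zero threshold for binarization, as a fraction of max |W*|
    zero_tolerance_scale: float = 1e-9
    #: build B as the graph Laplacian (default) or the raw weighted adjacency
    laplacian: bool = True
    #: optionally scale each X row to unit SD before factorization
    standardize_rows: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise SmoothingConfigError("alpha must be >= 0")
        if self.rank not in (1, 2):
            raise SmoothingConfigError("rank must be 1 or 2")


@dataclass
class ObservationGraph:
    """Weighted adjacency over all (day, hour) cells in day-major node order."""

    n_days: int
    adjacency: np.ndarray  # (n, n) symmetric, nonnegative

    @property
    def n_nodes(self) -> int:
        return 24 * self.n_days


@dataclass
class GraphSVDResult:
    loadings: np.ndarray          # H*, 2 x r, orthonormal columns
    trajectory: np.ndarray        # W*, r x n
    singular_values: np.ndarray   # the r retained values
    n_days: int                   # 0 when the node count is not a day grid
    alpha: float
    rank: int
    zero_tolerance: float         # epsilon for downstream binarization

    def trajectory_matrix(self, component: int = 0) -> np.ndarray:
        """One W* component reshaped to days x 24."""
        if self.n_days == 0:
            raise ValueError("trajectory is not a days x 24 grid")
        return self.trajectory[component].reshape(self.n_days, 24)

    def clamped_trajectory(self, component: int = 0) -> np.ndarray:
        """days x 24 view with residual negative entries clamped to zero."""
        return np.clip(self.trajectory_matrix(component), 0.0, None)


def hour_edge_weight(k_cur: float, k_next: float) -> float:
    """Mean typing activity of two hour-adjacent cells (incl. the 23->0 wrap)."""
    return (k_cur + k_next) / 2.0


def day_edge_weight(column: np.ndarray, j: int) -> float:
    """Median keystroke count of one hour over days j-3..j+3, truncated at ends."""
    lo, hi = max(0, j - DAY_EDGE_REACH), min(len(column), j + DAY_EDGE_REACH + 1)
    return float(np.median(column[lo:hi]))


def build_graph(counts: np.ndarray | ActivityMatrix) -> ObservationGraph:
    """Construct the toroidal observation graph from the raw count matrix.

    Day adjacency follows row order (chronological neighbors among surviving
    rows), so non-contiguous dates remain connected by rank.
    """
    k = counts.values if isinstance(counts, ActivityMatrix) else np.asarray(counts, float)
    n_days = k.shape[0]
    n = 24 * n_days
    flat = k.reshape(-1)
    adj = np.zeros((n, n))

    # hour edges: consecutive cells in day-major order cover both the
    # within-day pairs and the midnight wrap into the next row
    w = (flat[:-1] + flat[1:]) / 2.0
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = w
    adj[idx + 1, idx] = w

    # day edges: same hour, rows 1..3 apart, symmetrized centered medians
    for i in range(24):
        col = k[:, i]
        med = np.array([day_edge_weight(col, j) for j in range(n_days)])
        for gap in range(1, DAY_EDGE_REACH + 1):
            for j in range(n_days - gap):
                wgt = (med[j] + med[j + gap]) / 2.0
                a, b = j * 24 + i, (j + gap) * 24 + i
                adj[a, b] = wgt
                adj[b, a] = wgt
    return ObservationGraph(n_days=n_days, adjacency=adj)


def build_regularizer(graph: ObservationGraph, laplacian: bool = True) -> np.ndarray:
    """B = combinatorial Laplacian (degree - adjacency) of the weighted graph.

    The Laplacian is symmetric PSD, so I + alpha*B is positive-definite and
    Cholesky-factorizable for any alpha >= 0. ``laplacian=False`` returns the
    raw adjacency for comparison (positive-definiteness not guaranteed).
    """
    A = graph.adjacency
    if not np.allclose(A, A.T):
        raise NumericalError("adjacency must be symmetric")
    if not laplacian:
        return A
    return np.diag(A.sum(axis=1)) - A


def build_data_matrix(
    normalized_counts: ActivityMatrix, speed: ActivityMatrix
) -> np.ndarray:
    """Stack normalized counts and hourly speed as a 2 x n matrix, day-major."""
    if len(normalized_counts.dates) != len(speed.dates):
        raise ValueError("count and speed matrices must share dates")
    return np.vstack([normalized_counts.values.reshape(-1),
                      speed.values.reshape(-1)])


def smoothing_objective(X: np.ndarray, H: np.ndarray, W: np.ndarray,
                        B: np.ndarray, alpha: float) -> float:
    """||X - HW||_F^2 + alpha * Tr(W B W^T)."""
    resid = X - H @ W
    return float(np.sum(resid**2) + alpha * np.trace(W @ B @ W.T))


def graph_regularized_svd(
    X: np.ndarray, B: np.ndarray, config: SmoothingConfig | None = None
) -> GraphSVDResult:
    """Solve the graph-regularized factorization X ~ H* W*.

    D is the lower Cholesky factor of I + alpha*B; the thin SVD of X D^{-T}
    yields H* from its first r left singular vectors and
    W* = S_r F_r^T D^{-1}. With alpha = 0 this reduces to the plain
    truncated SVD of X.
    """
    config = config or SmoothingConfig()
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    n = X.shape[1]
    if B.shape != (n, n):
        raise ValueError("B must be n x n with n = X.shape[1]")

    scales = np.ones(X.shape[0])
    if config.standardize_rows:
        sd = X.std(axis=1)
        scales = np.where(sd > 0, sd, 1.0)
        X = X / scales[:, None]

    M = np.eye(n) + config.alpha * B
    try:
        D = scipy.linalg.cholesky(M, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            f"I + alpha*B is not positive-definite (alpha={config.alpha})"
        ) from exc

    # X D^{-T} = (D^{-1} X^T)^T
    Y = scipy.linalg.solve_triangular(D, X.T, lower=True).T
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    r = config.rank
    H = U[:, :r]
    sv = s[:r]
    G = sv[:, None] * Vt[:r]  # S_r F_r^T, r x n
    # W = G D^{-1}  <=>  D^T W^T = G^T
    W = scipy.linalg.solve_triangular(D, G.T, lower=True, trans="T").T

    # Sign fix: the factorization's sign is arbitrary; flip so activity is
    # positive. Entries within the zero tolerance count as exact zeros
    # (isolated inactive cells come out as 0 up to rounding), so the matrix
    # is "all negative" when nothing is significantly positive.
    eps = config.zero_tolerance_scale * (np.max(np.abs(W)) if W.size else 0.0)
    if W.size and (W < -eps).any() and not (W > eps).any():
        W = -W
        H = -H
    return GraphSVDResult(
        loadings=H, trajectory=W, singular_values=sv,
        n_days=n // 24 if n % 24 == 0 else 0,
        alpha=config.alpha, rank=r, zero_tolerance=eps,
    )


def smooth_participant(
    counts: ActivityMatrix, speed: ActivityMatrix,
    config: SmoothingConfig | None = None,
) -> tuple[GraphSVDResult, ObservationGraph]:
    """Full smoothing stage: graph from raw counts, X from normalized counts
    and speed, then the regularized factorization."""
    config = config or SmoothingConfig()
    graph = build_graph(counts)
    B = build_regularizer(graph, laplacian=config.laplacian)
    X = build_data_matrix(normalize_counts(counts), speed)
    result = graph_regularized_svd(X, B, config)
    return result, graph
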