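"""Ridge-regularized partial-correlation connectivity estimation.

Functional connectivity between regions of interest (ROIs) is estimated as
the partial correlation implied by a Tikhonov-regularized precision matrix:
the sample correlation matrix :math:`\\hat\\Sigma` of the (standardized)
ROI time series is inverted after adding a ridge :math:`\\alpha I`,

.. math:: \\Theta = (\\hat\\Sigma + \\alpha I)^{-1}, \\qquad
          \\rho_{ij} = -\\Theta_{ij} / \\sqrt{\\Theta_{ii}\\Theta_{jj}},

which keeps the estimate well defined when the number of timepoints is not
much larger than the number of nodes. Partial correlations are mapped to
Fisher z-scores and thresholded onto a sparsity grid, yielding one weighted,
undirected graph per grid point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "WeightedGraph",
    "tikhonov_partial_correlation",
    "fisher_z",
    "threshold_by_sparsity",
    "sparsity_grid",
    "max_edges",
]

# |rho| within this distance of 1 is treated as numerical round-off and
# clipped; anything farther out is a genuine contract violation.
_CLIP_TOL = 1e-9
_CLIP_TO = 1.0 - 1e-12


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Per-subject ROI time series: rows are timepoints, columns are ROIs."""

    values: np.ndarray
    node_labels: tuple[str, ...]
    subject_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D array")
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints and 2 nodes")
        if values.shape[1] != len(self.node_labels):
            raise ValueError("node_labels length must match column count")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric matrix of Fisher-z partial correlations with zero diagonal."""

    z_values: np.ndarray
    alpha: float
    node_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if z.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length must match matrix size")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite Fisher-z values")
        if not np.allclose(z, z.T, atol=1e-12):
            raise ValueError("z_values must be symmetric")
        if np.any(np.diag(z) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.z_values.shape[0]


@dataclass(frozen=True)
class WeightedGraph:
    """Sparsity-thresholded undirected graph with strictly positive weights.

    Edges are stored as parallel arrays of upper-triangle indices
    (``i < j``) and weights.
    """

    n_nodes: int
    edge_i: np.ndarray
    edge_j: np.ndarray
    weights: np.ndarray
    sparsity: float
    node_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ei = np.asarray(self.edge_i, dtype=np.intp)
        ej = np.asarray(self.edge_j, dtype=np.intp)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "edge_i", ei)
        object.__setattr__(self, "edge_j", ej)
        object.__setattr__(self, "weights", w)
        if not (len(ei) == len(ej) == len(w)):
            raise ValueError("edge arrays must have equal length")
        if np.any(ei >= ej):
            raise ValueError("edges must be upper-triangle (i < j)")
        if np.any(w <= 0):
            raise ValueError("all edge weights must be strictly positive")

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def to_dense(self) -> np.ndarray:
        """Symmetric dense weight matrix with zero diagonal."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        W[self.edge_i, self.edge_j] = self.weights
        W[self.edge_j, self.edge_i] = self.weights
        return W


def max_edges(n_nodes: int) -> int:
    """Number of possible undirected edges, N(N-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def tikhonov_partial_correlation(ts: TimeSeriesMatrix, alpha: float = 0.1) -> np.ndarray:
    """Partial-correlation matrix from a ridge-regularized precision.

    Columns are standardized to unit variance, so the regularized matrix is
    the sample correlation plus ``alpha`` on the diagonal. With ``alpha=0``
    this is the classical partial correlation and requires more timepoints
    than nodes.

    Parameters
    ----------
    ts : TimeSeriesMatrix
        Timepoints x nodes data.
    alpha : float
        Non-negative ridge added to the correlation matrix before inversion.

    Returns
    -------
    ndarray
        Symmetric nodes x nodes matrix with zero diagonal, all ``|rho| < 1``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    X = np.asarray(ts.values, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [ts.node_labels[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for node(s) {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    n = Xs.shape[1]
    S = (Xs.T @ Xs) / (Xs.shape[0] - 1)
    S_reg = S + alpha * np.eye(n)
    if alpha == 0:
        # an (near-)singular correlation matrix cannot be inverted stably
        w = np.linalg.eigvalsh(S)
        if w[0] < 1e-10 * max(w[-1], 1.0):
            raise np.linalg.LinAlgError(
                "sample correlation matrix is singular (e.g. fewer timepoints "
                "than nodes); use a positive ridge alpha"
            )
    theta = np.linalg.inv(S_reg)
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    rho = (rho + rho.T) / 2.0
    if np.any(np.abs(rho) >= 1.0):
        raise FloatingPointError("partial correlation reached |rho| >= 1")
    return rho


def fisher_z(
    rho: np.ndarray,
    *,
    alpha: float = 0.0,
    node_labels: tuple[str, ...] | None = None,
    subject_id: str = "",
) -> ConnectivityMatrix:
    """Apply Fisher's r-to-z transform, z = atanh(rho), entrywise.

    Values within ``1e-9`` of +/-1 are treated as round-off and clipped just
    inside the open interval; larger violations raise.
    """
    rho = np.asarray(rho, dtype=float)
    absr = np.abs(rho)
    offdiag = ~np.eye(rho.shape[0], dtype=bool)
    if np.any(absr[offdiag] >= 1.0 + _CLIP_TOL):
        raise ValueError("off-diagonal |rho| >= 1: not a valid partial correlation")
    clipped = np.clip(rho, -_CLIP_TO, _CLIP_TO)
    z = np.arctanh(clipped)
    np.fill_diagonal(z, 0.0)
    if node_labels is None:
        node_labels = tuple(f"node{k}" for k in range(rho.shape[0]))
    return ConnectivityMatrix(z_values=z, alpha=alpha, node_labels=node_labels, subject_id=subject_id)


def connectivity_from_timeseries(
    ts: TimeSeriesMatrix, alpha: float = 0.1
) -> ConnectivityMatrix:
    """Convenience: ridge partial correlation followed by Fisher-z."""
    rho = tikhonov_partial_correlation(ts, alpha)
    return fisher_z(rho, alpha=alpha, node_labels=ts.node_labels, subject_id=ts.subject_id)


def threshold_by_sparsity(cm: ConnectivityMatrix, s: float) -> WeightedGraph:
    """Keep the ``floor(s * N(N-1)/2)`` largest signed z-values as edges.

    Ranking is on signed z (strongest positive couplings), with ties broken
    by lexicographic (i, j) order. Retaining a non-positive weight is an
    error: the grid is too dense for this matrix.
    """
    if not (0 < s <= 1):
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = cm.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    z = cm.z_values[iu, ju]
    m = int(np.floor(s * max_edges(n)))
    if m < 1:
        raise ValueError(f"sparsity {s} retains zero edges for {n} nodes")
    # np.lexsort: last key is primary -> sort by (-z, i, j)
    order = np.lexsort((ju, iu, -z))[:m]
    w = z[order]
    if np.any(w <= 0):
        raise ValueError(
            f"sparsity {s} would retain non-positive weights; "
            "grid too dense for this connectivity matrix"
        )
    ei, ej = iu[order], ju[order]
    keep = np.lexsort((ej, ei))  # canonical edge order
    return WeightedGraph(
        n_nodes=n,
        edge_i=ei[keep],
        edge_j=ej[keep],
        weights=w[keep],
        sparsity=s,
        node_labels=cm.node_labels,
    )


def sparsity_grid(lo: float = 0.05, hi: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Inclusive arithmetic grid of sparsity values, rounded to step precision."""
    if not (0 < lo <= hi <= 1):
        raise ValueError("need 0 < lo <= hi <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    decimals = max(0, -int(np.floor(np.log10(step))) + 2)
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = np.round(lo + step * np.arange(n), decimals)
    grid = grid[grid <= hi + 1e-12]
    if len(grid) == 0:
        raise ValueError("empty sparsity grid")
    return grid
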