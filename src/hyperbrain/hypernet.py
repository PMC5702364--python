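"""Per-subject hyper-network construction by l1-regularized regression.

Each ROI's z-scored mean time series x_m is regressed on all other ROIs'
series (the design matrix has the m-th column zeroed), minimizing

    ||x_m - A_m alpha_m||_2^2 + lambda_eff * ||alpha_m||_1

by cyclic coordinate descent.  The regularization strength is expressed
on a standardized relative scale: lambda_eff = lambda_rel * lambda_max,
where lambda_max = 2 * max_j |a_j^T x_m| is the smallest penalty at which
the all-zero solution is optimal, so lambda_rel = 1 always yields an
empty support regardless of the data scale.  One hyper-edge per
(ROI, lambda) pair is the seed ROI together with the support of alpha_m;
singleton edges are dropped and duplicate node sets within a subject are
merged, keeping the smallest lambda_rel as provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SparseRegressionProblem",
    "HyperEdge",
    "HyperNetwork",
    "lambda_max",
    "solve_l1_regression",
    "build_hypernetwork",
    "hyperedge_adjacency",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

SUPPORT_TOL = 1e-8  # |weight| above this counts as a nonzero element


@dataclass
class SparseRegressionProblem:
    """One ROI's sparse regression: response x_m against design A_m.

    ``design`` must have its ``target`` column identically zero so the
    ROI never predicts itself; the corresponding weight is pinned at 0.
    """

    response: np.ndarray  # length d
    design: np.ndarray  # d x M, column `target` all zeros
    target: int
    lambda_relative: float = 0.5

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        d, m = self.design.shape
        if self.response.shape != (d,):
            raise ValueError("response length must match design rows")
        if not 0 <= self.target < m:
            raise ValueError("target column index out of range")
        if np.any(self.design[:, self.target] != 0):
            raise ValueError("design column of the target ROI must be all zeros")
        if not 0 < self.lambda_relative <= 1:
            raise ValueError("lambda_relative must lie in (0, 1]")


@dataclass(frozen=True)
class HyperEdge:
    """A hyper-edge: the seed ROI plus the ROIs in its regression support."""

    nodes: frozenset[int]
    seed_roi: int
    lambda_relative: float

    def __post_init__(self) -> None:
        if self.seed_roi not in self.nodes:
            raise ValueError("seed ROI must be a member of its hyper-edge")
        if len(self.nodes) < 2:
            raise ValueError("hyper-edges must contain at least two nodes")


@dataclass
class HyperNetwork:
    """A subject's hypergraph: node count, edges, and the incidence matrix."""

    n_nodes: int
    edges: list[HyperEdge] = field(default_factory=list)

    @property
    def incidence(self) -> np.ndarray:
        """|V| x |E| binary incidence matrix H, H[v, e] = 1 iff v in edge e."""
        h = np.zeros((self.n_nodes, len(self.edges)), dtype=np.int64)
        for j, edge in enumerate(self.edges):
            for v in edge.nodes:
                h[v, j] = 1
        return h

    @property
    def node_degrees(self) -> np.ndarray:
        """d(v): number of hyper-edges containing each node (row sums of H)."""
        return self.incidence.sum(axis=1)

    @property
    def edge_degrees(self) -> np.ndarray:
        """delta(e): number of nodes in each hyper-edge (column sums of H)."""
        return self.incidence.sum(axis=0)

    @property
    def edge_node_sets(self) -> set[tuple[int, ...]]:
        return {tuple(sorted(e.nodes)) for e in self.edges}


def lambda_max(problem: SparseRegressionProblem) -> float:
    """Smallest penalty for which the all-zero weight vector is optimal.

    For the objective ||x - A a||^2 + lam*||a||_1 the zero vector satisfies
    the subgradient conditions iff lam >= 2*max_j |a_j^T x|.
    """
    if not np.any(problem.design):
        raise ValueError("design matrix is all zeros; no regression possible")
    return float(2.0 * np.max(np.abs(problem.design.T @ problem.response)))


@njit(cache=True)
def _cd_lasso(gram, corr, target, lam, w, tol, max_iter):  # pragma: no cover
    """Cyclic coordinate descent on the Gram form of the lasso objective.

    Minimizes ||x - A w||^2 + lam*||w||_1 given gram = A^T A (full-series
    Gram; rows/cols of `target` are neutralized because w[target] stays 0)
    and corr = A^T x.  Returns the iteration count, negated on
    non-convergence.
    """
    m = corr.shape[0]
    half = lam / 2.0
    for it in range(max_iter):
        max_delta = 0.0
        for j in range(m):
            if j == target:
                continue
            gjj = gram[j, j]
            if gjj <= 0.0:
                continue
            cj = corr[j] - np.dot(gram[j], w) + gjj * w[j]
            if cj > half:
                new = (cj - half) / gjj
            elif cj < -half:
                new = (cj + half) / gjj
            else:
                new = 0.0
            delta = new - w[j]
            if delta != 0.0:
                w[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            return it + 1
    return -max_iter


@njit(cache=True)
def _support_paths(gram, lam_grid, tol, max_iter):  # pragma: no cover
    """Solve the lasso for every ROI at every relative lambda.

    gram is the M x M Gram matrix of the z-scored series.  For seed ROI m
    the design Gram is gram with row/col m neutralized and the correlation
    vector is gram[:, m].  Solutions are warm-started from the next-larger
    lambda (sparser to denser).  Returns an (M, L, M) float array of
    weights.
    """
    m_rois = gram.shape[0]
    n_lam = lam_grid.shape[0]
    weights = np.zeros((m_rois, n_lam, m_rois))
    for m in range(m_rois):
        corr = gram[:, m].copy()
        corr[m] = 0.0
        lam_max = 0.0
        for j in range(m_rois):
            if j != m and abs(corr[j]) > lam_max:
                lam_max = abs(corr[j])
        lam_max *= 2.0
        if lam_max <= 0.0:
            continue
        w = np.zeros(m_rois)
        for li in range(n_lam - 1, -1, -1):
            lam = lam_grid[li] * lam_max
            _cd_lasso(gram, corr, m, lam, w, tol, max_iter)
            weights[m, li] = w
    return weights


def solve_l1_regression(problem: SparseRegressionProblem, tol: float = 1e-6,
                        max_iter: int = 10_000) -> np.ndarray:
    """Solve one l1-regularized regression at the problem's lambda_relative.

    The effective penalty is ``lambda_relative * lambda_max(problem)``.
    Emits a warning and returns the best iterate on non-convergence.
    """
    lam = problem.lambda_relative * lambda_max(problem)
    gram = problem.design.T @ problem.design
    corr = problem.design.T @ problem.response
    w = np.zeros(problem.design.shape[1])
    status = _cd_lasso(gram, corr, problem.target, lam, w, tol, max_iter)
    if status < 0:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} iterations "
            f"(target ROI {problem.target})", RuntimeWarning)
    return w


def objective(problem: SparseRegressionProblem, weights: np.ndarray) -> float:
    """Value of ||x - A w||^2 + lambda_eff*||w||_1 at the given weights."""
    lam = problem.lambda_relative * lambda_max(problem)
    resid = problem.response - problem.design @ weights
    return float(resid @ resid + lam * np.sum(np.abs(weights)))


def _zscore_checked(series: np.ndarray, roi_names: list[str] | None) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    sd = series.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        name = roi_names[dead[0]] if roi_names else f"index {dead[0]}"
        raise ValueError(f"ROI {name} has a constant (zero-variance) series")
    return (series - series.mean(axis=0)) / sd


def build_hypernetwork(series: np.ndarray,
                       lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                       roi_names: list[str] | None = None,
                       tol: float = 1e-6,
                       max_iter: int = 10_000) -> HyperNetwork:
    """Construct one subject's hyper-network across the lambda grid.

    For every ROI m and every lambda in the grid, solves the sparse
    regression and emits the hyper-edge {m} union support(alpha_m).
    Singletons are dropped; duplicate node sets within the subject are
    merged keeping the smallest lambda_rel.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be a timepoints x ROIs matrix with >= 2 ROIs")
    if series.shape[0] <= 2:
        raise ValueError("series must have more than 2 timepoints")
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("lambda grid values must lie in (0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("lambda grid must be strictly increasing")

    z = _zscore_checked(series, roi_names)
    gram = z.T @ z
    weights = _support_paths(gram, grid, tol, max_iter)

    m_rois = series.shape[1]
    best_lambda: dict[tuple[int, ...], tuple[float, int]] = {}
    for m in range(m_rois):
        for li, lam_rel in enumerate(grid):
            support = np.flatnonzero(np.abs(weights[m, li]) > SUPPORT_TOL)
            if support.size == 0:
                continue
            nodes = tuple(sorted({m, *support.tolist()}))
            prev = best_lambda.get(nodes)
            if prev is None or lam_rel < prev[0]:
                best_lambda[nodes] = (float(lam_rel), m)

    edges = [
        HyperEdge(nodes=frozenset(nodes), seed_roi=seed, lambda_relative=lam)
        for nodes, (lam, seed) in sorted(best_lambda.items())
    ]
    return HyperNetwork(n_nodes=m_rois, edges=edges)


def restrict_lambda(network: HyperNetwork, max_lambda: float) -> HyperNetwork:
    """Sub-network of edges whose (smallest) lambda_rel is <= max_lambda.

    Because duplicate node sets are merged keeping the smallest lambda,
    this equals rebuilding the network on the grid prefix up to
    ``max_lambda`` — useful for lambda-grid sweeps without re-solving.
    """
    keep = [e for e in network.edges if e.lambda_relative <= max_lambda + 1e-12]
    return HyperNetwork(n_nodes=network.n_nodes, edges=keep)


def hyperedge_adjacency(network: HyperNetwork) -> np.ndarray:
    """A = H H^T - D_v: A[i, j] counts hyper-edges containing both i and j."""
    h = network.incidence
    a = h @ h.T
    np.fill_diagonal(a, 0)
    return a
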