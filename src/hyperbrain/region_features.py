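"""Hypergraph clustering coefficients and region-feature selection.

Three local clustering coefficients summarize each node's neighborhood
in the hyper-network:

* HCC1 — fraction of neighbor pairs (u, t) of node v connected by some
  hyper-edge that does NOT contain v ("connections not facilitated by v").
* HCC2 — fraction of neighbor pairs connected by some hyper-edge that
  DOES contain v ("connections facilitated by v").
* HCC3 — overlap among v's hyper-edges:
  2 * (sum_{e in S(v)} (|e|-1) - |N(v)|) / (|N(v)| * (|S(v)|-1)),
  zero when a star is disjoint and growing with multiply-covered
  neighbors.

Degenerate cases (fewer than two neighbors, or at most one incident
edge for HCC3) are defined as 0: no clustering evidence.

Feature selection uses the two-sample Kolmogorov-Smirnov test per
feature column with Benjamini-Hochberg FDR control; confounds (age,
sex, education) can first be regressed out of every column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hyperbrain.hypernet import HyperNetwork

__all__ = [
    "RegionFeatureTable",
    "hcc1",
    "hcc2",
    "hcc3",
    "compute_region_features",
    "residualize_confounds",
    "ks_fdr_select",
]

COEFFICIENTS = ("HCC1", "HCC2", "HCC3")

# Exact KS p-values when both groups are at most this large; asymptotic otherwise.
_KS_EXACT_MAX_N = 25


@dataclass
class RegionFeatureTable:
    """Subjects x (3*M) clustering-coefficient features with selection state."""

    features: pd.DataFrame  # columns "<roi>_<HCCk>", index subject ids
    labels: np.ndarray
    covariates: np.ndarray | None = None
    selection: pd.DataFrame | None = None  # feature, D, p, p_adj, selected

    @property
    def selected_columns(self) -> list[str]:
        if self.selection is None:
            return list(self.features.columns)
        return list(self.selection.loc[self.selection["selected"], "feature"])


def _neighborhood(network: HyperNetwork, node: int):
    """Star S(v) (incident edge indices) and neighbor set N(v)."""
    if not 0 <= node < network.n_nodes:
        raise IndexError(f"node index {node} out of range [0, {network.n_nodes})")
    star = [j for j, e in enumerate(network.edges) if node in e.nodes]
    neighbors: set[int] = set()
    for j in star:
        neighbors |= network.edges[j].nodes
    neighbors.discard(node)
    return star, neighbors


def hcc1(network: HyperNetwork, node: int) -> float:
    """Fraction of neighbor pairs of v co-members of an edge avoiding v."""
    _, neigh = _neighborhood(network, node)
    if len(neigh) < 2:
        return 0.0
    others = [e.nodes for e in network.edges if node not in e.nodes]
    pairs = 0
    nb = sorted(neigh)
    for i, u in enumerate(nb):
        for t in nb[i + 1:]:
            if any(u in e and t in e for e in others):
                pairs += 1
    n = len(neigh)
    return 2.0 * pairs / (n * (n - 1))


def hcc2(network: HyperNetwork, node: int) -> float:
    """Fraction of neighbor pairs of v co-members of an edge containing v."""
    star, neigh = _neighborhood(network, node)
    if len(neigh) < 2:
        return 0.0
    own = [network.edges[j].nodes for j in star]
    pairs = 0
    nb = sorted(neigh)
    for i, u in enumerate(nb):
        for t in nb[i + 1:]:
            if any(u in e and t in e for e in own):
                pairs += 1
    n = len(neigh)
    return 2.0 * pairs / (n * (n - 1))


def hcc3(network: HyperNetwork, node: int) -> float:
    """Overlap among v's incident hyper-edges (0 for disjoint stars)."""
    star, neigh = _neighborhood(network, node)
    if len(star) <= 1 or not neigh:
        return 0.0
    covered = sum(len(network.edges[j].nodes) - 1 for j in star)
    return 2.0 * (covered - len(neigh)) / (len(neigh) * (len(star) - 1))


def _all_coefficients(network: HyperNetwork) -> np.ndarray:
    """(M, 3) array of HCC1..HCC3, vectorized over the incidence matrix."""
    m = network.n_nodes
    out = np.zeros((m, 3))
    if not network.edges:
        return out
    h = network.incidence.astype(bool)  # M x E
    edge_sizes = h.sum(axis=0)
    for v in range(m):
        star = h[v]
        n_star = int(star.sum())
        if n_star == 0:
            continue
        neigh = h[:, star].any(axis=1)
        neigh[v] = False
        nb_idx = np.flatnonzero(neigh)
        n = nb_idx.size
        if n >= 2:
            denom = n * (n - 1)
            co_without = h[np.ix_(nb_idx, ~star)]
            a1 = (co_without @ co_without.T)
            np.fill_diagonal(a1, 0)
            out[v, 0] = float(np.count_nonzero(a1)) / denom
            co_with = h[np.ix_(nb_idx, star)]
            a2 = (co_with @ co_with.T)
            np.fill_diagonal(a2, 0)
            out[v, 1] = float(np.count_nonzero(a2)) / denom
        if n_star > 1 and n > 0:
            covered = int((edge_sizes[star] - 1).sum())
            out[v, 2] = 2.0 * (covered - n) / (n * (n_star - 1))
    return out


def compute_region_features(networks: list[HyperNetwork],
                            subject_ids: list[str] | None = None,
                            labels: np.ndarray | None = None,
                            covariates: np.ndarray | None = None,
                            roi_names: list[str] | None = None) -> RegionFeatureTable:
    """HCC1/HCC2/HCC3 for every ROI of every subject, ROI-major columns."""
    if not networks:
        raise ValueError("no networks given")
    n_nodes = {net.n_nodes for net in networks}
    if len(n_nodes) != 1:
        raise ValueError(f"networks disagree on node count: {sorted(n_nodes)}")
    m = n_nodes.pop()
    if roi_names is None:
        roi_names = [f"ROI{j + 1:03d}" for j in range(m)]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1}" for i in range(len(networks))]

    rows = np.stack([_all_coefficients(net).reshape(-1) for net in networks])
    columns = [f"{roi}_{c}" for roi in roi_names for c in COEFFICIENTS]
    features = pd.DataFrame(rows, index=subject_ids, columns=columns)
    return RegionFeatureTable(
        features=features,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        covariates=None if covariates is None else np.asarray(covariates, dtype=float),
    )


def residualize_confounds(table: RegionFeatureTable,
                          covariates: np.ndarray | None = None) -> RegionFeatureTable:
    """Replace each feature column by its least-squares residual against
    [intercept, covariates], with the column mean added back."""
    covs = table.covariates if covariates is None else np.asarray(covariates, dtype=float)
    if covs is None:
        raise ValueError("no covariates available to residualize against")
    x = table.features.to_numpy(dtype=float)
    if covs.shape[0] != x.shape[0]:
        raise ValueError("covariate matrix must have one row per subject")
    design = np.column_stack([np.ones(len(covs)), covs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("rank-deficient covariate matrix; using pseudo-inverse",
                      RuntimeWarning)
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    resid += x.mean(axis=0, keepdims=True)
    features = pd.DataFrame(resid, index=table.features.index,
                            columns=table.features.columns)
    return RegionFeatureTable(features=features, labels=table.labels,
                              covariates=covs, selection=table.selection)


def ks_fdr_select(table: RegionFeatureTable, labels: np.ndarray | None = None,
                  q: float = 0.05) -> RegionFeatureTable:
    """Two-sample KS test per feature with Benjamini-Hochberg control.

    A column is selected when its BH-adjusted p-value falls below ``q``.
    """
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels are required for selection")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    x = table.features.to_numpy(dtype=float)
    g0, g1 = x[y == 0], x[y == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs at least 3 subjects for the KS test")
    method = "exact" if max(len(g0), len(g1)) <= _KS_EXACT_MAX_N else "asymp"

    d_stats = np.empty(x.shape[1])
    p_vals = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        res = stats.ks_2samp(g0[:, j], g1[:, j], method=method)
        d_stats[j], p_vals[j] = res.statistic, res.pvalue
    p_adj = stats.false_discovery_control(p_vals, method="bh")
    selection = pd.DataFrame({
        "feature": table.features.columns,
        "D": d_stats,
        "p": p_vals,
        "p_adj": p_adj,
        "selected": p_adj < q,
    })
    return RegionFeatureTable(features=table.features, labels=y,
                              covariates=table.covariates, selection=selection)
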