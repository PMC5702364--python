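"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different algorithmic route from the
package code it checks: accelerated proximal-gradient descent instead of
coordinate descent for the lasso, exhaustive pair/edge enumeration for
the hypergraph coefficients, uncompressed string relabeling for the WL
kernel, and brute-force subset enumeration for the selection objective.
"""

from itertools import combinations

import numpy as np


def prox_gradient_lasso(design, response, lam, target, n_iter=5000):
    """Minimize ||x - A w||^2 + lam*||w||_1 with w[target] pinned to 0.

    FISTA with the target coordinate projected to zero each step; run to
    high accuracy so its objective certifies the coordinate-descent
    solution.
    """
    a = np.asarray(design, float)
    x = np.asarray(response, float)
    lip = 2.0 * np.linalg.norm(a.T @ a, 2) + 1e-12
    w = np.zeros(a.shape[1])
    z = w.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = -2.0 * a.T @ (x - a @ z)
        v = z - grad / lip
        w_new = np.sign(v) * np.maximum(np.abs(v) - lam / lip, 0.0)
        w_new[target] = 0.0
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = w_new + (t - 1) / t_new * (w_new - w)
        w, t = w_new, t_new
    return w


def lasso_objective(design, response, lam, w):
    r = response - design @ w
    return float(r @ r + lam * np.sum(np.abs(w)))


def hcc_brute(network, v):
    """(HCC1, HCC2, HCC3) by exhaustive enumeration over pairs and edges."""
    edges = [set(e.nodes) for e in network.edges]
    star = [e for e in edges if v in e]
    neigh = set().union(*star) - {v} if star else set()
    n = len(neigh)
    h1 = h2 = 0.0
    if n >= 2:
        pairs = list(combinations(sorted(neigh), 2))
        c1 = sum(1 for u, t in pairs
                 if any(u in e and t in e and v not in e for e in edges))
        c2 = sum(1 for u, t in pairs
                 if any(u in e and t in e and v in e for e in edges))
        h1 = 2.0 * c1 / (n * (n - 1))
        h2 = 2.0 * c2 / (n * (n - 1))
    h3 = 0.0
    if len(star) > 1 and n > 0:
        covered = sum(len(e) - 1 for e in star)
        h3 = 2.0 * (covered - n) / (n * (len(star) - 1))
    return h1, h2, h3


def adjacency_brute(network):
    """Pairwise co-membership counts by exhaustive edge enumeration."""
    m = network.n_nodes
    a = np.zeros((m, m), dtype=int)
    for e in network.edges:
        for u, t in combinations(sorted(e.nodes), 2):
            a[u, t] += 1
            a[t, u] += 1
    return a


def wl_kernel_strings(graphs, h):
    """WL subtree kernel via uncompressed string labels (no codebook)."""
    adjs = [g.adjacency_lists() for g in graphs]
    labels = [[f"<{lab}>" for lab in g.labels] for g in graphs]
    n = len(graphs)
    k = np.zeros((n, n))
    for it in range(h + 1):
        hists = []
        for labs in labels:
            hist = {}
            for lab in labs:
                hist[lab] = hist.get(lab, 0) + 1
            hists.append(hist)
        for i in range(n):
            for j in range(n):
                k[i, j] += sum(c * hists[j].get(lab, 0)
                               for lab, c in hists[i].items())
        if it == h:
            break
        labels = [
            [labs[v] + "(" + ",".join(sorted(labs[u] for u in adj[v])) + ")"
             for v in range(len(labs))]
            for labs, adj in zip(labels, adjs)
        ]
    return k


def best_selection_value(scores0, scores1, K, t1, t2):
    """Max sum of selected scores over all subsets obeying the caps,
    considering only patterns with score >= K, by full enumeration."""
    best = 0.0
    c0 = [s for s in scores0 if s >= K]
    c1 = [s for s in scores1 if s >= K]
    for k0 in range(min(t1, len(c0)) + 1):
        for sub0 in combinations(c0, k0):
            for k1 in range(min(t2, len(c1)) + 1):
                for sub1 in combinations(c1, k1):
                    best = max(best, sum(sub0) + sum(sub1))
    return best


def auc_pairs(decisions, labels):
    """AUC by counting concordant pairs, ties worth 1/2."""
    pos = [d for d, y in zip(decisions, labels) if y == 1]
    neg = [d for d, y in zip(decisions, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def relief_brute(features, labels):
    """Classic Relief with every instance as anchor, explicit loops."""
    x = np.asarray(features, float)
    y = np.asarray(labels, int)
    rng_ = x.max(axis=0) - x.min(axis=0)
    rng_[rng_ == 0] = 1.0
    xs = (x - x.min(axis=0)) / rng_
    n, p = xs.shape
    w = np.zeros(p)
    for i in range(n):
        best_hit = best_miss = None
        for j in range(n):
            if j == i:
                continue
            d = np.sqrt(((xs[i] - xs[j]) ** 2).sum())
            if y[j] == y[i]:
                if best_hit is None or d < best_hit[0]:
                    best_hit = (d, j)
            else:
                if best_miss is None or d < best_miss[0]:
                    best_miss = (d, j)
        w += np.abs(xs[i] - xs[best_miss[1]]) - np.abs(xs[i] - xs[best_hit[1]])
    return w / n
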