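"""Multi-kernel SVM classification under repeated stratified k-fold CV.

Per outer fold, feature selection (KS+FDR over region features, FSFS
over subgraph patterns) runs on the training subjects only
(``selection_scope='fold'``, the default) so the reported metrics are
leakage-free; ``'global'`` scope performs one selection on the whole
cohort and is optimistically biased.  The kernel weight alpha and the
SVM cost are chosen per fold by an inner stratified CV grid search.
Metrics (accuracy, sensitivity, specificity from the pooled confusion
matrix; AUC from pooled decision values) are averaged arithmetically
over the repeats.  Label 1 (the patient group) is the positive class.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from hyperbrain.hypernet import HyperNetwork
from hyperbrain.kernels import (LabeledGraph, default_gamma, normalize_kernel,
                                rbf_kernel, wl_kernel, combine_kernels)
from hyperbrain.region_features import (compute_region_features, ks_fdr_select,
                                        residualize_confounds)

__all__ = [
    "CVConfig",
    "CVReport",
    "svm_fit_predict",
    "cross_validate",
    "roc_auc",
    "relief_weights",
    "permutation_test",
]

DEFAULT_COST_GRID = tuple(2.0 ** e for e in (-5, -3, -1, 1, 3, 5))
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    n_repeats: int = 100
    selection_scope: str = "fold"
    svm_cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    inner_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.selection_scope not in ("fold", "global"):
            raise ValueError("selection_scope must be 'fold' or 'global'")
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if any(c <= 0 for c in self.svm_cost_grid):
            raise ValueError("SVM costs must be positive")


@dataclass
class CVReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_repeat_accuracy: list[float]
    per_repeat_sensitivity: list[float]
    per_repeat_specificity: list[float]
    per_repeat_auc: list[float]
    chosen_alpha: list[list[float]]  # per repeat, per fold
    chosen_cost: list[list[float]]
    roc_points: list[tuple[float, float]]
    config: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def svm_fit_predict(train_kernel: np.ndarray, train_labels: np.ndarray,
                    test_kernel_rows: np.ndarray, cost: float = 1.0):
    """Fit a precomputed-kernel soft-margin SVM; return predictions and
    decision values for the test rows."""
    train_labels = np.asarray(train_labels, dtype=int)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training fold contains a single class")
    clf = SVC(C=cost, kernel="precomputed")
    clf.fit(train_kernel, train_labels)
    pred = clf.predict(test_kernel_rows)
    dec = clf.decision_function(test_kernel_rows)
    return pred, dec


def roc_auc(decision_values: np.ndarray, labels: np.ndarray):
    """AUC as the normalized Mann-Whitney U (midranks for ties) + ROC points."""
    decision_values = np.asarray(decision_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    if np.ptp(decision_values) == 0:
        warnings.warn("constant decision values; AUC is 0.5 by convention",
                      RuntimeWarning)
        return 0.5, [(0.0, 0.0), (1.0, 1.0)]
    ranks = rankdata(decision_values)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n0 * n1))
    fpr, tpr, _ = roc_curve(labels, decision_values)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def relief_weights(features: np.ndarray, labels: np.ndarray,
                   n_iterations: int | None = None, seed: int = 0) -> np.ndarray:
    """Classic Relief weights (nearest hit/miss on min-max scaled features).

    By default every instance serves as an anchor; ``n_iterations`` below
    n samples anchors without replacement from a seeded RNG.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    counts = Counter(y.tolist())
    if len(counts) != 2 or min(counts.values()) < 2:
        raise ValueError("Relief needs two classes with >= 2 instances each")
    rng_ = x.max(axis=0) - x.min(axis=0)
    rng_ = np.where(rng_ == 0, 1.0, rng_)
    xs = (x - x.min(axis=0)) / rng_

    n = len(xs)
    if n_iterations is None or n_iterations >= n:
        anchors = np.arange(n)
    else:
        anchors = np.random.default_rng(seed).choice(n, size=n_iterations,
                                                     replace=False)
    w = np.zeros(x.shape[1])
    for i in anchors:
        diffs = np.abs(xs - xs[i])
        dist = np.sqrt((diffs ** 2).sum(axis=1))
        dist[i] = np.inf
        same = y == y[i]
        hit = int(np.argmin(np.where(same, dist, np.inf)))
        miss = int(np.argmin(np.where(~same, dist, np.inf)))
        w += diffs[miss] - diffs[hit]
    return w / len(anchors)


def permutation_test(statistic, labels: np.ndarray, n_permutations: int = 999,
                     seed: int = 0) -> float:
    """p = (1 + #{permuted >= observed}) / (n_permutations + 1)."""
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    labels = np.asarray(labels)
    observed = float(statistic(labels))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if float(statistic(rng.permutation(labels))) >= observed:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# cross-validation of the full multi-kernel pipeline


def _rank_key(score: float, nodes: tuple[int, ...]):
    return (-score, len(nodes), nodes)


def _select_patterns(edge_sets: list[set[tuple[int, ...]]], train_idx: np.ndarray,
                     y: np.ndarray, K: float, match: str) -> set[tuple[int, ...]]:
    """Fold-local FSFS: balanced top-t patterns with score >= K.

    Equivalent to extract_patterns + score_catalog + fsfs_select on the
    training subjects, specialized for speed inside the CV loop.
    """
    tr0 = [edge_sets[i] for i in train_idx if y[i] == 0]
    tr1 = [edge_sets[i] for i in train_idx if y[i] == 1]
    if not tr0 or not tr1:
        return set()
    c0: Counter = Counter()
    c1: Counter = Counter()
    if match == "exact":
        for s in tr0:
            c0.update(s)
        for s in tr1:
            c1.update(s)
    else:  # superset matching: count subjects containing each pattern
        universe = set().union(*tr0, *tr1)
        for pat in universe:
            target = set(pat)
            c0[pat] = sum(1 for s in tr0 if any(target <= set(e) for e in s))
            c1[pat] = sum(1 for s in tr1 if any(target <= set(e) for e in s))
    ranked: dict[int, list[tuple[int, ...]]] = {0: [], 1: []}
    scores: dict[tuple[int, ...], float] = {}
    for grp, counter in ((0, c0), (1, c1)):
        cand = []
        for pat in counter:
            s = abs(c1[pat] / len(tr1) - c0[pat] / len(tr0))
            if s >= K:
                scores[pat] = s
                cand.append(pat)
        cand.sort(key=lambda p: _rank_key(scores[p], p))
        ranked[grp] = cand
    t = min(len(ranked[0]), len(ranked[1]))
    return set(ranked[0][:t]) | set(ranked[1][:t])


def _clique_graphs(edge_lists: list[list[tuple[int, ...]]], m: int,
                   selected: set[tuple[int, ...]]) -> list[LabeledGraph]:
    labels = tuple(range(m))
    graphs = []
    for edges in edge_lists:
        pair_edges: set[tuple[int, int]] = set()
        for nodes in edges:
            if nodes in selected:
                for a in range(len(nodes)):
                    for b in range(a + 1, len(nodes)):
                        pair_edges.add((nodes[a], nodes[b]))
        graphs.append(LabeledGraph(n_nodes=m, edges=pair_edges, labels=labels))
    return graphs


def _inner_accuracy(k_comb: np.ndarray, y: np.ndarray, train_idx: np.ndarray,
                    cost: float, inner_folds: int, rs: int) -> float:
    y_tr = y[train_idx]
    n_splits = min(inner_folds, int(np.bincount(y_tr).min()))
    if n_splits < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rs)
    correct = 0
    for sub_tr, sub_te in skf.split(np.zeros(len(train_idx)), y_tr):
        a, b = train_idx[sub_tr], train_idx[sub_te]
        pred, _ = svm_fit_predict(k_comb[np.ix_(a, a)], y[a],
                                  k_comb[np.ix_(b, a)], cost)
        correct += int((pred == y[b]).sum())
    return correct / len(train_idx)


def cross_validate(networks: list[HyperNetwork], labels: np.ndarray,
                   cv: CVConfig, *,
                   covariates: np.ndarray | None = None,
                   subject_ids: list[str] | None = None,
                   roi_names: list[str] | None = None,
                   K: float = 0.25, q: float = 0.05,
                   wl_iterations: int = 3, match: str = "exact",
                   gamma: float | None = None,
                   residualize: bool = False,
                   mode: str = "combined") -> CVReport:
    """Evaluate the multi-kernel pipeline by repeated stratified k-fold CV.

    ``mode`` restricts the classifier to a single view: ``'region'``
    pins alpha=1 (RBF kernel only), ``'subgraph'`` pins alpha=0 (WL
    kernel only), ``'combined'`` searches the alpha grid.
    """
    cv.validate()
    if mode not in ("combined", "region", "subgraph"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if len(networks) != n:
        raise ValueError("one network per label is required")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < cv.n_folds:
        raise ValueError("each class needs at least n_folds subjects")

    table = compute_region_features(networks, subject_ids=subject_ids,
                                    labels=y, covariates=covariates,
                                    roi_names=roi_names)
    if residualize:
        if covariates is None:
            raise ValueError("residualize=True requires covariates")
        table = residualize_confounds(table)
    feat_all = table.features.to_numpy(dtype=float)

    edge_sets = [net.edge_node_sets for net in networks]
    edge_lists = [sorted(s) for s in edge_sets]
    m_rois = networks[0].n_nodes

    global_cols = global_patterns = None
    if cv.selection_scope == "global":
        sel = ks_fdr_select(table, q=q)
        mask = sel.selection["selected"].to_numpy()
        global_cols = np.flatnonzero(mask)
        global_patterns = _select_patterns(edge_sets, np.arange(n), y, K, match)

    acc_r, sen_r, spe_r, auc_r = [], [], [], []
    alphas_r, costs_r = [], []
    all_dec: list[float] = []
    all_lab: list[int] = []

    for rep in range(cv.n_repeats):
        rs = int(np.random.SeedSequence((cv.seed, rep)).generate_state(1)[0]
                 % (2 ** 31 - 1))
        skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=rs)
        tp = tn = fp = fn = 0
        rep_dec: list[float] = []
        rep_lab: list[int] = []
        rep_alpha: list[float] = []
        rep_cost: list[float] = []

        for fold_i, (train_idx, test_idx) in enumerate(
                skf.split(np.zeros(n), y)):
            if cv.selection_scope == "fold":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    sel = ks_fdr_select(
                        _subset_table(table, train_idx), q=q)
                cols = np.flatnonzero(sel.selection["selected"].to_numpy())
                patterns = _select_patterns(edge_sets, train_idx, y, K, match)
            else:
                cols, patterns = global_cols, global_patterns

            k_region = None
            if cols is not None and len(cols) > 0:
                sub = feat_all[:, cols]
                g = gamma if gamma is not None else default_gamma(sub[train_idx])
                if g <= 0:
                    g = 1.0 / max(len(cols), 1)
                k_region = normalize_kernel(rbf_kernel(sub, g))
            k_sub = None
            if patterns:
                graphs = _clique_graphs(edge_lists, m_rois, patterns)
                k_sub = normalize_kernel(wl_kernel(graphs, wl_iterations))

            if mode == "region":
                k_region_eff, k_sub_eff = k_region, None
                alpha_cand = (1.0,) if k_region is not None else ()
            elif mode == "subgraph":
                k_region_eff, k_sub_eff = None, k_sub
                alpha_cand = (0.0,) if k_sub is not None else ()
            else:
                k_region_eff, k_sub_eff = k_region, k_sub
                if k_region is not None and k_sub is not None:
                    alpha_cand = cv.alpha_grid
                elif k_region is None and k_sub is None:
                    alpha_cand = ()
                elif k_region is None:
                    # only alpha=0 is realizable without the region view
                    alpha_cand = (0.0,) if 0.0 in cv.alpha_grid else ()
                else:
                    alpha_cand = (1.0,) if 1.0 in cv.alpha_grid else ()

            if not alpha_cand:
                # no usable view in this fold: majority-class fallback
                maj = int(np.bincount(y[train_idx]).argmax())
                pred = np.full(len(test_idx), maj)
                dec = np.zeros(len(test_idx))
                rep_alpha.append(float("nan"))
                rep_cost.append(float("nan"))
            else:
                best = None
                for alpha in alpha_cand:
                    k_comb = combine_kernels(k_region_eff, k_sub_eff, alpha) \
                        if (k_region_eff is not None and k_sub_eff is not None) \
                        else (k_region_eff if alpha == 1.0 or k_sub_eff is None
                              else k_sub_eff)
                    for cost in cv.svm_cost_grid:
                        if len(alpha_cand) == 1 and len(cv.svm_cost_grid) == 1:
                            score = 0.0
                        else:
                            score = _inner_accuracy(k_comb, y, train_idx, cost,
                                                    cv.inner_folds, rs + fold_i)
                        if best is None or score > best[0]:
                            best = (score, alpha, cost, k_comb)
                _, alpha, cost, k_comb = best
                pred, dec = svm_fit_predict(
                    k_comb[np.ix_(train_idx, train_idx)], y[train_idx],
                    k_comb[np.ix_(test_idx, train_idx)], cost)
                rep_alpha.append(float(alpha))
                rep_cost.append(float(cost))

            truth = y[test_idx]
            tp += int(((pred == 1) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
            rep_dec.extend(np.asarray(dec, dtype=float).tolist())
            rep_lab.extend(truth.tolist())

        acc_r.append((tp + tn) / n)
        sen_r.append(tp / (tp + fn) if tp + fn else 0.0)
        spe_r.append(tn / (tn + fp) if tn + fp else 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            auc, _ = roc_auc(np.array(rep_dec), np.array(rep_lab))
        auc_r.append(auc)
        alphas_r.append(rep_alpha)
        costs_r.append(rep_cost)
        all_dec.extend(rep_dec)
        all_lab.extend(rep_lab)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, roc_points = roc_auc(np.array(all_dec), np.array(all_lab))
    return CVReport(
        accuracy=float(np.mean(acc_r)),
        sensitivity=float(np.mean(sen_r)),
        specificity=float(np.mean(spe_r)),
        auc=float(np.mean(auc_r)),
        per_repeat_accuracy=[float(v) for v in acc_r],
        per_repeat_sensitivity=[float(v) for v in sen_r],
        per_repeat_specificity=[float(v) for v in spe_r],
        per_repeat_auc=[float(v) for v in auc_r],
        chosen_alpha=alphas_r,
        chosen_cost=costs_r,
        roc_points=roc_points,
        config={
            "n_folds": cv.n_folds, "n_repeats": cv.n_repeats,
            "selection_scope": cv.selection_scope, "seed": cv.seed,
            "K": K, "q": q, "wl_iterations": wl_iterations,
            "match": match, "mode": mode,
            "alpha_grid": [float(a) for a in cv.alpha_grid],
            "svm_cost_grid": [float(c) for c in cv.svm_cost_grid],
        },
    )


def _subset_table(table, idx: np.ndarray):
    from hyperbrain.region_features import RegionFeatureTable
    return RegionFeatureTable(
        features=table.features.iloc[idx],
        labels=table.labels[idx],
        covariates=None if table.covariates is None else table.covariates[idx],
    )
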