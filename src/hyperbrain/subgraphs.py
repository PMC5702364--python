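"""Discriminative hyper-edge (subgraph) patterns and FSFS selection.

Each subject's hyper-edges are treated as subgraph patterns: canonical
sorted node sets.  Within each group the union of all subjects' patterns
is deduplicated.  A pattern's frequency in a group is the fraction of
that group's subjects whose hyper-network contains an edge with exactly
that node set, and its discriminative score is

    S(g) = | fq(g | group 1) - fq(g | group 0) |.

Selection ranks each group's patterns by score, keeps those with
S(g) >= K, and (optionally) truncates both groups to the same count t so
the selected set is balanced.  Because the selection objective
J(T) = sum of selected scores is additive, taking the top-t per group is
the exact maximizer under per-group cardinality caps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hyperbrain.hypernet import HyperNetwork

__all__ = [
    "SubgraphPattern",
    "SubgraphCatalog",
    "extract_patterns",
    "pattern_frequency",
    "discriminative_score",
    "fsfs_select",
]


@dataclass(frozen=True)
class SubgraphPattern:
    """A canonical hyper-edge node set, tagged with its source group."""

    nodes: tuple[int, ...]
    source_group: int

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValueError("patterns must contain at least two nodes")
        if tuple(sorted(set(self.nodes))) != self.nodes:
            raise ValueError("pattern nodes must be sorted and unique")


@dataclass
class SubgraphCatalog:
    """Patterns with per-group frequencies, scores, and selection state."""

    patterns: list[SubgraphPattern]
    freq_group0: np.ndarray = field(default_factory=lambda: np.empty(0))
    freq_group1: np.ndarray = field(default_factory=lambda: np.empty(0))
    score: np.ndarray = field(default_factory=lambda: np.empty(0))
    selected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    K: float = 0.0
    t1: int | None = None
    t2: int | None = None

    @property
    def selected_patterns(self) -> list[SubgraphPattern]:
        return [p for p, s in zip(self.patterns, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pattern": [",".join(map(str, p.nodes)) for p in self.patterns],
            "source_group": [p.source_group for p in self.patterns],
            "freq_group0": self.freq_group0,
            "freq_group1": self.freq_group1,
            "score": self.score,
            "selected": self.selected,
        })


def _edge_sets(network: HyperNetwork) -> set[tuple[int, ...]]:
    return network.edge_node_sets


def extract_patterns(networks_group0: list[HyperNetwork],
                     networks_group1: list[HyperNetwork]) -> SubgraphCatalog:
    """Union of hyper-edge node sets per group, deduplicated within group."""
    for grp, nets in ((0, networks_group0), (1, networks_group1)):
        if not nets or all(not n.edges for n in nets):
            raise ValueError(f"group {grp} has no hyper-edges to extract patterns from")

    patterns: list[SubgraphPattern] = []
    for grp, nets in ((0, networks_group0), (1, networks_group1)):
        seen: set[tuple[int, ...]] = set()
        for net in nets:
            seen |= _edge_sets(net)
        patterns.extend(SubgraphPattern(nodes=n, source_group=grp)
                        for n in sorted(seen))
    return SubgraphCatalog(patterns=patterns)


def pattern_frequency(pattern: SubgraphPattern | tuple[int, ...],
                      networks: list[HyperNetwork],
                      match: str = "exact") -> float:
    """Fraction of the group's subjects whose network contains the pattern.

    ``match='exact'`` requires a hyper-edge with exactly the pattern's
    node set; ``match='superset'`` accepts any hyper-edge containing it.
    """
    if not networks:
        raise ValueError("empty group")
    nodes = pattern.nodes if isinstance(pattern, SubgraphPattern) else tuple(sorted(pattern))
    if match == "exact":
        count = sum(1 for net in networks if nodes in _edge_sets(net))
    elif match == "superset":
        target = set(nodes)
        count = sum(1 for net in networks
                    if any(target <= e.nodes for e in net.edges))
    else:
        raise ValueError(f"unknown match mode {match!r}")
    return count / len(networks)


def discriminative_score(pattern: SubgraphPattern | tuple[int, ...],
                         networks_group0: list[HyperNetwork],
                         networks_group1: list[HyperNetwork],
                         match: str = "exact") -> float:
    """|fq(g | group 1) - fq(g | group 0)|; symmetric under group swap."""
    f0 = pattern_frequency(pattern, networks_group0, match)
    f1 = pattern_frequency(pattern, networks_group1, match)
    return abs(f1 - f0)


def score_catalog(catalog: SubgraphCatalog,
                  networks_group0: list[HyperNetwork],
                  networks_group1: list[HyperNetwork],
                  match: str = "exact") -> SubgraphCatalog:
    """Fill per-group frequencies and discriminative scores."""
    sets0 = [_edge_sets(n) for n in networks_group0]
    sets1 = [_edge_sets(n) for n in networks_group1]
    f0 = np.empty(len(catalog.patterns))
    f1 = np.empty(len(catalog.patterns))
    for i, p in enumerate(catalog.patterns):
        if match == "exact":
            f0[i] = sum(1 for s in sets0 if p.nodes in s) / len(sets0)
            f1[i] = sum(1 for s in sets1 if p.nodes in s) / len(sets1)
        else:
            target = set(p.nodes)
            f0[i] = sum(1 for s in sets0 if any(target <= set(e) for e in s)) / len(sets0)
            f1[i] = sum(1 for s in sets1 if any(target <= set(e) for e in s)) / len(sets1)
    catalog.freq_group0 = f0
    catalog.freq_group1 = f1
    catalog.score = np.abs(f1 - f0)
    catalog.selected = np.zeros(len(catalog.patterns), dtype=bool)
    return catalog


def _rank_key(score: float, pattern: SubgraphPattern):
    # descending score; ties broken by smaller pattern, then lexicographic
    return (-score, len(pattern.nodes), pattern.nodes)


def fsfs_select(catalog: SubgraphCatalog, K: float = 0.25,
                balance: bool = True) -> SubgraphCatalog:
    """Threshold at K, rank by score per group, optionally balance counts.

    With ``balance`` on, both groups keep t = min(count0, count1) top
    patterns (t1 = t2 = t).  Because the selection objective is the sum of
    the selected scores, per-group top-t is the exact maximizer under the
    cardinality caps.
    """
    if not 0 <= K <= 1:
        raise ValueError("K must lie in [0, 1]")
    if catalog.score.size != len(catalog.patterns):
        raise ValueError("catalog is unscored; call score_catalog first")

    order: dict[int, list[int]] = {0: [], 1: []}
    for grp in (0, 1):
        idx = [i for i, p in enumerate(catalog.patterns)
               if p.source_group == grp and catalog.score[i] >= K]
        idx.sort(key=lambda i: _rank_key(catalog.score[i], catalog.patterns[i]))
        order[grp] = idx

    t1, t2 = len(order[0]), len(order[1])
    if balance:
        t = min(t1, t2)
        t1 = t2 = t
    selected = np.zeros(len(catalog.patterns), dtype=bool)
    selected[order[0][:t1]] = True
    selected[order[1][:t2]] = True
    if not selected.any():
        warnings.warn(f"no subgraph pattern passes the score threshold K={K}",
                      RuntimeWarning)
    return SubgraphCatalog(patterns=catalog.patterns,
                           freq_group0=catalog.freq_group0,
                           freq_group1=catalog.freq_group1,
                           score=catalog.score, selected=selected,
                           K=K, t1=t1, t2=t2)
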