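"""Interaction-network structure: weighted nestedness, unipartite projection,
modularity and Louvain module detection, host-breadth summaries.

Weighted nestedness follows the WNODF family: for every ordered pair of rows
with strictly decreasing row totals, the pair contributes the percentage of
columns in which the poorer row holds a positive count strictly smaller than
the richer row's count; likewise over column pairs; ties in totals contribute
zero. The average over all row and column pairs, rescaled to [0, 1], is the
statistic. Significance comes from a fixed-marginal null ensemble: a network is
*antinested* when its observed value falls below the null interval.

The unipartite projection collapses the bipartite plant-fungus matrix onto
plant nodes: each fungus shared by two plant genera contributes the smaller of
its two observation counts to their edge, minima summed over fungi; every
fungus also contributes its full count to the self-loop of each host, so
host-specific fungi stay in the graph instead of vanishing. Modularity Q uses
the convention in which a self-loop counts once in the total weight and twice
in its node's strength, matching mainstream graph libraries so printed Q
values are comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .nullmodels import NullEnsemble, null_interval
from .records import InteractionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weighted nestedness (WNODF)

def _axis_nestedness(X: np.ndarray) -> tuple[float, int]:
    """Sum of pair contributions (in percent) and pair count over rows of X."""
    n = X.shape[0]
    if n < 2:
        return 0.0, 0
    totals = X.sum(axis=1)
    # comp[i, j, k] = True where row j has 0 < X[j, k] < X[i, k]
    comp = (X[None, :, :] > 0) & (X[None, :, :] < X[:, None, :])
    frac = comp.mean(axis=2) * 100.0
    decreasing = totals[:, None] > totals[None, :]
    return float(frac[decreasing].sum()), n * (n - 1) // 2


def weighted_nestedness(m: InteractionMatrix | np.ndarray) -> float:
    """WNODF of a count matrix, rescaled to [0, 1]."""
    X = m.counts if isinstance(m, InteractionMatrix) else np.asarray(m)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("nestedness needs a 2-D matrix")
    rows_ok = (X.sum(axis=1) > 0).sum() >= 2
    cols_ok = (X.sum(axis=0) > 0).sum() >= 2
    if not (rows_ok or cols_ok):
        raise ValidationError(
            "nestedness is undefined for a single-row-and-column matrix"
        )
    row_sum, row_pairs = _axis_nestedness(X)
    col_sum, col_pairs = _axis_nestedness(X.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs) / 100.0


@dataclass(frozen=True)
class NestednessResult:
    observed: float
    null_lo: float
    null_hi: float
    null_mean: float
    p: float
    direction: str  # antinested | nested | ns
    level: float
    n_samples: int
    seed: Optional[int] = None


def nestedness_test(
    m: InteractionMatrix | np.ndarray,
    ensemble: NullEnsemble,
    level: float = 0.95,
    statistic=weighted_nestedness,
) -> NestednessResult:
    """Two-sided fixed-marginal randomization test of weighted nestedness.

    The empirical p is 2 * min(frac null <= obs, frac null >= obs) with the
    add-one correction, capped at 1. Direction is "antinested" when the
    observed value lies below the null interval with p < 1 - level, "nested"
    for the mirror case, else "ns". ``statistic`` makes the metric pluggable:
    any callable mapping a count matrix to a real number (weighted-nestedness
    conventions differ between implementations, e.g. in whether decreasing
    fill is required on top of decreasing marginal totals).
    """
    observed = statistic(m)
    nulls = np.array([statistic(s) for s in ensemble])
    lo, hi = null_interval(nulls, level=level)
    n = nulls.size
    p_low = (1 + (nulls <= observed).sum()) / (1 + n)
    p_high = (1 + (nulls >= observed).sum()) / (1 + n)
    p = float(min(1.0, 2.0 * min(p_low, p_high)))
    alpha = 1.0 - level
    if observed < lo and p < alpha:
        direction = "antinested"
    elif observed > hi and p < alpha:
        direction = "nested"
    else:
        direction = "ns"
    return NestednessResult(
        observed=float(observed),
        null_lo=lo,
        null_hi=hi,
        null_mean=float(nulls.mean()),
        p=p,
        direction=direction,
        level=level,
        n_samples=n,
        seed=ensemble.seed,
    )


def write_nestedness_report(result: NestednessResult, path) -> None:
    payload = {
        "observed": result.observed,
        "null_interval": [result.null_lo, result.null_hi],
        "null_mean": result.null_mean,
        "p": result.p,
        "direction": result.direction,
        "level": result.level,
        "n_samples": result.n_samples,
        "seed": result.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Unipartite projection

@dataclass(frozen=True)
class UnipartiteGraph:
    """Weighted plant-plant projection with self-loops.

    ``weights`` maps sorted node pairs (u, v) with u <= v to positive integer
    weights; (g, g) pairs are self-loops. ``link_records`` keeps the
    per-fungus links (fungus, u, v, weight) the aggregate edges were summed
    from, for rendering and audit.
    """

    status: Mapping[str, str]
    weights: Mapping[tuple[str, str], int]
    region: str = ""
    link_records: tuple[tuple[str, str, str, int], ...] = ()

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.status)

    def edge_weight(self, u: str, v: str) -> int:
        return int(self.weights.get((min(u, v), max(u, v)), 0))

    def total_weight(self) -> float:
        """Sum of edge weights, each non-loop edge and each loop counted once."""
        return float(sum(self.weights.values()))

    def strengths(self) -> dict[str, float]:
        """Node strength: incident non-loop weight + 2 x self-loop weight."""
        s = {v: 0.0 for v in self.status}
        for (u, v), w in self.weights.items():
            if u == v:
                s[u] += 2.0 * w
            else:
                s[u] += w
                s[v] += w
        return s

    def to_networkx(self, include_self_loops: bool = True) -> nx.Graph:
        g = nx.Graph(region=self.region)
        for node, status in self.status.items():
            g.add_node(node, status=status)
        for (u, v), w in self.weights.items():
            if u == v and not include_self_loops:
                continue
            g.add_edge(u, v, weight=int(w))
        return g


def project_unipartite(m: InteractionMatrix) -> UnipartiteGraph:
    """Project the bipartite count matrix onto plant genera.

    For each fungus f and unordered genus pair (g, h) with positive counts on
    both, min(m[g,f], m[h,f]) is added to edge (g, h); each genus hosting f
    gains m[g,f] on its self-loop. Edges aggregate over fungi by summation.
    """
    if m.counts.size == 0:
        raise ValidationError("cannot project an empty matrix")
    genera = m.row_labels
    weights: dict[tuple[str, str], int] = {}
    links: list[tuple[str, str, str, int]] = []
    for j, fungus in enumerate(m.col_labels):
        col = m.counts[:, j]
        hosts = np.flatnonzero(col)
        for a_idx, a in enumerate(hosts):
            g = genera[a]
            w_loop = int(col[a])
            weights[(g, g)] = weights.get((g, g), 0) + w_loop
            links.append((fungus, g, g, w_loop))
            for b in hosts[a_idx + 1 :]:
                h = genera[b]
                w = int(min(col[a], col[b]))
                key = (min(g, h), max(g, h))
                weights[key] = weights.get(key, 0) + w
                links.append((fungus, key[0], key[1], w))
    return UnipartiteGraph(
        status=dict(m.row_status),
        weights=weights,
        region=m.region,
        link_records=tuple(links),
    )


# ---------------------------------------------------------------------------
# Modularity and Louvain

def modularity(g: UnipartiteGraph, partition: Mapping[str, int]) -> float:
    """Weighted modularity Q of a node partition.

    Q = sum_c [ w_in(c)/W - (s(c) / 2W)^2 ], with W the total edge weight
    (loops once), w_in(c) the within-module weight (loops once) and s(c) the
    summed node strengths (loops twice).
    """
    missing = [v for v in g.status if v not in partition]
    if missing:
        raise ValidationError(f"partition missing nodes: {missing}")
    W = g.total_weight()
    if W == 0:
        raise ValidationError("graph has no edge weight")
    strengths = g.strengths()
    w_in: dict[int, float] = {}
    s: dict[int, float] = {}
    for v, st in strengths.items():
        s[partition[v]] = s.get(partition[v], 0.0) + st
    for (u, v), w in g.weights.items():
        if partition[u] == partition[v]:
            w_in[partition[u]] = w_in.get(partition[u], 0.0) + w
    q = 0.0
    for c in s:
        q += w_in.get(c, 0.0) / W - (s[c] / (2.0 * W)) ** 2
    return float(q)


@dataclass(frozen=True)
class ModulePartition:
    assignment: Mapping[str, int]
    Q: float
    n_modules: int
    seed: Optional[int]
    n_restarts: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, []).append(v)
        return out


def _canonicalize(assignment: Mapping[str, int], node_order: Sequence[str]) -> dict[str, int]:
    """Renumber modules by first appearance in node order (ids contiguous)."""
    relabel: dict[int, int] = {}
    out = {}
    for v in node_order:
        c = assignment[v]
        if c not in relabel:
            relabel[c] = len(relabel)
        out[v] = relabel[c]
    return out


def louvain_partition(
    g: UnipartiteGraph,
    seed: Optional[int] = None,
    n_restarts: int = 100,
    include_self_loops: bool = True,
) -> ModulePartition:
    """Best-of-restarts Louvain module detection.

    Louvain's greedy two-phase heuristic is run ``n_restarts`` times with
    sub-seeds derived from ``seed``; each candidate is scored with
    :func:`modularity` and the maximum-Q partition returned. Ties (within
    1e-12) break to the lexicographically smallest canonical labelling, so
    results are reproducible.
    """
    if not g.status:
        raise ValidationError("graph has no nodes")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    node_order = list(g.status)
    nxg = g.to_networkx(include_self_loops=include_self_loops)
    score_graph = g
    if not include_self_loops:
        score_graph = UnipartiteGraph(
            status=dict(g.status),
            weights={k: w for k, w in g.weights.items() if k[0] != k[1]},
            region=g.region,
        )
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
    best_q = -np.inf
    best_key: Optional[tuple[int, ...]] = None
    best_assignment: Optional[dict[str, int]] = None
    for sub in sub_seeds:
        communities = nx.community.louvain_communities(
            nxg, weight="weight", seed=sub
        )
        assignment = {}
        for c, members in enumerate(communities):
            for v in members:
                assignment[v] = c
        canon = _canonicalize(assignment, node_order)
        q = modularity(score_graph, canon)
        key = tuple(canon[v] for v in node_order)
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and key < best_key):
            best_q, best_key, best_assignment = q, key, canon
    assert best_assignment is not None
    return ModulePartition(
        assignment=best_assignment,
        Q=float(best_q),
        n_modules=len(set(best_assignment.values())),
        seed=seed,
        n_restarts=n_restarts,
    )


# ---------------------------------------------------------------------------
# Host breadth

def host_breadth_summary(m: InteractionMatrix) -> dict[str, float]:
    """Mean fungal host breadth per plant status group.

    Host breadth of a fungal taxon is the number of plant genera it occurs on.
    Each taxon-genus occurrence attributes the taxon's breadth to that genus's
    status group, so a fungus shared by a native and an alien counts in both
    group means.
    """
    if m.counts.size == 0:
        raise ValidationError("empty matrix")
    presence = m.counts > 0
    breadth = presence.sum(axis=0)  # per fungal taxon
    statuses = m.status_array()
    out: dict[str, float] = {}
    for status in np.unique(statuses):
        rows = statuses == status
        # every (taxon, genus) occurrence within the group contributes breadth
        occ = presence[rows]
        weights = occ.sum(axis=0)
        total_occ = weights.sum()
        if total_occ == 0:
            out[str(status)] = float("nan")
        else:
            out[str(status)] = float((breadth * weights).sum() / total_occ)
    return out


# ---------------------------------------------------------------------------
# Writers

def write_edge_list_csv(g: UnipartiteGraph, path) -> None:
    rows = [
        {"u": u, "v": v, "weight": w, "is_loop": u == v}
        for (u, v), w in sorted(g.weights.items())
    ]
    pd.DataFrame(rows, columns=["u", "v", "weight", "is_loop"]).to_csv(path, index=False)


def write_graphml(g: UnipartiteGraph, path) -> None:
    nx.write_graphml(g.to_networkx(), path)


def write_partition_csv(g: UnipartiteGraph, partition: ModulePartition, path) -> None:
    rows = [
        {"node": v, "status": g.status[v], "module": partition.assignment[v]}
        for v in g.status
    ]
    pd.DataFrame(rows, columns=["node", "status", "module"]).to_csv(path, index=False)
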