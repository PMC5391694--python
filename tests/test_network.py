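"""Nestedness, projection, modularity, Louvain and host breadth."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from symbionet.errors import ValidationError
from symbionet.network import (
    ModulePartition,
    UnipartiteGraph,
    host_breadth_summary,
    louvain_partition,
    modularity,
    nestedness_test,
    project_unipartite,
    weighted_nestedness,
)
from symbionet.nullmodels import NullEnsemble, sample_null

from conftest import make_matrix


def wnodf_oracle(X):
    """Straight-from-definition weighted nestedness, nested python loops."""
    X = np.asarray(X, dtype=float)

    def axis_pairs(M):
        total = 0.0
        n, c = M.shape
        for i in range(n):
            for j in range(n):
                if M[i].sum() > M[j].sum():
                    hits = sum(1 for k in range(c) if 0 < M[j, k] < M[i, k])
                    total += 100.0 * hits / c
        return total, n * (n - 1) // 2

    rsum, rpairs = axis_pairs(X)
    csum, cpairs = axis_pairs(X.T)
    return (rsum + csum) / (rpairs + cpairs) / 100.0


def graph_from_weights(weights, statuses=None):
    nodes = sorted({v for k in weights for v in k})
    statuses = statuses or {v: "native" for v in nodes}
    return UnipartiteGraph(status=statuses, weights=dict(weights))


def all_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def brute_force_max_q(g):
    best = -np.inf
    for part in all_partitions(list(g.status)):
        q = modularity(g, {v: i for i, blk in enumerate(part) for v in blk})
        best = max(best, q)
    return best


class TestWeightedNestedness:
    def test_fully_tied_marginals_give_zero(self):
        # all row totals equal and all column totals equal: the strictly
        # decreasing-total condition never holds, every pair contributes 0
        tied = np.array([[2, 2], [2, 2]])
        assert weighted_nestedness(tied) == 0.0
        assert weighted_nestedness(np.array([[1, 2], [2, 1]])) == 0.0

    def test_triangular_matrix_matches_oracle(self):
        m = np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        assert weighted_nestedness(m) == pytest.approx(wnodf_oracle(m), abs=1e-12)
        # and the oracle value is the hand-derived 4/9
        assert wnodf_oracle(m) == pytest.approx(4 / 9, abs=1e-12)

    @given(
        hnp.arrays(
            np.int64,
            st.tuples(st.integers(2, 6), st.integers(2, 7)),
            elements=st.integers(0, 8),
        ).filter(
            lambda m: (m.sum(axis=1) > 0).sum() >= 2 or (m.sum(axis=0) > 0).sum() >= 2
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_random(self, m):
        assert weighted_nestedness(m) == pytest.approx(wnodf_oracle(m), abs=1e-12)

    def test_invariant_to_simultaneous_permutation(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 9, size=(5, 5))
        rp = rng.permutation(5)
        cp = rng.permutation(5)
        assert weighted_nestedness(m[rp][:, cp]) == pytest.approx(
            weighted_nestedness(m), abs=1e-12
        )

    def test_degenerate_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            weighted_nestedness(np.array([[3]]))


class TestNestednessTest:
    def test_degenerate_ensemble_ns(self):
        m = np.array([[3, 1, 0], [1, 2, 2]])
        ens = NullEnsemble(
            samples=tuple(m.copy() for _ in range(99)),
            burn_in=0,
            n_samples=99,
            thin=1,
            seed=0,
            source_dims=m.shape,
        )
        res = nestedness_test(m, ens)
        assert res.direction == "ns"
        assert res.p == 1.0

    def test_observed_below_all_nulls_addone_p(self):
        m = np.array([[3, 1, 0], [1, 2, 2]])
        obs = weighted_nestedness(m)
        nulls = [m + 0 for _ in range(999)]
        # synthetic ensemble whose statistic is strictly above the observed:
        # shift via a matrix with a strictly larger statistic
        high = np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        ens = NullEnsemble(
            samples=tuple(high.copy() for _ in range(999)),
            burn_in=0,
            n_samples=999,
            thin=1,
            seed=0,
            source_dims=high.shape,
        )
        res = nestedness_test(m, ens)
        assert weighted_nestedness(high) > obs
        assert res.p == pytest.approx(2 * (1 / 1000))
        assert res.direction == "antinested"

    def test_real_ensemble_consistency(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 6, size=(5, 8))
        ens = sample_null(m, burn_in=99, n_samples=199, seed=2)
        res = nestedness_test(m, ens)
        assert res.null_lo <= res.null_hi
        assert 0 < res.p <= 1.0


class TestProjection:
    def test_worked_example_min_weighting_and_loops(self):
        m = make_matrix([[15], [3]], ["native", "alien"], row_labels=["PG1", "PG2"])
        g = project_unipartite(m)
        assert g.edge_weight("PG1", "PG2") == 3
        assert g.edge_weight("PG1", "PG1") == 15
        assert g.edge_weight("PG2", "PG2") == 3

    def test_host_specific_fungus_only_self_loop(self):
        m = make_matrix([[4], [0]], ["native", "alien"], row_labels=["PG1", "PG2"])
        g = project_unipartite(m)
        assert g.edge_weight("PG1", "PG1") == 4
        assert g.edge_weight("PG1", "PG2") == 0
        assert "PG2" in g.status  # node kept even without edges

    def test_multiple_fungi_sum_minima(self):
        m = make_matrix(
            [[15, 2], [3, 5]], ["native", "alien"], row_labels=["PG1", "PG2"]
        )
        g = project_unipartite(m)
        assert g.edge_weight("PG1", "PG2") == 3 + 2

    def test_loop_conservation(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.integers(0, 7, (4, 9)), ["native"] * 2 + ["alien"] * 2)
        g = project_unipartite(m)
        loops = sum(w for (u, v), w in g.weights.items() if u == v)
        assert loops == m.total()

    @given(
        hnp.arrays(
            np.int64,
            st.tuples(st.integers(2, 4), st.integers(1, 6)),
            elements=st.integers(0, 6),
        ),
        st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_observations(self, counts, data):
        m = make_matrix(counts, ["native"] * counts.shape[0])
        g1 = project_unipartite(m)
        i = data.draw(st.integers(0, counts.shape[0] - 1))
        j = data.draw(st.integers(0, counts.shape[1] - 1))
        bumped = counts.copy()
        bumped[i, j] += 1
        g2 = project_unipartite(make_matrix(bumped, ["native"] * counts.shape[0]))
        for key, w in g1.weights.items():
            assert g2.weights.get(key, 0) >= w

    def test_link_records_retained_per_fungus(self):
        m = make_matrix(
            [[15, 2], [3, 5]], ["native", "alien"], row_labels=["PG1", "PG2"]
        )
        g = project_unipartite(m)
        cross = [r for r in g.link_records if r[1] != r[2]]
        assert sorted(r[3] for r in cross) == [2, 3]


class TestModularity:
    def test_single_module_q_zero(self):
        g = graph_from_weights({("a", "b"): 3, ("b", "c"): 1, ("a", "a"): 5})
        q = modularity(g, {"a": 0, "b": 0, "c": 0})
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_q_half(self):
        w = {}
        for u, v in itertools.combinations("abc", 2):
            w[(u, v)] = 1
        for u, v in itertools.combinations("def", 2):
            w[(u, v)] = 1
        g = graph_from_weights(w)
        part = {v: (0 if v in "abc" else 1) for v in "abcdef"}
        assert modularity(g, part) == pytest.approx(0.5, abs=1e-12)

    def test_singleton_partition_negative_without_loops(self):
        w = {("a", "b"): 2, ("b", "c"): 1, ("c", "a"): 4}
        g = graph_from_weights(w)
        q = modularity(g, {"a": 0, "b": 1, "c": 2})
        assert q < 0

    def test_matches_networkx_with_self_loops(self):
        rng = np.random.default_rng(7)
        nodes = list("abcdef")
        w = {}
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < 0.6:
                w[(u, v)] = int(rng.integers(1, 9))
        for v in nodes:
            if rng.random() < 0.5:
                w[(v, v)] = int(rng.integers(1, 9))
        g = graph_from_weights(w)
        part = {v: int(rng.integers(0, 3)) for v in nodes}
        communities = {}
        for v, c in part.items():
            communities.setdefault(c, set()).add(v)
        ref = nx.community.modularity(
            g.to_networkx(), communities.values(), weight="weight"
        )
        assert modularity(g, part) == pytest.approx(ref, abs=1e-12)

    def test_missing_node_rejected(self):
        g = graph_from_weights({("a", "b"): 1})
        with pytest.raises(ValidationError):
            modularity(g, {"a": 0})


class TestLouvain:
    def test_two_cliques_found(self):
        w = {}
        for u, v in itertools.combinations("abcd", 2):
            w[(u, v)] = 5
        for u, v in itertools.combinations("efgh", 2):
            w[(u, v)] = 5
        w[("a", "e")] = 1
        g = graph_from_weights(w)
        part = louvain_partition(g, seed=0, n_restarts=20)
        assert part.n_modules == 2
        assert len({part.assignment[v] for v in "abcd"}) == 1
        assert len({part.assignment[v] for v in "efgh"}) == 1
        # internal consistency: stored Q equals recomputed modularity
        assert part.Q == pytest.approx(modularity(g, part.assignment), abs=1e-12)

    def test_never_beats_brute_force_small(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(3, 7))
            nodes = [f"n{i}" for i in range(n)]
            w = {}
            for u, v in itertools.combinations(nodes, 2):
                if rng.random() < 0.5:
                    w[(u, v)] = int(rng.integers(1, 10))
            for v in nodes:
                if rng.random() < 0.3:
                    w[(v, v)] = int(rng.integers(1, 10))
            if not w:
                continue
            g = UnipartiteGraph(
                status={v: "native" for v in nodes},
                weights=w,
            )
            part = louvain_partition(g, seed=3, n_restarts=30)
            assert part.Q <= brute_force_max_q(g) + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        w = {}
        nodes = list("abcdefg")
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < 0.4:
                w[(u, v)] = int(rng.integers(1, 6))
        g = graph_from_weights(w)
        p1 = louvain_partition(g, seed=42, n_restarts=10)
        p2 = louvain_partition(g, seed=42, n_restarts=10)
        assert p1.assignment == p2.assignment and p1.Q == p2.Q

    def test_module_ids_contiguous_first_seen(self):
        w = {("a", "b"): 3, ("c", "d"): 3}
        g = graph_from_weights(w)
        part = louvain_partition(g, seed=0, n_restarts=5)
        assert part.assignment["a"] == 0
        assert sorted(set(part.assignment.values())) == list(range(part.n_modules))


class TestHostBreadth:
    def test_all_specialists_mean_one(self):
        m = make_matrix(np.eye(3, dtype=np.int64) * 4, ["native", "native", "alien"])
        assert host_breadth_summary(m) == {"alien": 1.0, "native": 1.0}

    def test_single_generalist_counts_everywhere(self):
        m = make_matrix([[2], [5], [1]], ["native", "alien", "alien"])
        out = host_breadth_summary(m)
        assert out == {"alien": 3.0, "native": 3.0}

    def test_mixed_matrix_hand_enumeration(self):
        # fungi F1 on G1,G2 (breadth 2); F2 on G2 (1); F3 on G1,G2,G3 (3); F4 on G3 (1)
        counts = [[1, 0, 2, 0], [3, 1, 1, 0], [0, 0, 4, 2]]
        m = make_matrix(counts, ["native", "native", "alien"])
        out = host_breadth_summary(m)
        # native occurrences: G1:F1,F3 G2:F1,F2,F3 -> breadths 2,3,2,1,3 mean 11/5
        assert out["native"] == pytest.approx(11 / 5)
        # alien occurrences: G3:F3,F4 -> breadths 3,1 mean 2
        assert out["alien"] == pytest.approx(2.0)
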