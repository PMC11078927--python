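"""Upstream-neighborhood induction, iterative core pruning, MR annotation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from mrgrn.mr import (
    annotate_candidates,
    iterative_core_pruning,
    select_master_regulators,
    upstream_neighborhood,
)
from mrgrn.network import RegulatoryNetwork, build_reference_network

from conftest import edges


def _net(*pairs) -> RegulatoryNetwork:
    return build_reference_network([edges(*pairs)])


# ---------------------------------------------------------------------------
# upstream neighborhood
# ---------------------------------------------------------------------------


def test_upstream_two_step_rule_hand_trace():
    net = _net(("A", "B"), ("B", "g"), ("C", "A"))
    sub = upstream_neighborhood(net, {"g"})
    assert set(sub.nodes) == {"g", "B", "A"}  # C is 3 steps upstream


def test_upstream_deg_without_regulators_is_singleton():
    net = _net(("A", "B"), ("X", "Y"))
    sub = upstream_neighborhood(net, {"B", "Y"})
    solo = upstream_neighborhood(net, {"Y"})
    assert set(solo.nodes) == {"X", "Y"}
    # a DEG that nothing regulates stays a single node
    net2 = _net(("A", "B"))
    lone = upstream_neighborhood(net2, {"A"})
    assert set(lone.nodes) == {"A"}
    assert sub.number_of_nodes() == 4


def test_upstream_saturation_returns_whole_network():
    net = _net(("A", "B"), ("B", "C"), ("C", "A"))
    sub = upstream_neighborhood(net, set(net.nodes))
    assert sub.edge_set() == net.edge_set()


def test_upstream_missing_degs_warn_and_empty_errors():
    net = _net(("A", "B"))
    with pytest.warns(UserWarning, match="ignored"):
        sub = upstream_neighborhood(net, {"B", "nope"})
    assert "B" in sub.nodes
    with pytest.raises(ValueError, match="symbol space"):
        upstream_neighborhood(net, {"nope"})


def test_upstream_edges_are_induced():
    # edge A->B retained even though B enters only as upstream of g via B->g
    net = _net(("A", "B"), ("B", "g"), ("A", "g"))
    sub = upstream_neighborhood(net, {"g"})
    assert sub.edge_set() == {("A", "B"), ("B", "g"), ("A", "g")}


# ---------------------------------------------------------------------------
# iterative core pruning
# ---------------------------------------------------------------------------


def test_pruning_hand_trace_two_hubs():
    """Targets fall first (min out-degree, ties by in-degree then id);
    pruning stops when the remainder would drop below 2 nodes."""
    net = _net(
        ("M1", "g1"), ("M1", "g2"), ("M2", "g2"), ("M2", "g3"),
        ("M1", "M2"), ("M2", "M1"),
    )
    survivors, trace = iterative_core_pruning(net)
    assert set(survivors.nodes) == {"M1", "M2"}
    # g1 (in-deg 1) before g3 (in-deg 1, later id)? No: g1 < g3 lexicographically,
    # and both precede g2 whose in-degree is 2.
    assert trace.removal_order() == ["g1", "g3", "g2"]
    assert trace.blocks[-1].reason == "too_few_nodes"
    assert trace.blocks[-1].blocked_node == "M1"


def test_pruning_two_node_network_blocks_immediately():
    net = _net(("A", "B"))
    survivors, trace = iterative_core_pruning(net)
    assert set(survivors.nodes) == {"A", "B"}
    assert trace.removal_order() == []
    assert trace.blocks[0].reason == "too_few_nodes"


def test_pruning_single_node_and_empty_network():
    g = nx.DiGraph()
    g.add_node("solo")
    survivors, trace = iterative_core_pruning(RegulatoryNetwork(g))
    assert set(survivors.nodes) == {"solo"}
    assert trace.removal_order() == []
    survivors, trace = iterative_core_pruning(RegulatoryNetwork(nx.DiGraph()))
    assert survivors.number_of_nodes() == 0
    assert trace.removals == [] and trace.blocks == []


def test_pruning_stops_on_disconnection():
    # star through a shared target: removing 'g' strands 'B'
    net = _net(("A", "g"), ("B", "g"), ("A", "C"))
    survivors, trace = iterative_core_pruning(net)
    # first victim is C (out 0, in 1) -> ok; then g (out 0) would strand B
    assert trace.removal_order() == ["C"]
    assert trace.blocks[0] == type(trace.blocks[0])("g", "disconnection")
    assert set(survivors.nodes) == {"A", "B", "g"}


def test_pruning_disconnected_input_pruned_per_component():
    net = _net(("A", "B"), ("X", "Y"), ("Y", "X"))
    survivors, trace = iterative_core_pruning(net)
    assert set(survivors.nodes) == {"A", "B", "X", "Y"}
    assert len(trace.blocks) == 2


def test_pruning_self_loop_neutral():
    g = nx.DiGraph()
    g.add_edge("A", "A")
    g.add_edge("A", "B")
    g.add_edge("B", "A")
    survivors, trace = iterative_core_pruning(RegulatoryNetwork(g))
    assert set(survivors.nodes) == {"A", "B"}


def test_pruning_trace_replay_reproduces_survivors():
    rng = np.random.default_rng(17)
    for _ in range(50):
        g = nx.gnp_random_graph(rng.integers(2, 10), 0.3, directed=True,
                                seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        net = RegulatoryNetwork(g.copy())
        survivors, trace = iterative_core_pruning(net)
        replay = g.copy()
        replay.remove_nodes_from(trace.removal_order())
        assert set(replay.nodes) == set(survivors.nodes)


def test_pruning_minimality_at_each_committed_step():
    """No node present at a committed removal had strictly smaller out-degree."""
    rng = np.random.default_rng(29)
    for _ in range(50):
        g = nx.gnp_random_graph(rng.integers(2, 10), 0.35, directed=True,
                                seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        survivors, trace = iterative_core_pruning(RegulatoryNetwork(g.copy()))
        current = g.copy()
        for ev in trace.removals:
            comp = nx.node_connected_component(current.to_undirected(), ev.node)
            min_out = min(current.out_degree(n) for n in comp)
            assert current.out_degree(ev.node) == ev.out_degree_at_removal
            assert ev.out_degree_at_removal == min_out
            current.remove_node(ev.node)


def test_pruning_deterministic():
    g = nx.gnp_random_graph(9, 0.4, directed=True, seed=99)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    s1, t1 = iterative_core_pruning(RegulatoryNetwork(g.copy()))
    s2, t2 = iterative_core_pruning(RegulatoryNetwork(g.copy()))
    assert set(s1.nodes) == set(s2.nodes)
    assert t1.removal_order() == t2.removal_order()


def test_pruning_skip_blockers_removes_at_least_as_many():
    rng = np.random.default_rng(31)
    for _ in range(20):
        g = nx.gnp_random_graph(8, 0.3, directed=True, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        s_stop, _ = iterative_core_pruning(RegulatoryNetwork(g.copy()))
        s_skip, _ = iterative_core_pruning(
            RegulatoryNetwork(g.copy()), skip_blockers=True
        )
        assert s_skip.number_of_nodes() <= s_stop.number_of_nodes()


def test_survivors_weakly_connected_per_component():
    rng = np.random.default_rng(41)
    for _ in range(30):
        g = nx.gnp_random_graph(rng.integers(2, 10), 0.3, directed=True,
                                seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        n_comp_in = nx.number_weakly_connected_components(g) if g.number_of_nodes() else 0
        survivors, _ = iterative_core_pruning(RegulatoryNetwork(g.copy()))
        if survivors.number_of_nodes():
            n_comp_out = nx.number_weakly_connected_components(survivors.graph)
            assert n_comp_out <= n_comp_in


# ---------------------------------------------------------------------------
# annotation and selection
# ---------------------------------------------------------------------------


def _det(status: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"status": pd.Series(status)},
        index=pd.Index(list(status), name="gene_id"),
    )


def test_annotate_reciprocal_and_physical():
    net = _net(("M1", "M2"), ("M2", "M1"), ("M1", "g"))
    survivors, _ = iterative_core_pruning(net)
    det = _det({"M1": "up", "M2": "down", "g": "ns"})
    physical = {frozenset({"M1", "M2"})}
    cands = annotate_candidates(survivors, det, physical)
    by_gene = {c.gene: c for c in cands}
    assert by_gene["M1"].reciprocal and by_gene["M2"].reciprocal
    assert by_gene["M1"].physical_support and by_gene["M2"].physical_support
    assert by_gene["M1"].direction == "up" and by_gene["M2"].direction == "down"


def test_annotate_without_physical_table_is_unknown():
    net = _net(("M1", "M2"), ("M2", "M1"))
    survivors, _ = iterative_core_pruning(net)
    cands = annotate_candidates(survivors, _det({"M1": "up"}), None)
    assert all(c.physical_support is None for c in cands)


def test_annotate_survivor_absent_from_de_table_not_de():
    net = _net(("M1", "M2"), ("M2", "M1"))
    survivors, _ = iterative_core_pruning(net)
    cands = annotate_candidates(survivors, _det({"M1": "up"}), None)
    m2 = next(c for c in cands if c.gene == "M2")
    assert not m2.is_de and m2.direction == "none"


def test_annotate_only_reference_tfs_become_candidates():
    net = _net(("A", "g"), ("B", "g"))
    survivors, _ = iterative_core_pruning(net)  # blocks immediately, g survives
    cands = annotate_candidates(survivors, None, None)
    assert {c.gene for c in cands} == {"A", "B"}  # g is never a candidate


def test_select_master_regulators_splits_on_de_status():
    # treat the full reciprocal core as the surviving network
    survivors = _net(
        ("Lef1", "Jup"), ("Jup", "Lef1"), ("Lef1", "Foxo3"), ("Foxo3", "Lef1"),
    )
    det = _det({"Lef1": "up", "Jup": "up", "Foxo3": "down"})
    cands = annotate_candidates(survivors, det)
    all_mrs, de_mrs = select_master_regulators(cands)
    assert {c.gene for c in de_mrs} == {"Lef1", "Jup", "Foxo3"}
    assert len(all_mrs) >= len(de_mrs)
    directions = {c.gene: c.direction for c in de_mrs}
    assert directions["Foxo3"] == "down"
    # no DE candidates -> empty de_mrs, all_mrs unchanged
    cands2 = annotate_candidates(survivors, _det({"Lef1": "ns"}))
    all2, de2 = select_master_regulators(cands2)
    assert de2 == [] and len(all2) == len(cands2)
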