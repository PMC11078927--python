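"""Master-regulator inference by upstream-neighborhood induction and
iterative lowest-out-degree core pruning.

Master regulators are transcription factors that sit atop the regulatory
hierarchy: they direct (and are often directed by) other regulators and
control many genes at once. Operationally, the candidates are the
transcription factors that survive when, starting from the subnetwork of
differentially expressed genes and their first/second upstream neighbors,
nodes of minimal out-degree are deleted one at a time until any further
deletion would disconnect the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import RegulatoryNetwork

__all__ = [
    "RemovalEvent",
    "BlockEvent",
    "PruningTrace",
    "MasterRegulatorCandidate",
    "upstream_neighborhood",
    "iterative_core_pruning",
    "annotate_candidates",
    "select_master_regulators",
]


# ---------------------------------------------------------------------------
# neighborhood induction
# ---------------------------------------------------------------------------


def upstream_neighborhood(
    net: RegulatoryNetwork, degs: set[str]
) -> RegulatoryNetwork:
    """Induce the subgraph of DEGs plus their first/second upstream neighbors.

    A node u is retained if it is a DEG present in the network, or if a
    directed path u -> ... -> d of length 1 or 2 reaches some DEG d. Edges
    are all network edges among retained nodes (induced subgraph). DEGs
    absent from the network are ignored with a warning; an empty
    intersection is an error (usually a symbol-space mismatch).
    """
    g = net.graph
    present = {d for d in degs if d in g}
    missing = set(degs) - present
    if not present:
        raise ValueError(
            "none of the DEGs occur in the network; "
            "check that the count matrix and edge lists share a symbol space"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} DEG(s) absent from the network were ignored",
            stacklevel=2,
        )
    keep = set(present)
    for d in present:
        for u in g.predecessors(d):  # first upstream
            keep.add(u)
            for w in g.predecessors(u):  # second upstream
                keep.add(w)
    return net.induced_subgraph(keep)


# ---------------------------------------------------------------------------
# iterative core pruning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemovalEvent:
    node: str
    out_degree_at_removal: int


@dataclass(frozen=True)
class BlockEvent:
    blocked_node: str | None
    reason: str  # "disconnection" | "too_few_nodes" | "trivial_component"


@dataclass
class PruningTrace:
    """Ordered committed removals plus the terminal blocking event(s).

    Networks that start weakly disconnected are pruned one weak component
    at a time (components ordered by their lexicographically smallest
    node), so the trace carries one block event per component.
    """

    removals: list[RemovalEvent] = field(default_factory=list)
    blocks: list[BlockEvent] = field(default_factory=list)

    def removal_order(self) -> list[str]:
        return [ev.node for ev in self.removals]


def _prune_key(g: nx.DiGraph):
    def key(node):
        return (g.out_degree(node), g.in_degree(node), node)

    return key


def _prune_component(g: nx.DiGraph, trace: PruningTrace) -> set[str]:
    """Prune one weakly connected component in place; return survivors."""
    if g.number_of_nodes() < 2:
        trace.blocks.append(BlockEvent(None, "trivial_component"))
        return set(g.nodes)
    while True:
        victim = min(g.nodes, key=_prune_key(g))
        out_deg = g.out_degree(victim)
        rest = [n for n in g.nodes if n != victim]
        if len(rest) < 2:
            trace.blocks.append(BlockEvent(victim, "too_few_nodes"))
            break
        if not nx.is_weakly_connected(g.subgraph(rest)):
            trace.blocks.append(BlockEvent(victim, "disconnection"))
            break
        g.remove_node(victim)
        trace.removals.append(RemovalEvent(victim, out_deg))
    return set(g.nodes)


def _prune_component_skip(g: nx.DiGraph, trace: PruningTrace) -> set[str]:
    """Variant: skip a blocking node and try the next-lowest instead."""
    if g.number_of_nodes() < 2:
        trace.blocks.append(BlockEvent(None, "trivial_component"))
        return set(g.nodes)
    while True:
        blocked: set[str] = set()
        committed = False
        for victim in sorted(g.nodes, key=_prune_key(g)):
            rest = [n for n in g.nodes if n != victim]
            if len(rest) < 2:
                blocked.add(victim)
                continue
            if not nx.is_weakly_connected(g.subgraph(rest)):
                blocked.add(victim)
                continue
            trace.removals.append(RemovalEvent(victim, g.out_degree(victim)))
            g.remove_node(victim)
            committed = True
            break
        if not committed:
            first = min(blocked) if blocked else None
            trace.blocks.append(BlockEvent(first, "disconnection"))
            break
    return set(g.nodes)


def iterative_core_pruning(
    net: RegulatoryNetwork, skip_blockers: bool = False
) -> tuple[RegulatoryNetwork, PruningTrace]:
    """Delete minimal-out-degree nodes until a deletion would disconnect.

    Each step picks the node with minimal current out-degree (ties broken
    by minimal in-degree, then lexicographic id), tentatively removes it,
    and commits unless the remainder would have fewer than 2 nodes or be
    weakly disconnected — in which case the removal is undone and pruning
    stops (default stop-at-first-block policy; ``skip_blockers=True``
    instead sets the blocker aside and tries the next-lowest node until no
    node can be removed). Self-loops count once toward each degree and
    never affect connectivity. A disconnected input is pruned per weak
    component and the surviving blocks are merged.
    """
    g_in = net.graph
    trace = PruningTrace()
    if g_in.number_of_nodes() == 0:
        return RegulatoryNetwork(nx.DiGraph()), trace
    survivors: set[str] = set()
    prune = _prune_component_skip if skip_blockers else _prune_component
    components = sorted(nx.weakly_connected_components(g_in), key=min)
    for comp in components:
        sub = g_in.subgraph(comp).copy()
        survivors |= prune(sub, trace)
    return net.induced_subgraph(survivors), trace


# ---------------------------------------------------------------------------
# candidate annotation and selection
# ---------------------------------------------------------------------------


@dataclass
class MasterRegulatorCandidate:
    """A TF that survived core pruning, with its DE and topology context."""

    gene: str
    out_degree: int
    in_degree: int
    is_de: bool
    direction: str  # "up" | "down" | "none"
    reciprocal: bool
    physical_support: bool | None  # None = no interaction table supplied

    def __post_init__(self) -> None:
        if (self.direction != "none") != self.is_de:
            raise ValueError("direction must be up/down exactly when is_de")


def annotate_candidates(
    survivors: RegulatoryNetwork,
    det: pd.DataFrame | None,
    physical: set[frozenset] | None = None,
) -> list[MasterRegulatorCandidate]:
    """One candidate per surviving node that is a TF in the reference.

    Degrees are computed within the surviving core. DE status and
    direction come from the DE table's ``status`` column (a survivor
    absent from the table is not DE). ``reciprocal`` means the node both
    directs and is directed by other survivors. ``physical_support`` is
    True iff any unordered pair of survivors containing the node occurs in
    the supplied interaction table, None when no table was given.
    """
    g = survivors.graph
    nodes = set(g.nodes)
    candidates = []
    for node in sorted(nodes):
        if not g.nodes[node].get("is_tf", g.out_degree(node) > 0):
            continue
        status = "ns"
        if det is not None and node in det.index:
            status = str(det.loc[node, "status"])
        is_de = status in ("up", "down")
        direction = status if is_de else "none"
        out_others = any(v != node for v in g.successors(node))
        in_others = any(u != node for u in g.predecessors(node))
        if physical is None:
            phys: bool | None = None
        else:
            phys = any(
                frozenset({node, other}) in physical
                for other in nodes
                if other != node
            )
        candidates.append(
            MasterRegulatorCandidate(
                gene=node,
                out_degree=g.out_degree(node),
                in_degree=g.in_degree(node),
                is_de=is_de,
                direction=direction,
                reciprocal=out_others and in_others,
                physical_support=phys,
            )
        )
    return candidates


def select_master_regulators(
    candidates: list[MasterRegulatorCandidate],
) -> tuple[list[MasterRegulatorCandidate], list[MasterRegulatorCandidate]]:
    """Split candidates into (all_mrs, de_mrs).

    Every surviving TF is a master-regulator candidate; the differentially
    expressed subset carries its direction and is the study's headline
    result set.
    """
    all_mrs = list(candidates)
    de_mrs = [c for c in candidates if c.is_de]
    return all_mrs, de_mrs


def candidates_to_frame(candidates: list[MasterRegulatorCandidate]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene,
            "out_degree": c.out_degree,
            "in_degree": c.in_degree,
            "is_de": c.is_de,
            "direction": c.direction,
            "reciprocal": c.reciprocal,
            "physical_support": "" if c.physical_support is None else c.physical_support,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "out_degree",
            "in_degree",
            "is_de",
            "direction",
            "reciprocal",
            "physical_support",
        ],
    )


def trace_to_frame(trace: PruningTrace) -> pd.DataFrame:
    rows = [
        {"event": "removal", "node": ev.node, "out_degree": ev.out_degree_at_removal, "reason": ""}
        for ev in trace.removals
    ]
    rows += [
        {"event": "blocked", "node": ev.blocked_node or "", "out_degree": "", "reason": ev.reason}
        for ev in trace.blocks
    ]
    return pd.DataFrame(rows, columns=["event", "node", "out_degree", "reason"])
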