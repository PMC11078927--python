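"""Reference regulatory network construction and expression-based contextualization.

The reference network is the deduplicated union of one or more curated
TF->target edge lists. Contextualization restricts it to a biological
condition by deleting every outgoing edge of a transcription factor whose
expression falls below a raw-count cutoff (default 10), the rationale being
that a regulator that is not transcribed cannot exert its regulation there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io import CountMatrix, EdgeRecord

__all__ = [
    "RegulatoryNetwork",
    "ExpressionStatus",
    "build_reference_network",
    "expression_status",
    "contextualize",
]

DEFAULT_TAU = 10.0


class RegulatoryNetwork:
    """Directed simple graph of TF->target regulations.

    Thin wrapper over a :class:`networkx.DiGraph`; at most one edge per
    ordered pair, with merged ``sources`` and a resolved ``mode`` stored as
    edge attributes. Nodes carry ``is_tf`` (had >=1 outgoing edge in the
    reference union), preserved through contextualization and subsetting.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction -------------------------------------------------------
    @classmethod
    def from_edge_records(cls, records: Iterable[EdgeRecord]) -> "RegulatoryNetwork":
        return build_reference_network([list(records)])

    # -- views ---------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_records(self) -> list[EdgeRecord]:
        out = []
        for u, v, data in self.graph.edges(data=True):
            out.append(
                EdgeRecord(
                    regulator=u,
                    target=v,
                    mode=data.get("mode", "unknown"),
                    sources=frozenset(data.get("sources", {"unknown"})),
                    confidence=data.get("confidence"),
                )
            )
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def is_tf(self, node: str) -> bool:
        return bool(self.graph.nodes[node].get("is_tf", False))

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.copy())

    def induced_subgraph(self, nodes: Iterable[str]) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.subgraph(nodes).copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RegulatoryNetwork({self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges)"
        )


def _resolve_mode(modes: set[str]) -> str:
    """Merge the modes reported for one ordered pair across databases.

    An explicit activation/repression conflict (or an already-ambiguous
    report) yields ``ambiguous``; ``unknown`` never conflicts with a signed
    mode and is absorbed by it.
    """
    if "ambiguous" in modes or {"activation", "repression"} <= modes:
        return "ambiguous"
    if "activation" in modes:
        return "activation"
    if "repression" in modes:
        return "repression"
    return "unknown"


def build_reference_network(
    edge_lists: Sequence[Sequence[EdgeRecord]],
) -> RegulatoryNetwork:
    """Union of edge lists with per-ordered-pair deduplication.

    Sources are merged; conflicting signed modes become ``ambiguous``;
    the best (lexicographically smallest, e.g. DoRothEA "A") confidence
    grade is retained. Raises if every input list is empty.
    """
    merged: dict[tuple[str, str], dict] = {}
    total = 0
    for records in edge_lists:
        for rec in records:
            total += 1
            key = (rec.regulator, rec.target)
            slot = merged.setdefault(
                key, {"modes": set(), "sources": set(), "confidence": None}
            )
            slot["modes"].add(rec.mode)
            slot["sources"] |= set(rec.sources)
            if rec.confidence is not None:
                if slot["confidence"] is None or rec.confidence < slot["confidence"]:
                    slot["confidence"] = rec.confidence
    if total == 0:
        raise ValueError("cannot build a reference network from empty edge lists")
    g = nx.DiGraph()
    for (reg, tgt), slot in merged.items():
        g.add_edge(
            reg,
            tgt,
            mode=_resolve_mode(slot["modes"]),
            sources=frozenset(slot["sources"]),
            confidence=slot["confidence"],
        )
    for node in g.nodes:
        g.nodes[node]["is_tf"] = g.out_degree(node) > 0
    return RegulatoryNetwork(g)


@dataclass
class ExpressionStatus:
    """Per-gene expression call for one condition.

    ``expressed`` iff the per-condition aggregate of raw counts meets the
    cutoff ``tau`` (boundary inclusive). Genes absent from the count matrix
    are not expressed.
    """

    mean_raw_count: pd.Series
    expressed: pd.Series
    tau: float
    aggregate: str
    condition: str

    def is_expressed(self, gene: str) -> bool:
        if gene in self.expressed.index:
            return bool(self.expressed[gene])
        return False


_AGGREGATES = {"mean": "mean", "min": "min", "max": "max"}


def expression_status(
    cm: CountMatrix,
    condition: str,
    tau: float = DEFAULT_TAU,
    aggregate: str = "mean",
) -> ExpressionStatus:
    """Call genes expressed/not-expressed from raw counts in one condition.

    The aggregate over the condition's replicates (arithmetic mean by
    default) is compared against ``tau``, inclusive at the boundary.
    """
    if aggregate not in _AGGREGATES:
        raise ValueError(f"aggregate must be one of {sorted(_AGGREGATES)}")
    samples = cm.samples_of(condition)
    if not samples:
        raise ValueError(f"no samples in condition {condition!r}")
    sub = cm.counts[samples]
    agg = getattr(sub, _AGGREGATES[aggregate])(axis=1).astype(float)
    return ExpressionStatus(
        mean_raw_count=agg,
        expressed=agg >= tau,
        tau=tau,
        aggregate=aggregate,
        condition=condition,
    )


def contextualize(ref: RegulatoryNetwork, status: ExpressionStatus) -> RegulatoryNetwork:
    """Remove outgoing edges of non-expressed TFs; drop isolated nodes.

    Incoming edges are kept regardless of the target's expression (a
    non-expressed gene can still be regulated). The result's edge set is a
    subset of the reference's; node attributes are preserved.
    """
    g = ref.graph.copy()
    to_drop = [
        (u, v) for u, v in g.edges() if not status.is_expressed(u)
    ]
    g.remove_edges_from(to_drop)
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return RegulatoryNetwork(g)
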