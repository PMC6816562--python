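"""Carrier-connectivity graphs over identity-by-descent breed relationships.

Breeds carrying a rare allele are linked through significant IBD-sharing
edges; when the carriers do not already form one connected component, a
greedy Steiner-style heuristic adds the non-carrier breed that merges the
most disconnected carrier components, repeating until no single addition
helps.  Carriers with no significant sharing anywhere attach through their
single highest non-significant sharing partner, flagged as a fallback
(dashed) edge.  Ties are broken lexicographically, so a fixed input yields
an identical graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = ["IBDEdge", "CarrierGraph", "connect_carriers", "write_dot"]


@dataclass(frozen=True)
class IBDEdge:
    breed_a: str
    breed_b: str
    value: Optional[float] = None
    significant: bool = False

    def __post_init__(self) -> None:
        if self.breed_a == self.breed_b:
            raise ValueError(f"self-edge on {self.breed_a!r}")


@dataclass
class CarrierGraph:
    graph: nx.Graph
    carriers: list[str]
    connectors: list[str]
    not_represented: list[str]
    unconnectable: list[str]
    fallback_edges: list[tuple[str, str]]

    @property
    def n_connectors(self) -> int:
        return len(self.connectors)

    @property
    def connected(self) -> bool:
        return not self.unconnectable and (
            len(self.graph) == 0 or nx.is_connected(self.graph)
        )


def _universe(edges: Sequence[IBDEdge]) -> tuple[nx.Graph, nx.Graph]:
    """(graph of significant edges, graph of all edges) over every breed seen."""
    sig = nx.Graph()
    full = nx.Graph()
    for e in edges:
        full.add_edge(e.breed_a, e.breed_b, value=e.value, significant=e.significant)
        sig.add_node(e.breed_a)
        sig.add_node(e.breed_b)
        if e.significant:
            sig.add_edge(e.breed_a, e.breed_b, value=e.value)
    return sig, full


def connect_carriers(
    edges: Sequence[IBDEdge],
    carriers: Iterable[str],
    disallowed: Optional[Iterable[str]] = None,
) -> CarrierGraph:
    """Build the carrier-connectivity graph for one rare allele.

    ``carriers`` are breeds observed to carry the allele; ``disallowed``
    optionally marks the subset whose standard forbids the associated
    phenotype (for presentation only).
    """
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("carrier set is empty")
    disallowed = set(disallowed or ())
    sig, full = _universe(edges)

    not_represented = [c for c in carriers if c not in full]
    present = [c for c in carriers if c in full]

    out = nx.Graph()
    fallback_edges: list[tuple[str, str]] = []
    for c in present:
        status = "carrier_disallowed" if c in disallowed else "carrier_permitted"
        out.add_node(c, status=status)

    # carrier-carrier significant edges
    for a, b, data in sig.edges(data=True):
        if a in out and b in out:
            out.add_edge(a, b, significant=True, fallback=False, value=data.get("value"))

    # fallback attachment for carriers with no significant sharing anywhere
    for c in sorted(present):
        if sig.degree(c) == 0:
            partners = sorted(
                full[c].items(),
                key=lambda kv: (-(kv[1].get("value") or 0.0), kv[0]),
            )
            if not partners:
                continue
            partner, data = partners[0]
            if partner not in out:
                out.add_node(partner, status="non_carrier_connector")
            out.add_edge(c, partner, significant=False, fallback=True,
                         value=data.get("value"))
            fallback_edges.append((c, partner))

    connectors = [n for n, d in out.nodes(data=True)
                  if d["status"] == "non_carrier_connector"]

    # greedy: add the non-carrier breed merging the most components
    def components() -> list[set[str]]:
        return [set(c) for c in nx.connected_components(out)]

    candidates = sorted(n for n in sig.nodes if n not in out)
    while True:
        comps = components()
        if len(comps) <= 1:
            break
        best: Optional[tuple[int, str]] = None
        for cand in candidates:
            if cand in out:
                continue
            touched = sum(
                1 for comp in comps if any(sig.has_edge(cand, m) for m in comp)
            )
            if touched >= 2 and (best is None or touched > best[0]):
                best = (touched, cand)
        if best is None:
            break
        _, chosen = best
        out.add_node(chosen, status="non_carrier_connector")
        connectors.append(chosen)
        for comp in comps:
            for m in sorted(comp):
                if sig.has_edge(chosen, m):
                    out.add_edge(chosen, m, significant=True, fallback=False,
                                 value=sig[chosen][m].get("value"))

    comps = components()
    unconnectable: list[str] = []
    if len(comps) > 1:
        # keep the component with most carriers (lexicographic tie-break)
        main = min(comps, key=lambda c: (-len(c & set(present)), sorted(c)))
        for comp in comps:
            if comp is not main:
                unconnectable.extend(sorted(n for n in comp if n in present))

    return CarrierGraph(
        graph=out,
        carriers=present,
        connectors=sorted(connectors),
        not_represented=not_represented,
        unconnectable=sorted(unconnectable),
        fallback_edges=fallback_edges,
    )


_DOT_COLORS = {
    "carrier_permitted": "green",
    "carrier_disallowed": "red",
    "non_carrier_connector": "grey",
}


def write_dot(result: CarrierGraph, path: str | Path) -> None:
    """Export the carrier graph as DOT; fallback edges are dashed."""
    lines = ["graph carriers {"]
    for node, data in sorted(result.graph.nodes(data=True)):
        color = _DOT_COLORS.get(data.get("status", ""), "black")
        lines.append(f'  "{node}" [color={color}];')
    for a, b, data in sorted(result.graph.edges(data=True)):
        style = "dashed" if data.get("fallback") else "solid"
        lines.append(f'  "{a}" -- "{b}" [style={style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
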