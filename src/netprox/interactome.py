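"""Protein–protein interaction graph: construction, normalization, and queries.

The interactome is an undirected, unweighted graph of physical
protein–protein interactions.  All distances used downstream (proximity,
module significance) are hop counts on this graph.  Node identifiers are
canonicalized strings (uppercased, whitespace-stripped); cross-namespace
identifier mapping (e.g. Entrez ↔ symbol) is the caller's responsibility —
all inputs to one analysis must share a namespace.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Interactome",
    "ComponentView",
    "LoadReport",
    "canonical_id",
    "build_interactome",
    "read_edge_tsv",
    "write_edge_tsv",
    "read_node_set",
    "largest_connected_component",
    "restrict_to_lcc",
    "shortest_path_lengths_from",
    "degrees",
]


def canonical_id(raw: object) -> str:
    """Canonicalize a protein identifier: strip whitespace, uppercase.

    Raises ``ValueError`` if the identifier is empty after stripping.
    """
    s = str(raw).strip().upper()
    if not s:
        raise ValueError("empty protein identifier")
    return s


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from edge-list ingestion."""

    n_records: int
    n_edges: int
    n_self_loops_dropped: int
    n_duplicates_collapsed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "n_edges": self.n_edges,
                "n_self_loops_dropped": self.n_self_loops_dropped,
                "n_duplicates_collapsed": self.n_duplicates_collapsed,
            },
            sort_keys=True,
        )


@dataclass
class Interactome:
    """Undirected, unweighted PPI graph with optional per-edge source tags.

    Invariants: no self-loops, no duplicate edges, every endpoint is a
    node, all identifiers canonical.  Nodes enter the graph only through
    edges.
    """

    graph: nx.Graph
    load_report: LoadReport | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def source_tags(self) -> Mapping[frozenset[str], set[str]]:
        """Edge → set of source-database names (edges without tags omitted)."""
        out: dict[frozenset[str], set[str]] = {}
        for u, v, data in self.graph.edges(data=True):
            if data.get("sources"):
                out[frozenset((u, v))] = set(data["sources"])
        return out

    def induced(self, nodes: Iterable[str]) -> "Interactome":
        """Interactome induced on ``nodes`` ∩ current nodes (copied)."""
        keep = set(nodes) & self.nodes
        return Interactome(graph=self.graph.subgraph(keep).copy())


@dataclass(frozen=True)
class ComponentView:
    """A connected component of (a restriction of) the interactome."""

    parent: Interactome
    member_nodes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_nodes)


def build_interactome(
    edge_records: Sequence[Sequence[object]],
) -> Interactome:
    """Build a normalized interactome from raw ``(idA, idB[, source])`` records.

    Self-loop records are dropped, (A,B)/(B,A) duplicates are collapsed,
    identifiers canonicalized.  Counts are recorded in ``load_report``.

    Raises
    ------
    ValueError
        If ``edge_records`` is empty, a record is missing a field (the
        error names the 1-based record number), or no edges remain after
        filtering.
    """
    if edge_records is None or len(edge_records) == 0:
        raise ValueError("no edges")
    g = nx.Graph()
    n_self = 0
    n_dup = 0
    for lineno, rec in enumerate(edge_records, start=1):
        rec = tuple(rec)
        if len(rec) < 2:
            raise ValueError(f"record {lineno}: missing field (need idA, idB)")
        try:
            a = canonical_id(rec[0])
            b = canonical_id(rec[1])
        except ValueError as exc:
            raise ValueError(f"record {lineno}: {exc}") from exc
        source = None
        if len(rec) >= 3 and rec[2] is not None and str(rec[2]).strip():
            source = str(rec[2]).strip()
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            if source:
                g[a][b].setdefault("sources", set()).add(source)
            continue
        g.add_edge(a, b, sources={source} if source else set())
    if g.number_of_edges() == 0:
        raise ValueError("no edges")
    report = LoadReport(
        n_records=len(edge_records),
        n_edges=g.number_of_edges(),
        n_self_loops_dropped=n_self,
        n_duplicates_collapsed=n_dup,
    )
    return Interactome(graph=g, load_report=report)


def read_edge_tsv(path: str | Path) -> Interactome:
    """Read an edge-list TSV with columns ``protein_a``, ``protein_b`` and
    optional ``source``; ``#`` lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"protein_a", "protein_b"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"edge TSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    cols = ["protein_a", "protein_b"] + (["source"] if "source" in df.columns else [])
    records = [tuple(row) for row in df[cols].itertuples(index=False)]
    return build_interactome(records)


def write_edge_tsv(g: Interactome, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(g.graph.edges(data=True)):
        src = ";".join(sorted(data.get("sources") or [])) or None
        rows.append((u, v, src))
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "source"])
    df.to_csv(path, sep="\t", index=False)


def read_node_set(path: str | Path) -> set[str]:
    """Read one canonical ID per line; blank and ``#`` lines ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.add(canonical_id(line))
    return out


def largest_connected_component(
    g: Interactome, restrict_to: Iterable[str] | None = None
) -> ComponentView:
    """Maximum-cardinality connected component of the subgraph induced on
    ``restrict_to`` ∩ nodes (or the full graph).

    Ties between equal-sized components are broken in favour of the one
    containing the lexicographically smallest member ID.  A restriction
    disjoint from the graph yields an empty (size-0) view.
    """
    if g.n_nodes == 0:
        raise ValueError("empty interactome")
    if restrict_to is None:
        pool = set(g.graph.nodes)
    else:
        pool = set(restrict_to) & set(g.graph.nodes)
    if not pool:
        return ComponentView(parent=g, member_nodes=frozenset())
    sub = g.graph.subgraph(pool)
    # largest size first, then smallest min-ID as the tie-break
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    return ComponentView(parent=g, member_nodes=frozenset(comps[0]))


def restrict_to_lcc(g: Interactome) -> Interactome:
    """Return the interactome induced on its own largest connected component.

    Proximity and module-significance analyses run on this component so
    that every pairwise distance is finite; nodes outside it are dropped
    with a warning.
    """
    lcc = largest_connected_component(g)
    dropped = g.n_nodes - lcc.size
    if dropped:
        warnings.warn(
            f"dropping {dropped} node(s) outside the interactome LCC",
            stacklevel=2,
        )
    return g.induced(lcc.member_nodes)


def shortest_path_lengths_from(
    g: Interactome, sources: Iterable[str]
) -> dict[str, int]:
    """Multi-source BFS hop distances from ``sources`` to every reachable node.

    Every source maps to 0; unreachable nodes are absent from the result.
    """
    src = set(sources)
    if not src:
        raise ValueError("empty source set")
    missing = src - set(g.graph.nodes)
    if missing:
        raise ValueError(f"sources not in interactome: {sorted(missing)[:5]}")
    dist: dict[str, int] = {s: 0 for s in src}
    queue = deque(src)
    adj = g.graph.adj
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def degrees(g: Interactome) -> dict[str, int]:
    """Node → number of incident edges."""
    return dict(g.graph.degree())
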