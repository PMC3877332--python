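"""Undirected simple graph and the topological measures used for marker screening.

The screening pipeline characterises each protein in a protein-protein
interaction (PPI) network by four node-level measures -- degree, shortest-path
betweenness, closeness, and coreness (the "K value" of k-core decomposition) --
and each interaction by its edge betweenness.  All measures are implemented
here directly on an adjacency-set representation; shortest paths are unweighted
hop counts (PPI edges carry no weights).

Conventions
-----------
* Betweenness uses fractional shortest-path counting (Brandes accumulation);
  the normalised form divides by ``(n-1)(n-2)/2``, the number of node pairs a
  node could possibly sit between.
* Closeness of node ``v`` is ``r_v / farness_v`` where ``r_v`` is the number of
  nodes reachable from ``v`` (excluding ``v``) and ``farness_v`` the sum of
  hop distances to them, so disconnected graphs are well defined and a
  complete-graph node scores exactly 1.  Isolated nodes score 0.
* Unreachable pairs contribute nothing to betweenness or farness.
* All iteration orders are sorted by node identifier, so outputs are
  deterministic for a given graph.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class GraphInputError(ValueError):
    """Malformed graph input (bad edge pair, negative k, empty graph where forbidden)."""


def _canon(u: str, v: str) -> Edge:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class Graph:
    """Simple undirected graph over string node identifiers.

    No self-loops, no parallel edges.  Construct via :func:`build_graph`
    (or :meth:`from_adjacency` for internal use).
    """

    __slots__ = ("_adj",)

    def __init__(self) -> None:
        self._adj: dict[str, set[str]] = {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_adjacency(cls, adj: Mapping[str, Iterable[str]]) -> "Graph":
        g = cls()
        g._adj = {u: set(vs) for u, vs in adj.items()}
        return g

    # -- basic queries ------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(vs) for vs in self._adj.values()) // 2

    def edges(self) -> list[Edge]:
        """Canonical sorted edge list."""
        return sorted(
            (u, v) for u, vs in self._adj.items() for v in vs if u < v
        )

    def neighbors(self, v: str) -> set[str]:
        return self._adj[v]

    def degree_of(self, v: str) -> int:
        return len(self._adj[v])

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def __contains__(self, v: str) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def subgraph(self, keep: Iterable[str]) -> "Graph":
        """Induced subgraph on ``keep`` (unknown identifiers ignored)."""
        keep_set = set(keep) & self.nodes
        return Graph.from_adjacency(
            {u: self._adj[u] & keep_set for u in keep_set}
        )


@dataclass(frozen=True)
class NodeFeatures:
    """The four node-level screening measures for one protein."""

    node: str
    degree: int
    betweenness: float
    closeness: float
    coreness: int


@dataclass(frozen=True)
class EdgeFeatures:
    """Edge betweenness of one interaction."""

    edge: Edge
    edge_betweenness: float


def build_graph(
    edge_pairs: Iterable[Sequence[str]],
    isolated_nodes: Iterable[str] = (),
) -> Graph:
    """Build a simple undirected graph from identifier pairs.

    Self-loops and duplicate edges are dropped (a count is logged); order of
    endpoints and of pairs is irrelevant.  ``isolated_nodes`` adds nodes with
    no edges.

    Raises
    ------
    GraphInputError
        If a pair does not consist of exactly two non-empty identifiers.
    """
    adj: dict[str, set[str]] = {}
    n_self = 0
    n_dup = 0
    for lineno, pair in enumerate(edge_pairs, start=1):
        try:
            u, v = pair
        except (TypeError, ValueError):
            raise GraphInputError(
                f"edge pair {lineno}: expected exactly 2 identifiers, got {pair!r}"
            ) from None
        u, v = str(u).strip(), str(v).strip()
        if not u or not v:
            raise GraphInputError(
                f"edge pair {lineno}: empty identifier in {pair!r}"
            )
        if u == v:
            n_self += 1
            adj.setdefault(u, set())
            continue
        if u in adj and v in adj[u]:
            n_dup += 1
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for v in isolated_nodes:
        adj.setdefault(str(v).strip(), set())
    if n_self or n_dup:
        logger.info(
            "build_graph: dropped %d self-loop(s) and %d duplicate edge(s)",
            n_self,
            n_dup,
        )
    return Graph.from_adjacency(adj)


# ---------------------------------------------------------------------------
# node-level measures
# ---------------------------------------------------------------------------


def degree(g: Graph) -> dict[str, int]:
    """Number of interaction partners of each node."""
    return {v: g.degree_of(v) for v in g.sorted_nodes()}


def _bfs_shortest(adj: dict[str, list[str]], s: str):
    """Single-source BFS: returns (visit order, predecessors, path counts, distances)."""
    dist = {s: 0}
    sigma = {s: 1}
    pred: dict[str, list[str]] = {s: []}
    order: list[str] = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        dv = dist[v]
        sv = sigma[v]
        for w in adj[v]:
            if w not in dist:
                dist[w] = dv + 1
                sigma[w] = 0
                pred[w] = []
                q.append(w)
            if dist[w] == dv + 1:
                sigma[w] += sv
                pred[w].append(v)
    return order, pred, sigma, dist


def _brandes(g: Graph, want_edges: bool):
    """Brandes dependency accumulation over all sources.

    Returns raw (unnormalised) node betweenness and, if requested, edge
    betweenness, each counting every unordered node pair once.
    """
    nodes = g.sorted_nodes()
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    ebc: dict[Edge, float] | None = (
        {e: 0.0 for e in g.edges()} if want_edges else None
    )
    for s in nodes:
        order, pred, sigma, _ = _bfs_shortest(adj, s)
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            coef = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                c = sigma[v] * coef
                delta[v] += c
                if ebc is not None:
                    ebc[_canon(v, w)] += c
            if w != s:
                bc[w] += delta[w]
    # every unordered pair was accumulated from both endpoints
    for v in bc:
        bc[v] /= 2.0
    if ebc is not None:
        for e in ebc:
            ebc[e] /= 2.0
    return bc, ebc


def node_betweenness(g: Graph, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness centrality of each node.

    Raw value of ``v`` sums, over unordered pairs ``(s, t)`` with
    ``s != v != t``, the fraction of shortest s-t paths passing through ``v``.
    With ``normalized`` the raw value is divided by ``(n-1)(n-2)/2``.
    """
    bc, _ = _brandes(g, want_edges=False)
    if normalized:
        n = g.n_nodes
        scale = (n - 1) * (n - 2) / 2.0
        if scale > 0:
            bc = {v: x / scale for v, x in bc.items()}
        else:
            bc = {v: 0.0 for v in bc}
    return bc


def edge_betweenness(g: Graph) -> dict[Edge, float]:
    """Shortest-path betweenness of each edge (raw, unordered pairs counted once).

    Satisfies the conservation identity: the sum over edges equals the sum of
    shortest-path distances over all connected node pairs.
    """
    _, ebc = _brandes(g, want_edges=True)
    assert ebc is not None
    return ebc


def closeness(g: Graph) -> dict[str, float]:
    """Reachable-scaled closeness: (number reachable) / (sum of distances to them)."""
    nodes = g.sorted_nodes()
    adj = {v: sorted(g.neighbors(v)) for v in nodes}
    out: dict[str, float] = {}
    for v in nodes:
        _, _, _, dist = _bfs_shortest(adj, v)
        farness = sum(dist.values())  # dist[v] == 0 contributes nothing
        reachable = len(dist) - 1
        out[v] = reachable / farness if farness > 0 else 0.0
    return out


def coreness(g: Graph) -> dict[str, int]:
    """Largest k such that the node survives in the k-core (the "K value").

    Computed by peeling nodes in nondecreasing order of current degree;
    isolated nodes have coreness 0.
    """
    deg = {v: g.degree_of(v) for v in g.nodes}
    remaining = set(deg)
    core: dict[str, int] = {}
    k = 0
    while remaining:
        v = min(remaining, key=lambda x: (deg[x], x))
        k = max(k, deg[v])
        core[v] = k
        remaining.discard(v)
        for w in g.neighbors(v):
            if w in remaining:
                deg[w] -= 1
    return {v: core[v] for v in g.sorted_nodes()}


def kcore_subgraph(g: Graph, k: int) -> Graph:
    """Maximal induced subgraph in which every node has degree >= k.

    May be empty.  Idempotent: applying it twice at the same k is the identity.
    """
    if k < 0:
        raise GraphInputError(f"k must be non-negative, got {k}")
    keep = set(g.nodes)
    deg = {v: g.degree_of(v) for v in keep}
    changed = True
    while changed:
        drop = {v for v in keep if deg[v] < k}
        changed = bool(drop)
        keep -= drop
        for v in drop:
            for w in g.neighbors(v):
                if w in keep:
                    deg[w] -= 1
    return g.subgraph(keep)


def compute_node_features(
    g: Graph,
    restrict: Iterable[str] | None = None,
    normalized_betweenness: bool = True,
) -> dict[str, NodeFeatures]:
    """All four screening measures, computed on ``g`` as a whole.

    ``restrict`` limits the *returned* nodes (e.g. to the hub set) without
    changing the graph the measures are computed on.
    """
    deg = degree(g)
    bet = node_betweenness(g, normalized=normalized_betweenness)
    clo = closeness(g)
    cor = coreness(g)
    keep = set(restrict) & g.nodes if restrict is not None else g.nodes
    return {
        v: NodeFeatures(
            node=v,
            degree=deg[v],
            betweenness=bet[v],
            closeness=clo[v],
            coreness=cor[v],
        )
        for v in sorted(keep)
    }


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return "\t"


def read_edge_list(
    path: str | Path, delimiter: str | None = None
) -> list[Edge]:
    """Read a 2-column delimited edge list; ``#`` comment lines and blanks skipped.

    Delimiter auto-detected between tab and comma unless given; identifiers
    are whitespace-trimmed and taken verbatim otherwise.
    """
    path = Path(path)
    pairs: list[Edge] = []
    sep: str | None = delimiter
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if sep is None:
                sep = _sniff_delimiter(line, delimiter)
            fields = [f.strip() for f in line.split(sep)]
            fields = [f for f in fields if f != ""]
            if len(fields) != 2:
                raise GraphInputError(
                    f"{path}:{lineno}: expected 2 identifiers, got {len(fields)}: {line!r}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def write_edge_list(
    edges: Iterable[Edge], path: str | Path, delimiter: str = "\t"
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for u, v in edges:
            fh.write(f"{u}{delimiter}{v}\n")


def features_to_frame(features: Mapping[str, NodeFeatures]) -> pd.DataFrame:
    """Feature table with columns node, degree, betweenness, closeness, coreness."""
    rows = [
        (f.node, f.degree, f.betweenness, f.closeness, f.coreness)
        for f in (features[v] for v in sorted(features))
    ]
    return pd.DataFrame(
        rows, columns=["node", "degree", "betweenness", "closeness", "coreness"]
    )


def write_feature_table(
    features: Mapping[str, NodeFeatures], path: str | Path, delimiter: str = "\t"
) -> None:
    features_to_frame(features).to_csv(path, sep=delimiter, index=False)
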