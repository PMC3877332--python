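"""Marker screening: hub selection, four-median candidate filter, core extraction.

The screen proceeds in stages on the marker-induced PPI subgraph:

1. *Hubs*: nodes whose degree strictly exceeds twice the median degree of all
   nodes in the network.
2. *Candidates*: hub nodes strictly above the hub-set median of **all four**
   measures (degree, betweenness, closeness, coreness).  Strict inequalities
   mean a node sitting exactly at a median is excluded.
3. *Crucial candidates*: k-core decomposition of the candidate subnetwork
   identifies the innermost (main) core; edge betweenness on the same
   subnetwork ranks interactions, the top one being the "key interaction"
   that stitches cores together.

All medians use the usual mean-of-middle-two rule for even counts.  The
module is fully deterministic: ties are broken by identifier order and no
randomness enters anywhere.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .graph import (
    Edge,
    Graph,
    GraphInputError,
    NodeFeatures,
    compute_node_features,
    coreness,
    degree,
    edge_betweenness,
)
from .ingest import MarkerList


class ScreeningError(ValueError):
    """Invalid screening input (empty sets where content is required)."""


@dataclass(frozen=True)
class ScreeningThresholds:
    """The four feature medians plus the hub degree cutoff (2x median degree)."""

    hub_degree_cutoff: float
    degree_med: float
    betweenness_med: float
    closeness_med: float
    kvalue_med: float


@dataclass(frozen=True)
class ScreeningConfig:
    """Tunable screening behaviour.

    median_scope
        ``"hubs"`` (default): the four feature medians are taken over the hub
        set; ``"all"``: over every node of the marker subgraph.
    eb_scope
        ``"candidates"`` (default): edge betweenness and k-core run on the
        candidate-induced subgraph; ``"full"``: on the whole marker subgraph.
    """

    median_scope: str = "hubs"
    eb_scope: str = "candidates"
    normalized_betweenness: bool = True
    top_n_interactions: int = 10


@dataclass
class ScreeningResult:
    hubs: set[str]
    candidates: set[str]
    innermost_core_nodes: set[str]
    main_core_k: int
    ranked_interactions: list[tuple[Edge, float]]
    thresholds: ScreeningThresholds | None = None
    features: dict[str, NodeFeatures] = field(default_factory=dict)
    report: dict = field(default_factory=dict)


def _median(values: Sequence[float]) -> float:
    return float(statistics.median(values))


def select_hubs(degrees: Mapping[str, int]) -> set[str]:
    """Nodes whose degree strictly exceeds twice the median degree."""
    if not degrees:
        raise ScreeningError("select_hubs: empty degree map")
    cutoff = 2.0 * _median(list(degrees.values()))
    return {v for v, d in degrees.items() if d > cutoff}


def compute_thresholds(
    features: Iterable[NodeFeatures],
    all_degrees: Mapping[str, int] | None = None,
) -> ScreeningThresholds:
    """Medians of the four measures over ``features`` plus the hub cutoff.

    The hub cutoff is twice the median of ``all_degrees`` when given (the
    whole-network degree map the hub rule was applied to); otherwise twice
    the degree median of ``features`` itself.
    """
    feats = list(features)
    if not feats:
        raise ScreeningError("compute_thresholds: empty feature list")
    degree_med = _median([f.degree for f in feats])
    hub_base = (
        _median(list(all_degrees.values())) if all_degrees else degree_med
    )
    return ScreeningThresholds(
        hub_degree_cutoff=2.0 * hub_base,
        degree_med=degree_med,
        betweenness_med=_median([f.betweenness for f in feats]),
        closeness_med=_median([f.closeness for f in feats]),
        kvalue_med=_median([f.coreness for f in feats]),
    )


def select_candidates(
    features: Iterable[NodeFeatures], thresholds: ScreeningThresholds
) -> set[str]:
    """Nodes strictly above all four medians."""
    return {
        f.node
        for f in features
        if f.degree > thresholds.degree_med
        and f.betweenness > thresholds.betweenness_med
        and f.closeness > thresholds.closeness_med
        and f.coreness > thresholds.kvalue_med
    }


def innermost_core(g: Graph) -> tuple[int, set[str]]:
    """The main core: maximum coreness k and the nodes attaining it."""
    if g.n_nodes == 0:
        raise ScreeningError("innermost_core: empty graph")
    core = coreness(g)
    k = max(core.values())
    return k, {v for v, c in core.items() if c == k}


def rank_key_interactions(
    eb: Mapping[Edge, float], top_n: int
) -> list[tuple[Edge, float]]:
    """Interactions ranked by descending edge betweenness, ties lexicographic."""
    if not eb:
        raise ScreeningError("rank_key_interactions: empty edge-betweenness map")
    if top_n <= 0:
        raise ScreeningError(f"rank_key_interactions: top_n must be positive, got {top_n}")
    ranked = sorted(eb.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def run_screening(
    markers: MarkerList,
    g: Graph,
    config: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Full screen: marker subgraph -> hubs -> four-median filter -> cores.

    Raises :class:`ScreeningError` if no marker identifier occurs in the
    graph.  An empty hub or candidate set is not an error; downstream stages
    simply return empty results.
    """
    config = config or ScreeningConfig()
    overlap = markers.ids & g.nodes
    if not overlap:
        raise ScreeningError(
            "run_screening: no marker identifier found among graph nodes "
            "(check identifier normalisation)"
        )
    sub = g.subgraph(overlap)
    degrees = degree(sub)
    hubs = select_hubs(degrees)

    report: dict = {
        "n_markers": len(markers.ids),
        "n_marker_nodes_in_graph": sub.n_nodes,
        "n_marker_edges": sub.n_edges,
        "n_unmapped_markers": markers.n_unmapped,
        "n_hubs": len(hubs),
    }

    if not hubs:
        report.update(n_candidates=0, main_core_k=0)
        return ScreeningResult(
            hubs=set(), candidates=set(), innermost_core_nodes=set(),
            main_core_k=0, ranked_interactions=[], report=report,
        )

    # measures computed on the whole marker subgraph, medians over the scope set
    features = compute_node_features(
        sub, normalized_betweenness=config.normalized_betweenness
    )
    scope = hubs if config.median_scope == "hubs" else set(sub.nodes)
    thresholds = compute_thresholds(
        [features[v] for v in sorted(scope)], all_degrees=degrees
    )
    candidates = select_candidates(
        [features[v] for v in sorted(hubs)], thresholds
    )
    report["n_candidates"] = len(candidates)
    report["median_scope"] = config.median_scope
    report["eb_scope"] = config.eb_scope

    if not candidates:
        report["main_core_k"] = 0
        return ScreeningResult(
            hubs=hubs, candidates=set(), innermost_core_nodes=set(),
            main_core_k=0, ranked_interactions=[], thresholds=thresholds,
            features={v: features[v] for v in sorted(hubs)}, report=report,
        )

    core_graph = sub.subgraph(candidates) if config.eb_scope == "candidates" else sub
    if core_graph.n_edges > 0:
        k, core_nodes = innermost_core(core_graph)
        ranked = rank_key_interactions(
            edge_betweenness(core_graph), config.top_n_interactions
        )
    else:
        k, core_nodes, ranked = 0, set(core_graph.nodes), []
    if config.eb_scope == "full":
        core_nodes &= candidates
    report["main_core_k"] = k
    report["n_innermost_core_nodes"] = len(core_nodes)
    if ranked:
        report["key_interaction"] = list(ranked[0][0])

    return ScreeningResult(
        hubs=hubs,
        candidates=candidates,
        innermost_core_nodes=core_nodes,
        main_core_k=k,
        ranked_interactions=ranked,
        thresholds=thresholds,
        features={v: features[v] for v in sorted(hubs)},
        report=report,
    )
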