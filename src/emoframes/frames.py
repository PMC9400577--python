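"""Semantic frames: neighbourhood extraction, communities, change metrics.

The semantic frame of a target stem is its distance-1 neighbourhood in the
flattened (both-layer) forma mentis network: exactly the words the corpus
directly associates with the target, syntactically or by synonymy.  Frames
can be partitioned into Louvain communities of tightly connected concepts,
compared structurally across time windows (degree change), and their edges
classified into the colour code used for frame visualisations: endpoint
valences determine the class of syntactic links, synonym-only links are
green.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import networkx as nx

from .corpus import EmotionLexicon
from .network import LAYER_SYNONYM, LAYER_SYNTACTIC, TFMN


class UndefinedBaselineError(ValueError):
    """A relative change has no defined baseline (zero or absent before)."""


@dataclass
class SemanticFrame:
    target: str
    neighbours: frozenset[str]
    subgraph: nx.Graph
    partition: dict[str, int] | None = None


def extract_frame(
    g: TFMN,
    target: str,
    layers: Literal["both", "syntactic"] = "both",
) -> SemanticFrame:
    """Distance-1 neighbourhood of ``target`` and its induced subgraph.

    A target absent from the network yields an empty frame (empty neighbour
    set, empty subgraph) rather than an error.
    """
    if target not in g.graph:
        return SemanticFrame(target=target, neighbours=frozenset(), subgraph=nx.Graph())
    if layers == "both":
        nbrs = set(g.graph.neighbors(target))
    elif layers == "syntactic":
        nbrs = {
            n for n in g.graph.neighbors(target)
            if LAYER_SYNTACTIC in g.graph.edges[target, n]["layers"]
        }
    else:
        raise ValueError(f"invalid layer selector {layers!r}")
    sub = g.graph.subgraph({target} | nbrs).copy()
    return SemanticFrame(target=target, neighbours=frozenset(nbrs), subgraph=sub)


def detect_communities(
    frame: SemanticFrame, seed: int = 0, resolution: float = 1.0
) -> dict[str, int]:
    """Louvain partition of the frame subgraph; deterministic given seed.

    Community ids are assigned in order of each community's smallest member
    so that the numbering itself is reproducible.  A subgraph with no edges
    partitions into singletons.
    """
    if frame.subgraph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty frame")
    if frame.subgraph.number_of_edges() == 0:
        communities = [{n} for n in frame.subgraph.nodes]
    else:
        communities = nx.community.louvain_communities(
            frame.subgraph, seed=seed, resolution=resolution
        )
    partition = {}
    for cid, comm in enumerate(sorted(communities, key=min)):
        for node in comm:
            partition[node] = cid
    frame.partition = partition
    return partition


def degree_change(g_before: TFMN, g_after: TFMN, target: str) -> float:
    """Signed percentage change of the target's flattened degree.

    ``100 * (deg_after - deg_before) / deg_before``; a target absent after
    counts as degree 0 (a -100% collapse), while a target absent before, or
    isolated before, has no defined baseline.
    """
    deg_before = g_before.degree(target)
    if deg_before == 0:
        raise UndefinedBaselineError(
            f"target {target!r} has no edges in the baseline network"
        )
    deg_after = g_after.degree(target)
    return 100.0 * (deg_after - deg_before) / deg_before


#: edge colour classes keyed by sorted endpoint-valence pair (syntactic links)
_VALENCE_COLOURS = {
    ("positive", "positive"): "cyan",
    ("negative", "negative"): "red",
    ("neutral", "neutral"): "grey",
    ("negative", "positive"): "purple",
    # exactly one neutral endpoint: least-emphasis grey
    ("neutral", "positive"): "grey",
    ("negative", "neutral"): "grey",
}


def classify_edges(
    frame: SemanticFrame, lexicon: EmotionLexicon | None = None
) -> dict[tuple[str, str], str]:
    """Total, single-valued edge -> colour-class map for frame drawings.

    Synonym-only edges are green; every other edge is classified by the
    valences of its endpoints (read from node attributes, or from the given
    lexicon as a fallback).
    """
    colours = {}
    for a, b, attrs in frame.subgraph.edges(data=True):
        key = (min(a, b), max(a, b))
        if attrs["layers"] == frozenset({LAYER_SYNONYM}):
            colours[key] = "green"
            continue
        va = frame.subgraph.nodes[a].get(
            "valence", lexicon.valence_of(a) if lexicon else "neutral"
        )
        vb = frame.subgraph.nodes[b].get(
            "valence", lexicon.valence_of(b) if lexicon else "neutral"
        )
        colours[key] = _VALENCE_COLOURS[tuple(sorted((va, vb)))]
    return colours


def frame_to_graphml(frame: SemanticFrame, path: str | Path) -> None:
    out = nx.Graph()
    partition = frame.partition or {}
    colours = classify_edges(frame)
    for node, attrs in frame.subgraph.nodes(data=True):
        out.add_node(
            node,
            valence=attrs.get("valence", "neutral"),
            emotions=",".join(sorted(attrs.get("emotions", ()))),
            community=partition.get(node, -1),
            is_target=node == frame.target,
        )
    for a, b, attrs in frame.subgraph.edges(data=True):
        out.add_edge(
            a, b,
            layers=",".join(sorted(attrs["layers"])),
            colour=colours[(min(a, b), max(a, b))],
        )
    nx.write_graphml(out, str(path))


def frame_summary(frame: SemanticFrame) -> dict:
    partition = frame.partition or {}
    return {
        "target": frame.target,
        "n_neighbours": len(frame.neighbours),
        "degree": len(frame.neighbours),
        "n_edges": frame.subgraph.number_of_edges(),
        "n_communities": len(set(partition.values())) if partition else None,
    }


def write_frame_summary(frame: SemanticFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(frame_summary(frame), indent=2) + "\n")
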