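"""Textual forma mentis network (TFMN) construction.

A TFMN is an undirected, simple, multiplex word graph built sentence by
sentence from parsed text.  Nodes are content-word stems.  A pair of nodes
is linked on the *syntactic* layer when the two tokens sit at distance at
most ``T`` on their sentence's dependency tree (distance is measured on the
full tree — function words count as path vertices — and only then are
non-content endpoints discarded), and on the *synonym* layer when the pair
appears in the synonym resource.  One edge may carry both layer flags.
Nodes carry the lexicon's valence and emotion attributes so that semantic
frames can be read emotionally.

The default proximity threshold is ``T = 4``, which keeps syntactic
relationships local while still joining words that are far apart in the
surface string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx

from .corpus import (
    ArticleRecord,
    EmotionLexicon,
    SynonymResource,
    normalize_record,
)
from .parsing import DependencyTree, ParserAdapter, parse
from .stemming import Stemmer, italian_stem
from .stopwords import ITALIAN_STOPWORDS

DEFAULT_T = 4

LAYER_SYNTACTIC = "syntactic"
LAYER_SYNONYM = "synonym"


class ConfigMismatchError(ValueError):
    """Two networks built under different configurations cannot be merged."""


@dataclass
class TFMN:
    """A built forma mentis network plus the configuration that shaped it."""

    graph: nx.Graph
    t: int
    lexicon: EmotionLexicon
    synonyms: SynonymResource
    provenance: frozenset[str] = field(default_factory=frozenset)

    def degree(self, stem: str) -> int:
        return self.graph.degree(stem) if stem in self.graph else 0

    def edge_layers(self, a: str, b: str) -> frozenset[str]:
        return self.graph.edges[a, b]["layers"]


def _empty_graph() -> nx.Graph:
    return nx.Graph()


def _add_node(g: nx.Graph, stem: str, lexicon: EmotionLexicon) -> None:
    if stem not in g:
        g.add_node(
            stem,
            valence=lexicon.valence_of(stem),
            emotions=lexicon.emotions_of(stem),
        )


def _add_edge(g: nx.Graph, a: str, b: str, layer: str) -> None:
    if g.has_edge(a, b):
        g.edges[a, b]["layers"] = g.edges[a, b]["layers"] | {layer}
    else:
        g.add_edge(a, b, layers=frozenset({layer}))


def syntactic_pairs(tree: DependencyTree, t: int) -> set[tuple[str, str]]:
    """Content-stem pairs at tree distance <= t within one sentence."""
    content = [i for i, tok in enumerate(tree.tokens) if tok.is_content]
    pairs: set[tuple[str, str]] = set()
    for idx, i in enumerate(content):
        dist = tree.distances_from(i)
        for j in content[idx + 1:]:
            if 0 <= dist[j] <= t:
                a, b = tree.tokens[i].stem, tree.tokens[j].stem
                if a != b:  # stem collisions would be self-loops
                    pairs.add((min(a, b), max(a, b)))
    return pairs


def _apply_synonyms(g: nx.Graph, synonyms: SynonymResource) -> None:
    for a, b in synonyms.pairs:
        if a in g and b in g:
            _add_edge(g, a, b, LAYER_SYNONYM)


def build_tfmn(
    articles: Sequence[ArticleRecord],
    fields: Literal["title", "body", "both"] = "both",
    adapter: ParserAdapter | None = None,
    lexicon: EmotionLexicon | None = None,
    synonyms: SynonymResource | None = None,
    t: int = DEFAULT_T,
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> TFMN:
    """Build one TFMN from a list of articles.

    Every content-word stem becomes a node (isolated nodes are kept so that
    an unconnected target still yields a well-defined empty frame); pairs
    within tree distance ``t`` gain a syntactic edge; once the node set is
    fixed, synonym pairs present in the graph gain the synonym layer flag.
    """
    if t < 1:
        raise ValueError(f"T must be >= 1, got {t}")
    if adapter is None:
        from .parsing import FixtureParser

        adapter = FixtureParser()
    lexicon = lexicon if lexicon is not None else EmotionLexicon(frozenset())
    synonyms = synonyms if synonyms is not None else SynonymResource(frozenset())

    g = _empty_graph()
    provenance = set()
    for article in articles:
        text = normalize_record(article, fields, stemmer=stemmer, stopwords=stopwords)
        if text.sentences:
            provenance.add(article.id)
        for tree in parse(adapter, text):
            for tok in tree.tokens:
                if tok.is_content:
                    _add_node(g, tok.stem, lexicon)
            for a, b in syntactic_pairs(tree, t):
                _add_edge(g, a, b, LAYER_SYNTACTIC)
    _apply_synonyms(g, synonyms)
    return TFMN(
        graph=g, t=t, lexicon=lexicon, synonyms=synonyms,
        provenance=frozenset(provenance),
    )


def merge(g1: TFMN, g2: TFMN) -> TFMN:
    """Union of two TFMNs built under identical configuration.

    Commutative, associative, idempotent; merging with an empty network is
    the identity.  The synonym layer is re-applied on the union node set,
    since a synonym pair may straddle the two operands.
    """
    if g1.t != g2.t:
        raise ConfigMismatchError(f"T mismatch: {g1.t} != {g2.t}")
    if g1.lexicon != g2.lexicon:
        raise ConfigMismatchError("lexicon mismatch")
    if g1.synonyms != g2.synonyms:
        raise ConfigMismatchError("synonym resource mismatch")
    g = _empty_graph()
    for src in (g1.graph, g2.graph):
        for node, attrs in src.nodes(data=True):
            if node not in g:
                g.add_node(node, **attrs)
        for a, b, attrs in src.edges(data=True):
            if g.has_edge(a, b):
                g.edges[a, b]["layers"] = g.edges[a, b]["layers"] | attrs["layers"]
            else:
                g.add_edge(a, b, layers=attrs["layers"])
    _apply_synonyms(g, g1.synonyms)
    return TFMN(
        graph=g, t=g1.t, lexicon=g1.lexicon, synonyms=g1.synonyms,
        provenance=g1.provenance | g2.provenance,
    )


def empty_like(g: TFMN) -> TFMN:
    return TFMN(
        graph=_empty_graph(), t=g.t, lexicon=g.lexicon, synonyms=g.synonyms
    )


# --------------------------------------------------------------------------
# export


def to_graphml(g: TFMN, path: str | Path) -> None:
    """GraphML with valence/emotions node attributes and a layers edge attribute."""
    out = nx.Graph()
    for node, attrs in g.graph.nodes(data=True):
        out.add_node(
            node,
            valence=attrs["valence"],
            emotions=",".join(sorted(attrs["emotions"])),
        )
    for a, b, attrs in g.graph.edges(data=True):
        out.add_edge(a, b, layers=",".join(sorted(attrs["layers"])))
    nx.write_graphml(out, str(path))


def to_edge_tsv(g: TFMN, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tlayers\n")
        for a, b, attrs in sorted(g.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{','.join(sorted(attrs['layers']))}\n")
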