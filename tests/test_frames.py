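"""Semantic frames: extraction, communities, degree change, edge colours."""

import itertools

import networkx as nx
import numpy as np
import pytest

from emoframes import (
    EmotionLexicon,
    SynonymResource,
    build_tfmn,
    classify_edges,
    degree_change,
    detect_communities,
    extract_frame,
    identity_stemmer,
    merge,
)
from emoframes.frames import SemanticFrame, UndefinedBaselineError, frame_summary
from emoframes.network import TFMN

from conftest import make_record


def graph_tfmn(edges, lexicon=None, layers="syntactic"):
    """Hand-built TFMN from an edge list (all edges on one layer)."""
    g = nx.Graph()
    lexicon = lexicon or EmotionLexicon(frozenset())
    for a, b in edges:
        for n in (a, b):
            if n not in g:
                g.add_node(n, valence=lexicon.valence_of(n),
                           emotions=lexicon.emotions_of(n))
        g.add_edge(a, b, layers=frozenset({layers}))
    return TFMN(graph=g, t=4, lexicon=lexicon,
                synonyms=SynonymResource(frozenset()))


def test_absent_target_yields_empty_frame():
    g = graph_tfmn([("a", "b")])
    frame = extract_frame(g, "vaccin")
    assert frame.neighbours == frozenset()
    assert frame.subgraph.number_of_nodes() == 0


def test_neighbours_are_direct_links_only():
    g = graph_tfmn([("astrazenec", "trombos"), ("astrazenec", "minacc"),
                    ("trombos", "reazion")])
    frame = extract_frame(g, "astrazenec")
    assert frame.neighbours == {"trombos", "minacc"}
    # induced subgraph keeps neighbour-neighbour edges but not outside nodes
    assert "reazion" not in frame.subgraph


def test_neighbours_equal_adjacency_oracle_on_random_graphs():
    rng = np.random.default_rng(19)
    for _ in range(50):
        n = int(rng.integers(2, 15))
        p = rng.uniform(0.1, 0.6)
        raw = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        g = graph_tfmn([(f"n{a}", f"n{b}") for a, b in raw.edges] or [("x", "y")])
        target = f"n{int(rng.integers(n))}"
        frame = extract_frame(g, target)
        if target not in g.graph:
            assert frame.neighbours == frozenset()
        else:
            expected = {v for u, v in g.graph.edges(target)} - {target}
            assert frame.neighbours == expected


def test_frame_monotone_under_merge(tiny_lexicon, synonyms):
    rec1 = make_record(rid="1", body="love is weakness",
                       body_heads=((2, 2, -1),),
                       body_pos=(("NOUN", "AUX", "NOUN"),))
    rec2 = make_record(rid="2", body="love joy_d fear_a",
                       body_heads=((-1, 0, 0),),
                       body_pos=(("NOUN", "NOUN", "NOUN"),))
    kw = dict(fields="body", lexicon=tiny_lexicon, synonyms=synonyms,
              stemmer=identity_stemmer)
    g1 = build_tfmn([rec1], **kw)
    g12 = merge(g1, build_tfmn([rec2], **kw))
    f1 = extract_frame(g1, "love")
    f12 = extract_frame(g12, "love")
    assert f1.neighbours <= f12.neighbours


# ------------------------------------------------------------- communities


def all_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] | {first}] + part[k + 1:]
        yield part + [{first}]


def test_louvain_separates_bridged_cliques_vs_exhaustive_modularity():
    """Two 4-cliques joined by one bridge: the optimum found by enumerating
    all 4140 partitions of the 8 nodes is the two cliques, and Louvain
    agrees."""
    g = nx.Graph()
    c1, c2 = list("abcd"), list("efgh")
    for c in (c1, c2):
        g.add_edges_from(itertools.combinations(c, 2))
    g.add_edge("d", "e")
    for n in g.nodes:
        g.nodes[n]["valence"] = "neutral"
    for e in g.edges:
        g.edges[e]["layers"] = frozenset({"syntactic"})

    best, best_q = None, -1.0
    for part in all_partitions(g.nodes):
        q = nx.community.modularity(g, part)
        if q > best_q:
            best, best_q = part, q
    assert {frozenset(c) for c in best} == {frozenset(c1), frozenset(c2)}

    frame = SemanticFrame(target="a", neighbours=frozenset(g.nodes) - {"a"},
                          subgraph=g)
    partition = detect_communities(frame, seed=0)
    comms = {}
    for node, cid in partition.items():
        comms.setdefault(cid, set()).add(node)
    assert {frozenset(c) for c in comms.values()} == {frozenset(c1), frozenset(c2)}


def test_single_node_is_one_community():
    g = nx.Graph()
    g.add_node("solo")
    frame = SemanticFrame(target="solo", neighbours=frozenset(), subgraph=g)
    assert detect_communities(frame) == {"solo": 0}


def test_empty_frame_cannot_be_partitioned():
    frame = SemanticFrame(target="x", neighbours=frozenset(), subgraph=nx.Graph())
    with pytest.raises(ValueError):
        detect_communities(frame)


def test_partition_is_deterministic_and_covers_and_beats_singletons():
    rng = np.random.default_rng(31)
    for trial in range(10):
        raw = nx.gnp_random_graph(12, 0.3, seed=trial)
        if raw.number_of_edges() == 0:
            continue
        g = nx.relabel_nodes(raw, {i: f"n{i}" for i in raw.nodes})
        frame = SemanticFrame(target="n0", neighbours=frozenset(), subgraph=g)
        p1 = detect_communities(frame, seed=17)
        p2 = detect_communities(frame, seed=17)
        assert p1 == p2
        assert set(p1) == set(g.nodes)  # covers exactly
        comms = {}
        for node, cid in p1.items():
            comms.setdefault(cid, set()).add(node)
        q = nx.community.modularity(g, comms.values())
        q_singleton = nx.community.modularity(g, [{n} for n in g.nodes])
        assert q >= q_singleton


# ------------------------------------------------------------ degree change


def test_degree_change_cases():
    before = graph_tfmn([("pfizer", f"x{i}") for i in range(4)])
    same = degree_change(before, before, "pfizer")
    assert same == 0.0
    gone = graph_tfmn([("a", "b")])
    assert degree_change(before, gone, "pfizer") == -100.0
    with pytest.raises(UndefinedBaselineError):
        degree_change(gone, before, "pfizer")


def test_degree_change_formula():
    before = graph_tfmn([("pfizer", f"x{i}") for i in range(100)])
    after = graph_tfmn([("pfizer", f"x{i}") for i in range(21)])
    assert degree_change(before, after, "pfizer") == pytest.approx(-79.0)


# -------------------------------------------------------------- edge colours


def test_caption_colour_rules(tiny_lexicon):
    g = graph_tfmn([("love", "weakness")], lexicon=tiny_lexicon)
    frame = extract_frame(g, "love")
    assert classify_edges(frame) == {("love", "weakness"): "purple"}
    g2 = graph_tfmn([("love", "joy_d")], lexicon=tiny_lexicon, layers="synonym")
    frame2 = extract_frame(g2, "love")
    assert classify_edges(frame2) == {("joy_d", "love"): "green"}


def test_colour_classification_total_over_valence_and_layer_grid():
    """Every valence pair x layer combination maps to exactly one colour."""
    expected = {  # keyed by sorted valence pair
        ("positive", "positive"): "cyan",
        ("negative", "negative"): "red",
        ("neutral", "neutral"): "grey",
        ("negative", "positive"): "purple",
        ("neutral", "positive"): "grey",
        ("negative", "neutral"): "grey",
    }
    for va, vb in itertools.product(("positive", "negative", "neutral"), repeat=2):
        for layers in (frozenset({"syntactic"}),
                       frozenset({"syntactic", "synonym"}),
                       frozenset({"synonym"})):
            g = nx.Graph()
            g.add_node("a", valence=va, emotions=frozenset())
            g.add_node("b", valence=vb, emotions=frozenset())
            g.add_edge("a", "b", layers=layers)
            frame = SemanticFrame(target="a", neighbours=frozenset({"b"}),
                                  subgraph=g)
            colours = classify_edges(frame)
            assert list(colours) == [("a", "b")]
            if layers == frozenset({"synonym"}):
                assert colours[("a", "b")] == "green"
            else:
                assert colours[("a", "b")] == expected[tuple(sorted((va, vb)))]


def test_frame_summary_fields():
    g = graph_tfmn([("v", "a"), ("v", "b"), ("a", "b")])
    frame = extract_frame(g, "v")
    detect_communities(frame)
    s = frame_summary(frame)
    assert s["target"] == "v" and s["n_neighbours"] == 2 and s["n_edges"] == 3
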