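"""Dependency-parsing contract plus a deterministic fixture parser.

A forma mentis network links words that sit within a bounded distance of one
another on a sentence's syntactic dependency tree.  Producing that tree is
the job of a :class:`ParserAdapter`.  This package deliberately ships no
trained parser: the bundled :class:`FixtureParser` honours explicit ``heads``
annotations (as emitted by the synthetic generator, making tree distances
exactly known) and otherwise falls back to a chain parse, where the head of
token *i* is token *i - 1* and distances reduce to ``|i - j|``.  A neural
parser can be plugged in by registering any object with the same interface.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .corpus import NormalizedText, Sentence, Token


class TreeIntegrityError(ValueError):
    """Adapter output violates the single-rooted-tree invariants."""


@dataclass(frozen=True)
class DependencyTree:
    """One sentence as a rooted tree; ``heads[i] == -1`` marks the root."""

    tokens: tuple[Token, ...]
    heads: tuple[int, ...]
    pos: tuple[str, ...] | None = None

    def validate(self) -> None:
        n = len(self.tokens)
        if len(self.heads) != n:
            raise TreeIntegrityError(f"{len(self.heads)} heads for {n} tokens")
        roots = [i for i, h in enumerate(self.heads) if h == -1]
        if len(roots) != 1:
            raise TreeIntegrityError(f"expected exactly one root, found {len(roots)}")
        for i, h in enumerate(self.heads):
            if h != -1 and not (0 <= h < n):
                raise TreeIntegrityError(f"head index {h} of token {i} out of range")
            if h == i:
                raise TreeIntegrityError(f"token {i} is its own head")
        # every token must reach the root (no cycles)
        for i in range(n):
            seen = set()
            j = i
            while self.heads[j] != -1:
                if j in seen:
                    raise TreeIntegrityError(f"cycle through token {i}")
                seen.add(j)
                j = self.heads[j]

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.tokens]
        for i, h in enumerate(self.heads):
            if h != -1:
                adj[i].append(h)
                adj[h].append(i)
        return adj

    def distances_from(self, i: int) -> list[int]:
        """BFS distances from token ``i`` over the undirected tree."""
        n = len(self.tokens)
        if not 0 <= i < n:
            raise IndexError(f"token index {i} out of range for {n} tokens")
        adj = self.adjacency()
        dist = [-1] * n
        dist[i] = 0
        queue = deque([i])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist


def tree_distance(tree: DependencyTree, i: int, j: int) -> int:
    """Length of the unique undirected path between tokens ``i`` and ``j``."""
    n = len(tree.tokens)
    if not 0 <= j < n:
        raise IndexError(f"token index {j} out of range for {n} tokens")
    return tree.distances_from(i)[j]


@runtime_checkable
class ParserAdapter(Protocol):
    """A named, deterministic provider of dependency trees."""

    name: str

    def parse_sentence(self, sentence: Sentence) -> DependencyTree: ...


class FixtureParser:
    """Deterministic parser: annotated heads if present, else a chain.

    The chain parse (token 0 root, head of *i* is *i - 1*) makes tree
    distance analytically ``|i - j|``, which property tests exploit.
    """

    name = "fixture"

    def parse_sentence(self, sentence: Sentence) -> DependencyTree:
        if sentence.heads is not None:
            heads = tuple(sentence.heads)
        else:
            heads = tuple(i - 1 for i in range(len(sentence.tokens)))
        return DependencyTree(tokens=sentence.tokens, heads=heads, pos=sentence.pos)


_ADAPTERS: dict[str, ParserAdapter] = {"fixture": FixtureParser()}


def register_adapter(adapter: ParserAdapter) -> None:
    _ADAPTERS[adapter.name] = adapter


def get_adapter(name: str) -> ParserAdapter:
    try:
        return _ADAPTERS[name]
    except KeyError:
        raise KeyError(
            f"unknown parser adapter {name!r}; available: {sorted(_ADAPTERS)}"
        ) from None


def parse(adapter: ParserAdapter, text: NormalizedText) -> list[DependencyTree]:
    """One validated tree per sentence; integrity failures name the sentence."""
    trees = []
    for k, sentence in enumerate(text.sentences):
        tree = adapter.parse_sentence(sentence)
        if len(tree.tokens) != len(sentence.tokens):
            raise TreeIntegrityError(
                f"sentence {k}: adapter changed token count "
                f"({len(sentence.tokens)} -> {len(tree.tokens)})"
            )
        try:
            tree.validate()
        except TreeIntegrityError as exc:
            raise TreeIntegrityError(f"sentence {k}: {exc}") from exc
        trees.append(tree)
    return trees
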