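import datetime as dt

import numpy as np
import pytest

from emoframes import (
    ArticleRecord,
    EmotionLexicon,
    FixtureParser,
    Sentence,
    SynonymResource,
    Token,
)
from emoframes.parsing import DependencyTree


@pytest.fixture
def adapter():
    return FixtureParser()


@pytest.fixture
def tiny_lexicon():
    """Handcrafted lexicon with known emotions and valences."""
    return EmotionLexicon(
        vocabulary=frozenset(
            ["love", "weakness", "fear_a", "fear_trust_b", "plain_c",
             "joy_d", "sad_e", "neutral_f"]
        ),
        assoc={
            "fear_a": frozenset({"fear"}),
            "fear_trust_b": frozenset({"fear", "trust"}),
            "joy_d": frozenset({"joy"}),
            "sad_e": frozenset({"sadness"}),
            "love": frozenset({"joy", "trust"}),
            "weakness": frozenset({"sadness"}),
        },
        valence={
            "love": "positive", "joy_d": "positive",
            "weakness": "negative", "sad_e": "negative",
            "fear_a": "negative",
        },
    )


@pytest.fixture
def synonyms():
    return SynonymResource.from_pairs([("love", "joy_d"), ("weakness", "sad_e")])


def make_token(stem: str, content: bool = True) -> Token:
    return Token(surface=stem, stem=stem, is_content=content)


def make_record(
    rid="a1",
    source_class="mainstream",
    date=dt.date(2021, 3, 10),
    title="t",
    body="b",
    **kw,
):
    return ArticleRecord(
        id=rid, domain="example.it", source_class=source_class, date=date,
        title=title, body=body, **kw,
    )


def random_tree(rng: np.random.Generator, n: int, content_prob=0.7) -> DependencyTree:
    """Random recursive tree over n tokens with random content flags."""
    heads = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    tokens = tuple(
        Token(surface=f"t{i}", stem=f"t{i}",
              is_content=bool(rng.random() < content_prob))
        for i in range(n)
    )
    return DependencyTree(tokens=tokens, heads=tuple(heads))


def tree_to_sentence(tree: DependencyTree) -> Sentence:
    return Sentence(tokens=tree.tokens, heads=tree.heads, pos=tree.pos)
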