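"""Synthetic lexicons and corpora with known ground truth.

Every pipeline stage can be tested offline against corpora whose generative
parameters — emotion enrichment around a target stem, per-day article counts
per source class, event-driven mention peaks, and the cross-platform share
correlation — are known exactly and recoverable from a config + seed.

Sentences are built from a flat template in which the target stem is the
root and its sampled neighbour stems attach directly to it, so every
target–neighbour pair sits at tree distance 1 (well inside any threshold
T >= 1) and frame membership is exact ground truth.  Explicit ``heads`` and
``pos`` arrays are emitted with each record, which the fixture parser
honours verbatim.

Share counts come from a latent bivariate log-normal popularity factor: the
latent normal correlation is calibrated analytically so that the Pearson
correlation of the resulting count-scale shares hits the requested rho,
while the log-normal marginals give the heavy tails characteristic of
re-share distributions.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .corpus import (
    EMOTIONS,
    ArticleRecord,
    EmotionLexicon,
    SynonymResource,
    write_corpus,
    write_lexicon,
    write_synonyms,
)


@dataclass(frozen=True)
class EventPeak:
    """A stem whose emission rate is boosted inside a date window."""

    stem: str
    start: dt.date
    end: dt.date
    factor: float = 3.0


@dataclass
class SyntheticGroundTruth:
    """The generative parameters a recovery test must re-detect."""

    target: str = "vaccin"
    #: per-emotion probability boost of emitting a tagged neighbour
    enrichment: dict[str, float] = field(default_factory=dict)
    neighbours_per_sentence: int = 4
    sentences_per_article: int = 2
    articles_per_day: dict[str, int] = field(
        default_factory=lambda: {"mainstream": 4, "alternative": 3}
    )
    #: baseline per-article probability of mentioning each stem in the body
    mention_probs: dict[str, float] = field(default_factory=dict)
    event: EventPeak | None = None
    #: target Pearson correlation of count-scale (fb, tw) shares
    rho: float = 0.4
    fb_log_mean: float = math.log(300.0)
    tw_log_mean: float = math.log(14.0)
    log_sd: float = 1.0
    fb_like_rate: float = 0.64
    tw_like_rate: float = 1.74
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.enrichment) - set(EMOTIONS)
        if bad:
            raise ValueError(f"unknown emotions in enrichment: {sorted(bad)}")
        total = sum(self.enrichment.values())
        if not 0 <= total <= 1:
            raise ValueError("enrichment probabilities must sum into [0, 1]")
        for p in self.mention_probs.values():
            if not 0 <= p <= 1:
                raise ValueError("mention probabilities must lie in [0, 1]")


def make_lexicon(
    n_words: int = 2000,
    emotion_probs: dict[str, float] | float = 0.08,
    valence_probs: tuple[float, float, float] = (0.3, 0.3, 0.4),
    seed: int = 0,
) -> EmotionLexicon:
    """Random lexicon: each word tagged with emotion e w.p. ``p_e``.

    Defaults emulate an NRC-style lexicon: each of the eight emotions covers
    a small fraction of the vocabulary (8% here), tags are independent, and
    valence splits 30/30/40 between positive/negative/neutral.
    """
    if isinstance(emotion_probs, (int, float)):
        emotion_probs = {e: float(emotion_probs) for e in EMOTIONS}
    if not math.isclose(sum(valence_probs), 1.0):
        raise ValueError("valence probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    words = [f"w{k:05d}" for k in range(n_words)]
    assoc: dict[str, frozenset[str]] = {}
    tags = {e: rng.random(n_words) < emotion_probs.get(e, 0.0) for e in EMOTIONS}
    for i, w in enumerate(words):
        es = frozenset(e for e in EMOTIONS if tags[e][i])
        if es:
            assoc[w] = es
    val_draw = rng.choice(
        ["positive", "negative", "neutral"], size=n_words, p=list(valence_probs)
    )
    valence = {
        w: v for w, v in zip(words, val_draw) if v != "neutral"
    }
    return EmotionLexicon(
        vocabulary=frozenset(words), assoc=assoc, valence=valence
    )


def make_synonyms(
    lexicon: EmotionLexicon, n_pairs: int = 50, seed: int = 0
) -> SynonymResource:
    """Random symmetric synonym pairs over the lexicon vocabulary."""
    rng = np.random.default_rng(seed)
    vocab = sorted(lexicon.vocabulary)
    pairs = set()
    while len(pairs) < min(n_pairs, len(vocab) * (len(vocab) - 1) // 2):
        a, b = rng.choice(len(vocab), size=2, replace=False)
        pairs.add((vocab[min(a, b)], vocab[max(a, b)]))
    return SynonymResource(frozenset(pairs))


def _latent_correlation(rho: float, sd: float) -> float:
    """Normal-scale correlation giving count-scale Pearson ``rho``.

    Inverts the log-normal correlation attenuation
    ``corr(X, Y) = (exp(r s^2) - 1) / (exp(s^2) - 1)`` for equal log-sds.
    """
    v = math.expm1(sd * sd)
    r = math.log1p(rho * v) / (sd * sd)
    if not -1 <= r <= 1:
        raise ValueError(f"rho={rho} unreachable at log-sd {sd}")
    return r


def _sample_neighbours(
    rng: np.random.Generator,
    k: int,
    vocab: list[str],
    by_emotion: dict[str, list[str]],
    enrichment: dict[str, float],
) -> list[str]:
    out = []
    emotions = list(enrichment)
    probs = [enrichment[e] for e in emotions]
    for _ in range(k):
        u = rng.random()
        acc = 0.0
        chosen = None
        for e, p in zip(emotions, probs):
            acc += p
            if u < acc and by_emotion[e]:
                chosen = by_emotion[e][rng.integers(len(by_emotion[e]))]
                break
        if chosen is None:
            chosen = vocab[rng.integers(len(vocab))]
        out.append(chosen)
    return out


def make_corpus(
    ground_truth: SyntheticGroundTruth,
    lexicon: EmotionLexicon,
    start_date: dt.date = dt.date(2021, 3, 1),
    n_days: int = 14,
) -> list[ArticleRecord]:
    """Generate dated, annotated articles from the ground-truth config.

    Titles and bodies contain the target-frame template sentences; bodies
    additionally carry a mention sentence emitting each configured stem with
    its (possibly event-boosted) probability.  All sentences ship explicit
    head/POS annotations.  Deterministic per (config, seed).
    """
    gt = ground_truth
    rng = np.random.default_rng(gt.seed)
    vocab = sorted(lexicon.vocabulary)
    by_emotion = {
        e: [w for w in vocab if e in lexicon.emotions_of(w)] for e in EMOTIONS
    }
    for e, p in gt.enrichment.items():
        if p > 0 and not by_emotion[e]:
            raise ValueError(f"enrichment on {e!r} but no {e}-tagged words")
    k = gt.neighbours_per_sentence
    if k < 1:
        raise ValueError("neighbours_per_sentence must be >= 1")

    r_latent = _latent_correlation(gt.rho, gt.log_sd)
    cov = np.array([[1.0, r_latent], [r_latent, 1.0]])
    chol = np.linalg.cholesky(cov)

    def frame_sentence() -> tuple[str, list[int], list[str]]:
        nbrs = _sample_neighbours(rng, k, vocab, by_emotion, gt.enrichment)
        tokens = [gt.target] + nbrs
        heads = [-1] + [0] * k
        pos = ["NOUN"] * (k + 1)
        return " ".join(tokens), heads, pos

    records = []
    for day_off in range(n_days):
        day = start_date + dt.timedelta(days=day_off)
        for cls, n_arts in gt.articles_per_day.items():
            for a in range(n_arts):
                title_txt, title_heads, title_pos = frame_sentence()
                body_sents = [frame_sentence() for _ in range(gt.sentences_per_article)]
                mention_tokens = []
                for stem, p in gt.mention_probs.items():
                    rate = p
                    if gt.event and gt.event.stem == stem \
                            and gt.event.start <= day <= gt.event.end:
                        rate = min(1.0, p * gt.event.factor)
                    if rng.random() < rate:
                        mention_tokens.append(stem)
                if mention_tokens:
                    heads = [-1] + [0] * (len(mention_tokens) - 1)
                    body_sents.append(
                        (" ".join(mention_tokens), heads,
                         ["NOUN"] * len(mention_tokens))
                    )
                z = chol @ rng.standard_normal(2)
                fb_shares = int(round(math.exp(gt.fb_log_mean + gt.log_sd * z[0])))
                tw_shares = int(round(math.exp(gt.tw_log_mean + gt.log_sd * z[1])))
                fb_likes = int(rng.poisson(gt.fb_like_rate * fb_shares))
                tw_likes = int(rng.poisson(gt.tw_like_rate * tw_shares))
                records.append(
                    ArticleRecord(
                        id=f"{cls[:4]}-{day.isoformat()}-{a:03d}",
                        domain=f"synthetic-{cls}.example",
                        source_class=cls,
                        date=day,
                        title=title_txt,
                        body=". ".join(s for s, _, _ in body_sents),
                        fb_shares=fb_shares, fb_likes=fb_likes,
                        tw_shares=tw_shares, tw_likes=tw_likes,
                        title_heads=(tuple(title_heads),),
                        title_pos=(tuple(title_pos),),
                        body_heads=tuple(tuple(h) for _, h, _ in body_sents),
                        body_pos=tuple(tuple(p) for _, _, p in body_sents),
                    )
                )
    return records


def write_bundle(
    ground_truth: SyntheticGroundTruth,
    lexicon: EmotionLexicon,
    synonyms: SynonymResource,
    out_dir: str | Path,
    start_date: dt.date = dt.date(2021, 3, 1),
    n_days: int = 14,
) -> dict[str, Path]:
    """Write corpus JSONL, lexicon/synonym TSVs and a ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = make_corpus(ground_truth, lexicon, start_date, n_days)
    paths = {
        "corpus": out_dir / "corpus.jsonl",
        "lexicon": out_dir / "lexicon.tsv",
        "synonyms": out_dir / "synonyms.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_corpus(corpus, paths["corpus"])
    write_lexicon(lexicon, paths["lexicon"])
    write_synonyms(synonyms, paths["synonyms"])
    gt = asdict(ground_truth)
    if ground_truth.event:
        gt["event"]["start"] = ground_truth.event.start.isoformat()
        gt["event"]["end"] = ground_truth.event.end.isoformat()
    gt["start_date"] = start_date.isoformat()
    gt["n_days"] = n_days
    paths["ground_truth"].write_text(json.dumps(gt, indent=2) + "\n")
    return paths
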