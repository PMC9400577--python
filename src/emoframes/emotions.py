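"""Emotion profiling of semantic frames against a lexicon resampling null.

The words in a frame are checked against an NRC-style lexicon of the eight
primary Plutchik emotions.  Raw counts are meaningless on their own (some
emotions are simply better represented in any lexicon), so each observed
count is standardised against the emotion distribution of repeated
equal-size random samples drawn uniformly, without replacement, from the
lexicon vocabulary itself (default 300 samples).  The resulting z-scores are
gated at |z| > 1.96 — the 0.975 standard-normal quantile — into
over-/under-expressed flags.

Frame words are counted as a *set* of unique stems, and each null sample
matches that set's cardinality: the comparison is against "an equal number
of random words", with cardinality the only matching variable.  A null
standard deviation of zero is reported as an explicit ``degenerate`` flag,
never as an infinite z.

Daily time series apply a trailing moving average (default 7 days) to the
per-day z-scores and flag emotions whose smoothed score stays outside the
gate on at least a given fraction of observed days (default 50%).
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    EMOTIONS,
    ArticleRecord,
    EmotionLexicon,
    SynonymResource,
    filter_by_stem,
)
from .frames import extract_frame
from .network import DEFAULT_T, build_tfmn
from .parsing import ParserAdapter
from .stemming import Stemmer, italian_stem
from .stopwords import ITALIAN_STOPWORDS

DEFAULT_Z_STAR = 1.96
DEFAULT_N_SAMPLES = 300


@dataclass(frozen=True)
class NullModelConfig:
    """Resampling null: how many lexicon samples, and the seed."""

    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    sampling: Literal["without_replacement"] = "without_replacement"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.sampling != "without_replacement":
            raise ValueError(f"unsupported sampling mode {self.sampling!r}")


@dataclass(frozen=True)
class EmotionScore:
    count: int
    mu: float
    sigma: float
    z: float | None
    flag: Literal["over", "under", "ns", "degenerate"]


@dataclass(frozen=True)
class EmotionProfile:
    scores: dict[str, EmotionScore]
    m: int  # number of (unique) frame words scored
    z_star: float

    def z(self, emotion: str) -> float | None:
        return self.scores[emotion].z

    def flag(self, emotion: str) -> str:
        return self.scores[emotion].flag


def count_emotions(
    words: Iterable[str], lexicon: EmotionLexicon
) -> dict[str, int]:
    """Per-emotion counts over a word set; out-of-lexicon words contribute 0."""
    counts = dict.fromkeys(EMOTIONS, 0)
    for w in set(words):
        for e in lexicon.emotions_of(w):
            counts[e] += 1
    return counts


def _emotion_matrix(lexicon: EmotionLexicon) -> tuple[list[str], np.ndarray]:
    """Sorted vocabulary and its |V| x 8 boolean emotion membership matrix."""
    vocab = sorted(lexicon.vocabulary)
    mat = np.zeros((len(vocab), len(EMOTIONS)), dtype=bool)
    eidx = {e: k for k, e in enumerate(EMOTIONS)}
    for i, w in enumerate(vocab):
        for e in lexicon.emotions_of(w):
            mat[i, eidx[e]] = True
    return vocab, mat


def _gate(z: float | None, sigma: float, z_star: float) -> str:
    if sigma == 0:
        return "degenerate"
    assert z is not None
    if z > z_star:
        return "over"
    if z < -z_star:
        return "under"
    return "ns"


def empty_profile(z_star: float = DEFAULT_Z_STAR) -> EmotionProfile:
    """The documented convention for an empty frame: all counts 0, flags ns."""
    scores = {
        e: EmotionScore(count=0, mu=0.0, sigma=0.0, z=None, flag="ns")
        for e in EMOTIONS
    }
    return EmotionProfile(scores=scores, m=0, z_star=z_star)


def zscore_profile(
    words: Iterable[str],
    lexicon: EmotionLexicon,
    null: NullModelConfig = NullModelConfig(),
    z_star: float = DEFAULT_Z_STAR,
) -> EmotionProfile:
    """Standardise a word set's emotion counts against the lexicon null.

    Draws ``null.n_samples`` uniform without-replacement samples of the same
    cardinality as ``words`` from the lexicon vocabulary; z is the observed
    count standardised by the sample mean and (ddof=1) standard deviation.
    """
    words = set(words)
    m = len(words)
    if m == 0:
        return empty_profile(z_star)
    vocab, mat = _emotion_matrix(lexicon)
    if m > len(vocab):
        raise ValueError(
            f"word set of size {m} exceeds lexicon vocabulary ({len(vocab)})"
        )
    observed = count_emotions(words, lexicon)
    rng = np.random.default_rng(null.seed)
    sample_counts = np.empty((null.n_samples, len(EMOTIONS)), dtype=np.int64)
    for s in range(null.n_samples):
        idx = rng.choice(len(vocab), size=m, replace=False)
        sample_counts[s] = mat[idx].sum(axis=0)
    mu = sample_counts.mean(axis=0)
    sigma = sample_counts.std(axis=0, ddof=1)
    scores = {}
    for k, e in enumerate(EMOTIONS):
        if sigma[k] == 0:
            scores[e] = EmotionScore(
                count=observed[e], mu=float(mu[k]), sigma=0.0, z=None,
                flag="degenerate",
            )
        else:
            z = (observed[e] - mu[k]) / sigma[k]
            scores[e] = EmotionScore(
                count=observed[e], mu=float(mu[k]), sigma=float(sigma[k]),
                z=float(z), flag=_gate(float(z), float(sigma[k]), z_star),
            )
    return EmotionProfile(scores=scores, m=m, z_star=z_star)


def frame_emotion_profile(
    articles: Sequence[ArticleRecord],
    target: str,
    fields: Literal["title", "body", "both"] = "both",
    adapter: ParserAdapter | None = None,
    lexicon: EmotionLexicon | None = None,
    synonyms: SynonymResource | None = None,
    t: int = DEFAULT_T,
    null: NullModelConfig = NullModelConfig(),
    z_star: float = DEFAULT_Z_STAR,
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> EmotionProfile:
    """Build a TFMN, extract the target's frame, and score its neighbours.

    The target itself is excluded from the scored word set.  An empty frame
    yields the all-zero, all-``ns`` profile.
    """
    if lexicon is None:
        raise ValueError("an emotion lexicon is required")
    g = build_tfmn(
        articles, fields=fields, adapter=adapter, lexicon=lexicon,
        synonyms=synonyms, t=t, stemmer=stemmer, stopwords=stopwords,
    )
    frame = extract_frame(g, target)
    if not frame.neighbours:
        return empty_profile(z_star)
    return zscore_profile(frame.neighbours, lexicon, null=null, z_star=z_star)


# --------------------------------------------------------------------------
# time series


def trailing_mean(values: Sequence[float], window: int) -> list[float]:
    """Trailing moving average over the last ``window`` defined values.

    NaNs mark gaps: they stay NaN in the output and are skipped (not zero
    -filled) when averaging, so the window counts *defined* entries.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    defined = [(i, v) for i, v in enumerate(values) if not math.isnan(v)]
    out = [math.nan] * len(values)
    for k, (i, _) in enumerate(defined):
        lo = max(0, k - window + 1)
        chunk = [v for _, v in defined[lo:k + 1]]
        out[i] = sum(chunk) / len(chunk)
    return out


@dataclass
class DailyZSeries:
    """Per-emotion daily z-scores, smoothed values and persistence flags."""

    frame: pd.DataFrame  # columns: date, emotion, z, smoothed_z, significant
    persistence: dict[str, bool]
    z_star: float
    window: int

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def daily_z_series(
    articles: Sequence[ArticleRecord],
    target: str,
    fields: Literal["title", "body", "both"] = "both",
    adapter: ParserAdapter | None = None,
    lexicon: EmotionLexicon | None = None,
    synonyms: SynonymResource | None = None,
    t: int = DEFAULT_T,
    null: NullModelConfig = NullModelConfig(),
    z_star: float = DEFAULT_Z_STAR,
    window: int = 7,
    persistence: float = 0.5,
    mode: Literal["frame", "article_words"] = "frame",
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> DailyZSeries:
    """Daily emotion z-scores for articles mentioning the target.

    Each calendar day with at least one matching article contributes one
    profile (frame mode scores the day's TFMN neighbourhood of the target;
    article-words mode scores all content words of the matching articles).
    Days without articles are gaps.  An emotion is *persistent* when its
    smoothed |z| exceeds the gate on at least ``persistence`` of the days
    where it is defined.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < persistence <= 1:
        raise ValueError("persistence must be in (0, 1]")
    filter_fields = "either" if fields == "both" else fields
    matching = filter_by_stem(
        articles, target, fields=filter_fields, stemmer=stemmer,
        stopwords=stopwords,
    )
    by_day: dict[dt.date, list[ArticleRecord]] = {}
    for r in matching:
        by_day.setdefault(r.date, []).append(r)
    days = sorted(by_day)

    z_by_emotion: dict[str, list[float]] = {e: [] for e in EMOTIONS}
    for k, day in enumerate(days):
        day_null = NullModelConfig(
            n_samples=null.n_samples, seed=null.seed + k, sampling=null.sampling
        )
        if mode == "frame":
            profile = frame_emotion_profile(
                by_day[day], target, fields=fields, adapter=adapter,
                lexicon=lexicon, synonyms=synonyms, t=t, null=day_null,
                z_star=z_star, stemmer=stemmer, stopwords=stopwords,
            )
        else:
            words: set[str] = set()
            from .corpus import normalize_record

            for r in by_day[day]:
                words |= normalize_record(
                    r, fields, stemmer=stemmer, stopwords=stopwords
                ).stems(content_only=True)
            words.discard(target)
            profile = (
                zscore_profile(words, lexicon, null=day_null, z_star=z_star)
                if words else empty_profile(z_star)
            )
        for e in EMOTIONS:
            z = profile.z(e)
            z_by_emotion[e].append(math.nan if z is None else z)

    rows = []
    persist: dict[str, bool] = {}
    for e in EMOTIONS:
        smoothed = trailing_mean(z_by_emotion[e], window)
        sig = [
            (not math.isnan(s)) and abs(s) > z_star for s in smoothed
        ]
        n_defined = sum(1 for s in smoothed if not math.isnan(s))
        persist[e] = n_defined > 0 and sum(sig) / n_defined >= persistence
        for day, z, s, flag in zip(days, z_by_emotion[e], smoothed, sig):
            rows.append(
                {"date": day, "emotion": e, "z": z, "smoothed_z": s,
                 "significant": flag}
            )
    frame = pd.DataFrame(
        rows, columns=["date", "emotion", "z", "smoothed_z", "significant"]
    )
    return DailyZSeries(
        frame=frame, persistence=persist, z_star=z_star, window=window
    )


# --------------------------------------------------------------------------
# export


def petal_data(profile: EmotionProfile) -> dict:
    """Plutchik-wheel petal data: length = z, coloured iff outside the gate.

    The grey ring radius is the gate itself — the region within 1.96 standard
    deviations where scores are not statistically odd.
    """
    petals = {}
    for e in EMOTIONS:
        s = profile.scores[e]
        petals[e] = {
            "z": s.z,
            "coloured": s.flag in ("over", "under"),
            "flag": s.flag,
        }
    return {"petals": petals, "ring_radius": profile.z_star, "m": profile.m}


def profile_to_json(profile: EmotionProfile, path: str | Path) -> None:
    obj = {
        "m": profile.m,
        "z_star": profile.z_star,
        "emotions": {
            e: {
                "count": s.count, "mu": s.mu, "sigma": s.sigma,
                "z": s.z, "flag": s.flag,
            }
            for e, s in profile.scores.items()
        },
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
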