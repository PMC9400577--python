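"""Corpus data model, readers/writers, normalization and filtering.

An article corpus is a list of :class:`ArticleRecord` — dated, source-labelled
news items (mainstream vs alternative outlets) with title/body text and
Facebook/Twitter engagement counts.  Records may optionally carry per-sentence
dependency annotations (``heads``/``pos`` arrays) so that synthetic corpora
with exactly known parse trees flow through the same pipeline as real text.

Serialisation formats are JSONL (one object per line) and UTF-8 comma CSV
with a header; dates are ISO 8601.  Emotion lexicons use the NRC word-emotion
TSV dialect (``word<TAB>category<TAB>0|1``); synonym resources are two-column
word-pair TSVs, symmetrised on load.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .stemming import Stemmer, italian_stem
from .stopwords import ITALIAN_STOPWORDS

logger = logging.getLogger(__name__)

SOURCE_CLASSES = ("mainstream", "alternative")

#: The eight primary emotions of Plutchik's wheel, in canonical order.
EMOTIONS = (
    "anger", "anticipation", "disgust", "fear",
    "joy", "sadness", "surprise", "trust",
)

VALENCES = ("positive", "negative", "neutral")

#: Universal-dependencies style tags treated as content (meaning-bearing) words.
CONTENT_POS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})


class CorpusSchemaError(ValueError):
    """A corpus row violates the documented schema."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ArticleRecord:
    """One dated, source-labelled news item with engagement counts."""

    id: str
    domain: str
    source_class: str
    date: dt.date
    title: str
    body: str
    fb_shares: int = 0
    fb_likes: int = 0
    tw_shares: int = 0
    tw_likes: int = 0
    #: optional per-sentence dependency annotations (root head = -1)
    title_heads: tuple[tuple[int, ...], ...] | None = None
    title_pos: tuple[tuple[str, ...], ...] | None = None
    body_heads: tuple[tuple[int, ...], ...] | None = None
    body_pos: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise CorpusSchemaError(
                f"source_class must be one of {SOURCE_CLASSES}, "
                f"got {self.source_class!r}"
            )
        if not isinstance(self.date, dt.date) or isinstance(self.date, dt.datetime):
            raise CorpusSchemaError(f"date must be a datetime.date, got {self.date!r}")
        for name in ("fb_shares", "fb_likes", "tw_shares", "tw_likes"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise CorpusSchemaError(f"{name} must be a non-negative int, got {v!r}")


@dataclass(frozen=True)
class Token:
    surface: str
    stem: str
    is_content: bool


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    heads: tuple[int, ...] | None = None
    pos: tuple[str, ...] | None = None

    def stems(self, content_only: bool = False) -> list[str]:
        return [t.stem for t in self.tokens if t.is_content or not content_only]


@dataclass(frozen=True)
class NormalizedText:
    """Lowercased, punctuation-stripped, sentence-split, stemmed text."""

    sentences: tuple[Sentence, ...]

    def stems(self, content_only: bool = False) -> set[str]:
        out: set[str] = set()
        for s in self.sentences:
            out.update(s.stems(content_only))
        return out

    def render(self) -> str:
        return ". ".join(" ".join(t.surface for t in s.tokens) for s in self.sentences)


@dataclass(frozen=True)
class EmotionLexicon:
    """Word-emotion associations plus positive/negative valence.

    ``vocabulary`` may exceed the keys of ``assoc``/``valence``: a word can be
    listed with no emotion and no polarity (it is then neutral and
    emotionless, but still participates in null-model sampling).
    """

    vocabulary: frozenset[str]
    assoc: dict[str, frozenset[str]] = field(default_factory=dict)
    valence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in self.assoc:
            if w not in self.vocabulary:
                raise ValueError(f"assoc key {w!r} missing from vocabulary")
        for w, v in self.valence.items():
            if w not in self.vocabulary:
                raise ValueError(f"valence key {w!r} missing from vocabulary")
            if v not in VALENCES:
                raise ValueError(f"invalid valence {v!r} for {w!r}")
        bad = {e for es in self.assoc.values() for e in es} - set(EMOTIONS)
        if bad:
            raise ValueError(f"unknown emotions in lexicon: {sorted(bad)}")

    def emotions_of(self, stem: str) -> frozenset[str]:
        return self.assoc.get(stem, frozenset())

    def valence_of(self, stem: str) -> str:
        return self.valence.get(stem, "neutral")


@dataclass(frozen=True)
class SynonymResource:
    """Symmetric, irreflexive set of stem pairs sharing a synset."""

    pairs: frozenset[tuple[str, str]]  # each stored sorted

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"reflexive synonym pair {a!r}")
            if a > b:
                raise ValueError("pairs must be stored in sorted order")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SynonymResource":
        out = set()
        for a, b in pairs:
            if a != b:
                out.add((min(a, b), max(a, b)))
        return cls(frozenset(out))


# --------------------------------------------------------------------------
# normalization

_SENT_SPLIT = re.compile(r"[.!?;\n]+")
_WORD = re.compile(r"[a-zà-ÿ0-9_']+")


def normalize(
    text: str,
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> NormalizedText:
    """Split text into sentences of lowercased, stemmed tokens.

    Content-word flags come from the stopword list here; when POS tags are
    available (annotated records), :func:`normalize_record` recomputes them.
    Empty text yields zero sentences.
    """
    sentences = []
    for chunk in _SENT_SPLIT.split(text.lower()):
        words = [w.strip("'") for w in _WORD.findall(chunk)]
        words = [w for w in words if w]
        if not words:
            continue
        tokens = tuple(
            Token(surface=w, stem=stemmer(w), is_content=w not in stopwords)
            for w in words
        )
        sentences.append(Sentence(tokens=tokens))
    return NormalizedText(sentences=tuple(sentences))


def normalize_record(
    record: ArticleRecord,
    fields: Literal["title", "body", "both"] = "both",
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> NormalizedText:
    """Normalize one article, attaching any dependency annotations.

    Per-sentence ``heads``/``pos`` arrays are attached when their length
    matches the tokenised sentence; on a length mismatch the annotation is
    dropped with a warning (the fixture parser then falls back to a chain
    parse).  With POS available, content flags are recomputed from the tags.
    """
    if fields not in ("title", "body", "both"):
        raise ValueError(f"invalid field selector {fields!r}")
    parts = []
    if fields in ("title", "both"):
        parts.append((record.title, record.title_heads, record.title_pos))
    if fields in ("body", "both"):
        parts.append((record.body, record.body_heads, record.body_pos))

    sentences: list[Sentence] = []
    for text, heads, pos in parts:
        norm = normalize(text, stemmer=stemmer, stopwords=stopwords)
        for i, sent in enumerate(norm.sentences):
            h = tuple(heads[i]) if heads is not None and i < len(heads) else None
            p = tuple(pos[i]) if pos is not None and i < len(pos) else None
            n = len(sent.tokens)
            if h is not None and len(h) != n:
                logger.warning(
                    "article %s: heads annotation length %d != %d tokens; dropped",
                    record.id, len(h), n,
                )
                h = None
            if p is not None and len(p) != n:
                p = None
            if p is not None:
                sent = Sentence(
                    tokens=tuple(
                        Token(t.surface, t.stem, tag in CONTENT_POS)
                        for t, tag in zip(sent.tokens, p)
                    ),
                    heads=h,
                    pos=p,
                )
            else:
                sent = Sentence(tokens=sent.tokens, heads=h, pos=p)
            sentences.append(sent)
    return NormalizedText(sentences=tuple(sentences))


def normalize_lexicon(lexicon: EmotionLexicon, stemmer: Stemmer) -> EmotionLexicon:
    """Re-key a lexicon through the pipeline's stemmer.

    Words colliding under stemming merge: emotions are unioned; a valence
    conflict (both positive and negative claimants) resolves to neutral.
    """
    vocab: set[str] = set()
    assoc: dict[str, set[str]] = {}
    val_votes: dict[str, set[str]] = {}
    for w in lexicon.vocabulary:
        s = stemmer(w)
        vocab.add(s)
        if w in lexicon.assoc:
            assoc.setdefault(s, set()).update(lexicon.assoc[w])
        if w in lexicon.valence:
            val_votes.setdefault(s, set()).add(lexicon.valence[w])
    valence = {}
    for s, votes in val_votes.items():
        votes = votes - {"neutral"}
        if len(votes) == 1:
            valence[s] = votes.pop()
    return EmotionLexicon(
        vocabulary=frozenset(vocab),
        assoc={w: frozenset(v) for w, v in assoc.items()},
        valence=valence,
    )


# --------------------------------------------------------------------------
# corpus IO

_REQUIRED = ("id", "domain", "source_class", "date", "title", "body")
_COUNTS = ("fb_shares", "fb_likes", "tw_shares", "tw_likes")
_ANNOT = ("title_heads", "title_pos", "body_heads", "body_pos")


def _record_from_dict(obj: dict, where: str) -> ArticleRecord:
    for key in _REQUIRED:
        if key not in obj or obj[key] is None:
            raise CorpusSchemaError(f"{where}: missing required field {key!r}")
    try:
        date = dt.date.fromisoformat(str(obj["date"]))
    except ValueError as exc:
        raise CorpusSchemaError(f"{where}: unparseable date {obj['date']!r}") from exc
    counts = {}
    for key in _COUNTS:
        raw = obj.get(key, 0)
        try:
            counts[key] = int(raw)
        except (TypeError, ValueError) as exc:
            raise CorpusSchemaError(f"{where}: bad count {key}={raw!r}") from exc
    annots = {}
    for key in _ANNOT:
        raw = obj.get(key)
        if raw in (None, ""):
            annots[key] = None
        else:
            if isinstance(raw, str):
                raw = json.loads(raw)
            annots[key] = tuple(tuple(x) for x in raw)
    try:
        return ArticleRecord(
            id=str(obj["id"]), domain=str(obj["domain"]),
            source_class=str(obj["source_class"]), date=date,
            title=str(obj["title"]), body=str(obj["body"]),
            **counts, **annots,
        )
    except CorpusSchemaError as exc:
        raise CorpusSchemaError(f"{where}: {exc}") from exc


def _record_to_dict(r: ArticleRecord) -> dict:
    obj = {
        "id": r.id, "domain": r.domain, "source_class": r.source_class,
        "date": r.date.isoformat(), "title": r.title, "body": r.body,
        **{k: getattr(r, k) for k in _COUNTS},
    }
    for key in _ANNOT:
        v = getattr(r, key)
        if v is not None:
            obj[key] = [list(x) for x in v]
    return obj


def load_corpus(
    path: str | Path,
    format: Literal["jsonl", "csv"] | None = None,
    strict: bool = True,
) -> list[ArticleRecord]:
    """Read a corpus file; malformed rows raise (strict) or are skipped."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    records: list[ArticleRecord] = []

    def handle(obj: dict, where: str) -> None:
        try:
            records.append(_record_from_dict(obj, where))
        except CorpusSchemaError:
            if strict:
                raise
            logger.warning("skipping malformed row at %s", where)

    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    if strict:
                        raise CorpusSchemaError(
                            f"line {lineno}: invalid JSON"
                        ) from exc
                    logger.warning("skipping invalid JSON at line %d", lineno)
                    continue
                handle(obj, f"line {lineno}")
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = set(_REQUIRED) - set(reader.fieldnames)
            if missing:
                raise CorpusSchemaError(f"CSV header missing fields {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                handle({k: v for k, v in row.items() if v != ""}, f"line {lineno}")
    return records


def write_corpus(
    records: Sequence[ArticleRecord],
    path: str | Path,
    format: Literal["jsonl", "csv"] | None = None,
) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(_record_to_dict(r), ensure_ascii=False) + "\n")
    elif format == "csv":
        fields = list(_REQUIRED) + list(_COUNTS) + list(_ANNOT)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for r in records:
                obj = _record_to_dict(r)
                for key in _ANNOT:
                    if key in obj:
                        obj[key] = json.dumps(obj[key])
                writer.writerow(obj)
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# --------------------------------------------------------------------------
# lexicon / synonym IO

_NRC_CATEGORIES = set(EMOTIONS) | {"positive", "negative"}


def load_lexicon(path: str | Path, stemmer: Stemmer | None = None) -> EmotionLexicon:
    """Read an NRC-dialect TSV (``word<TAB>category<TAB>0|1``).

    If a stemmer is given the lexicon is re-keyed through it so that its
    entries match pipeline stems.
    """
    vocab: set[str] = set()
    assoc: dict[str, set[str]] = {}
    pos_neg: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusSchemaError(f"lexicon line {lineno}: expected 3 columns")
            word, category, flag = parts
            if category not in _NRC_CATEGORIES:
                raise CorpusSchemaError(
                    f"lexicon line {lineno}: unknown category {category!r}"
                )
            word = word.strip().lower()
            vocab.add(word)
            if flag == "1":
                if category in ("positive", "negative"):
                    pos_neg.setdefault(word, set()).add(category)
                else:
                    assoc.setdefault(word, set()).add(category)
    valence = {}
    for w, flags in pos_neg.items():
        if len(flags) == 1:
            valence[w] = flags.pop()  # both flags set -> neutral (omitted)
    lex = EmotionLexicon(
        vocabulary=frozenset(vocab),
        assoc={w: frozenset(v) for w, v in assoc.items()},
        valence=valence,
    )
    return normalize_lexicon(lex, stemmer) if stemmer else lex


def write_lexicon(lexicon: EmotionLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for w in sorted(lexicon.vocabulary):
            for e in EMOTIONS:
                fh.write(f"{w}\t{e}\t{int(e in lexicon.emotions_of(w))}\n")
            v = lexicon.valence_of(w)
            fh.write(f"{w}\tpositive\t{int(v == 'positive')}\n")
            fh.write(f"{w}\tnegative\t{int(v == 'negative')}\n")


def load_synonyms(path: str | Path, stemmer: Stemmer | None = None) -> SynonymResource:
    """Read a two-column word-pair TSV, symmetrising and de-duplicating."""
    pairs = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusSchemaError(f"synonym line {lineno}: expected 2 columns")
            a, b = (p.strip().lower() for p in parts)
            if stemmer:
                a, b = stemmer(a), stemmer(b)
            pairs.append((a, b))
    return SynonymResource.from_pairs(pairs)


def write_synonyms(synonyms: SynonymResource, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b in sorted(synonyms.pairs):
            fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------------------
# filtering / splitting


def filter_by_stem(
    corpus: Sequence[ArticleRecord],
    stem: str,
    fields: Literal["title", "body", "either"] = "either",
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> list[ArticleRecord]:
    """Records whose chosen field's normalized stems contain ``stem``.

    ``stem`` must itself already be normalized; order is preserved.
    """
    if fields not in ("title", "body", "either"):
        raise ValueError(f"invalid field selector {fields!r}")
    out = []
    for r in corpus:
        texts = []
        if fields in ("title", "either"):
            texts.append(r.title)
        if fields in ("body", "either"):
            texts.append(r.body)
        for text in texts:
            if stem in normalize(text, stemmer=stemmer, stopwords=stopwords).stems():
                out.append(r)
                break
    return out


def split_by_date(
    corpus: Sequence[ArticleRecord], cutoff: dt.date
) -> tuple[list[ArticleRecord], list[ArticleRecord]]:
    """Partition records into (before, after); the cutoff day itself is "after"."""
    before = [r for r in corpus if r.date < cutoff]
    after = [r for r in corpus if r.date >= cutoff]
    return before, after
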