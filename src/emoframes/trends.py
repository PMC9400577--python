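"""Term prevalence, relative-change statistics and engagement analytics.

These are the descriptive statistics around the network core: how often each
source class mentions a stem per day (with 7-day trailing smoothing), how a
daily series changes around an event relative to reference windows, total
shares/likes per platform and source class, the log-binned share heatmap,
and the standard association tests (Pearson correlation of per-article
Facebook vs Twitter shares; a Wilcoxon rank-sum comparison of per-article
likes-per-share between source classes).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import SOURCE_CLASSES, ArticleRecord, filter_by_stem
from .emotions import trailing_mean
from .frames import UndefinedBaselineError
from .stemming import Stemmer, italian_stem
from .stopwords import ITALIAN_STOPWORDS


@dataclass
class PrevalenceSeries:
    """Daily fraction of each source class's articles mentioning a stem."""

    stem: str
    fields: str
    window: int
    frame: pd.DataFrame  # date, source_class, n_articles, n_mentions,
    #                      fraction, smoothed

    def series(self, source_class: str, smoothed: bool = True) -> pd.Series:
        sub = self.frame[self.frame.source_class == source_class]
        col = "smoothed" if smoothed else "fraction"
        return pd.Series(sub[col].values, index=pd.Index(sub.date, name="date"))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def prevalence(
    corpus: Sequence[ArticleRecord],
    stem: str,
    fields: Literal["title", "body", "either"] = "body",
    window: int = 7,
    stemmer: Stemmer = italian_stem,
    stopwords: frozenset[str] = ITALIAN_STOPWORDS,
) -> PrevalenceSeries:
    """Per-day, per-class fraction of articles whose field contains the stem.

    Days on which a class published nothing are gaps (absent rows), not
    zeros; smoothing is the trailing mean over the last ``window`` defined
    days of that class.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hits = {
        r.id for r in filter_by_stem(
            corpus, stem, fields=fields, stemmer=stemmer, stopwords=stopwords
        )
    }
    rows = []
    for cls in SOURCE_CLASSES:
        by_day: dict[dt.date, list[ArticleRecord]] = {}
        for r in corpus:
            if r.source_class == cls:
                by_day.setdefault(r.date, []).append(r)
        days = sorted(by_day)
        fractions = []
        for day in days:
            arts = by_day[day]
            n_hits = sum(1 for r in arts if r.id in hits)
            fractions.append(n_hits / len(arts))
        smoothed = trailing_mean(fractions, window)
        for day, frac, sm in zip(days, fractions, smoothed):
            rows.append(
                {"date": day, "source_class": cls,
                 "n_articles": len(by_day[day]),
                 "n_mentions": round(frac * len(by_day[day])),
                 "fraction": frac, "smoothed": sm}
            )
    frame = pd.DataFrame(
        rows,
        columns=["date", "source_class", "n_articles", "n_mentions",
                 "fraction", "smoothed"],
    ).sort_values(["source_class", "date"], ignore_index=True)
    return PrevalenceSeries(stem=stem, fields=fields, window=window, frame=frame)


def relative_change(
    series: pd.Series,
    event_date: dt.date,
    event_halfwidth: int = 2,
    ref_windows: tuple[tuple[dt.date, dt.date], tuple[dt.date, dt.date]] | None = None,
) -> float:
    """Percent change of the event-window mean vs pooled reference windows.

    ``series`` is indexed by date; NaNs are gaps.  The event window is
    ``event_date ± event_halfwidth`` days.  By default the references are
    the first five and last five days of the event month.  A zero (or
    undefined) reference mean has no defined baseline.
    """
    if ref_windows is None:
        month_start = event_date.replace(day=1)
        next_month = (month_start + dt.timedelta(days=32)).replace(day=1)
        month_end = next_month - dt.timedelta(days=1)
        ref_windows = (
            (month_start, month_start + dt.timedelta(days=4)),
            (month_end - dt.timedelta(days=4), month_end),
        )
    half = dt.timedelta(days=event_halfwidth)

    def window_values(lo: dt.date, hi: dt.date) -> list[float]:
        return [
            float(v) for d, v in series.items()
            if lo <= d <= hi and not math.isnan(float(v))
        ]

    event_vals = window_values(event_date - half, event_date + half)
    ref_vals = [v for lo, hi in ref_windows for v in window_values(lo, hi)]
    if not event_vals or not ref_vals:
        raise UndefinedBaselineError("empty event or reference window")
    ref_mean = sum(ref_vals) / len(ref_vals)
    if ref_mean == 0:
        raise UndefinedBaselineError("reference mean is zero")
    event_mean = sum(event_vals) / len(event_vals)
    return 100.0 * (event_mean - ref_mean) / ref_mean


# --------------------------------------------------------------------------
# engagement


def engagement_summary(corpus: Sequence[ArticleRecord]) -> dict:
    """Total shares/likes and likes-per-share per platform and source class.

    The likes-per-share ratio is rounded to two decimals; with zero shares
    it is reported as ``None`` with an explicit ``ratio_defined`` flag.
    """
    out: dict = {}
    groups = {"overall": list(corpus)}
    for cls in SOURCE_CLASSES:
        groups[cls] = [r for r in corpus if r.source_class == cls]
    for platform, share_f, like_f in (
        ("facebook", "fb_shares", "fb_likes"),
        ("twitter", "tw_shares", "tw_likes"),
    ):
        out[platform] = {}
        for name, records in groups.items():
            shares = sum(getattr(r, share_f) for r in records)
            likes = sum(getattr(r, like_f) for r in records)
            out[platform][name] = {
                "shares": shares,
                "likes": likes,
                "likes_per_share": round(likes / shares, 2) if shares else None,
                "ratio_defined": shares > 0,
                "n_articles": len(records),
            }
    return out


@dataclass
class ShareHeatmap:
    """2D article histogram over (Facebook shares, Twitter shares).

    Axes are logarithmically binned, with a dedicated [0, 1) bin for
    articles never shared on a platform.
    """

    fb_edges: np.ndarray
    tw_edges: np.ndarray
    counts: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.fb_edges[:-1], name="fb_bin_left"),
            columns=self.tw_edges[:-1],
        )
        df.to_csv(path)


def _log_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    top = max(float(values.max()), 1.0) + 1.0
    return np.concatenate([[0.0], np.geomspace(1.0, top, n_bins)])


def share_heatmap(
    corpus: Sequence[ArticleRecord], n_bins: int = 20
) -> ShareHeatmap:
    fb = np.array([r.fb_shares for r in corpus], dtype=float)
    tw = np.array([r.tw_shares for r in corpus], dtype=float)
    if len(corpus) == 0:
        edges = np.array([0.0, 1.0])
        return ShareHeatmap(edges, edges, np.zeros((1, 1)))
    fb_edges = _log_edges(fb, n_bins)
    tw_edges = _log_edges(tw, n_bins)
    counts, _, _ = np.histogram2d(fb, tw, bins=[fb_edges, tw_edges])
    return ShareHeatmap(fb_edges=fb_edges, tw_edges=tw_edges, counts=counts)


@dataclass
class AssociationTests:
    pearson_r: float | None
    pearson_p: float | None
    pearson_defined: bool
    ranksum: dict[str, dict]  # per platform: statistic, p_value, n per class


def association_tests(corpus: Sequence[ArticleRecord]) -> AssociationTests:
    """Pearson correlation of platform shares; rank-sum test of like ratios.

    Pearson is computed on raw per-article (Facebook, Twitter) share counts
    (constant input flags the correlation undefined).  The two-sided
    Wilcoxon rank-sum test compares mainstream vs alternative per-article
    likes-per-share ratios (articles with zero shares on a platform are
    excluded from that platform's test).
    """
    if len(corpus) < 3:
        raise ValueError("association tests need at least 3 articles")
    fb = np.array([r.fb_shares for r in corpus], dtype=float)
    tw = np.array([r.tw_shares for r in corpus], dtype=float)
    if fb.std() == 0 or tw.std() == 0:
        pearson_r, pearson_p, defined = None, None, False
    else:
        res = stats.pearsonr(fb, tw)
        pearson_r, pearson_p, defined = float(res.statistic), float(res.pvalue), True

    ranksum = {}
    for platform, share_f, like_f in (
        ("facebook", "fb_shares", "fb_likes"),
        ("twitter", "tw_shares", "tw_likes"),
    ):
        ratios = {}
        for cls in SOURCE_CLASSES:
            ratios[cls] = [
                getattr(r, like_f) / getattr(r, share_f)
                for r in corpus
                if r.source_class == cls and getattr(r, share_f) > 0
            ]
        if all(len(v) >= 1 for v in ratios.values()):
            res = stats.ranksums(*(ratios[c] for c in SOURCE_CLASSES))
            ranksum[platform] = {
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "n": {c: len(ratios[c]) for c in SOURCE_CLASSES},
            }
        else:
            ranksum[platform] = {
                "statistic": None, "p_value": None,
                "n": {c: len(ratios[c]) for c in SOURCE_CLASSES},
            }
    return AssociationTests(
        pearson_r=pearson_r, pearson_p=pearson_p, pearson_defined=defined,
        ranksum=ranksum,
    )
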