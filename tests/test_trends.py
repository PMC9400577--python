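"""Prevalence, relative change, engagement totals, heatmap, associations."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from emoframes import (
    association_tests,
    engagement_summary,
    identity_stemmer,
    prevalence,
    relative_change,
    share_heatmap,
)
from emoframes.frames import UndefinedBaselineError

from conftest import make_record


def day(offset):
    return dt.date(2021, 3, 1) + dt.timedelta(days=offset)


# ---------------------------------------------------------------- prevalence


def test_all_articles_mentioning_gives_fraction_one():
    corpus = [
        make_record(rid=str(i), body="mort", date=day(i % 3),
                    source_class="mainstream")
        for i in range(6)
    ]
    series = prevalence(corpus, "mort", fields="body", stemmer=identity_stemmer)
    main = series.frame[series.frame.source_class == "mainstream"]
    assert (main.fraction == 1.0).all()
    assert (main.smoothed == 1.0).all()


def test_known_daily_hit_counts():
    corpus = []
    # day 0: 1 of 4 mainstream mention; day 1: 3 of 4
    for i in range(4):
        corpus.append(make_record(rid=f"d0-{i}", date=day(0),
                                  body="mort" if i == 0 else "altro",
                                  source_class="mainstream"))
    for i in range(4):
        corpus.append(make_record(rid=f"d1-{i}", date=day(1),
                                  body="mort" if i < 3 else "altro",
                                  source_class="mainstream"))
    series = prevalence(corpus, "mort", fields="body", stemmer=identity_stemmer)
    main = series.frame[series.frame.source_class == "mainstream"]
    assert list(main.fraction) == [0.25, 0.75]
    assert list(main.n_mentions) == [1, 3]
    # alternative published nothing: gaps, not zeros
    assert series.frame[series.frame.source_class == "alternative"].empty


def test_smoothing_is_trailing_mean_of_fractions():
    rng = np.random.default_rng(3)
    corpus = []
    for d in range(20):
        for i in range(5):
            corpus.append(make_record(
                rid=f"{d}-{i}", date=day(d), source_class="alternative",
                body="trombos" if rng.random() < 0.4 else "x"))
    series = prevalence(corpus, "trombos", fields="body",
                        stemmer=identity_stemmer, window=7)
    alt = series.frame[series.frame.source_class == "alternative"]
    fr = list(alt.fraction)
    for k, sm in enumerate(alt.smoothed):
        chunk = fr[max(0, k - 6):k + 1]
        assert sm == pytest.approx(sum(chunk) / len(chunk))
    assert ((alt.fraction >= 0) & (alt.fraction <= 1)).all()


# ----------------------------------------------------------- relative change


def idx_series(values, start=0):
    return pd.Series(
        list(values),
        index=[day(start + i) for i in range(len(values))],
    )


def test_flat_series_changes_zero_percent():
    s = idx_series([0.2] * 31)
    assert relative_change(s, day(14)) == pytest.approx(0.0)


def test_direct_formula_example():
    """Event mean 0.39 vs reference mean 0.20 -> +95%."""
    values = [0.20] * 31
    for off in (12, 13, 14, 15, 16):
        values[off] = 0.39
    s = idx_series(values)
    got = relative_change(s, day(14), event_halfwidth=2)
    assert got == pytest.approx(95.0)


def test_step_doubling_gives_plus_100():
    values = [0.1] * 5 + [0.2] * 21 + [0.1] * 5
    s = idx_series(values)
    assert relative_change(s, day(14), event_halfwidth=2) == pytest.approx(100.0)


def test_zero_reference_is_undefined():
    s = idx_series([0.0] * 10 + [0.5] * 11 + [0.0] * 10)
    with pytest.raises(UndefinedBaselineError):
        relative_change(s, day(14))


# ----------------------------------------------------------------- engagement


def test_printed_aggregate_ratio():
    corpus = [
        make_record(rid="m", fb_shares=5_300_000, fb_likes=3_400_000),
    ]
    summary = engagement_summary(corpus)
    assert summary["facebook"]["overall"]["likes_per_share"] == 0.64


def test_zero_shares_ratio_undefined():
    summary = engagement_summary([make_record(rid="1")])
    fb = summary["facebook"]["overall"]
    assert fb["likes_per_share"] is None and not fb["ratio_defined"]


def test_totals_equal_per_record_sums():
    rng = np.random.default_rng(8)
    corpus = [
        make_record(
            rid=str(i),
            source_class="mainstream" if i % 2 else "alternative",
            fb_shares=int(rng.integers(0, 100)),
            fb_likes=int(rng.integers(0, 100)),
            tw_shares=int(rng.integers(0, 100)),
            tw_likes=int(rng.integers(0, 100)),
        )
        for i in range(100)
    ]
    summary = engagement_summary(corpus)
    for platform, share_f in (("facebook", "fb_shares"), ("twitter", "tw_shares")):
        assert summary[platform]["overall"]["shares"] == sum(
            getattr(r, share_f) for r in corpus)
        assert (summary[platform]["mainstream"]["shares"]
                + summary[platform]["alternative"]["shares"]
                == summary[platform]["overall"]["shares"])


# -------------------------------------------------------------------- heatmap


def test_single_article_single_cell():
    hm = share_heatmap([make_record(fb_shares=300, tw_shares=14)])
    assert hm.counts.sum() == 1
    assert (hm.counts == 1).sum() == 1


def test_heatmap_mass_conservation():
    rng = np.random.default_rng(21)
    corpus = [
        make_record(rid=str(i),
                    fb_shares=int(rng.integers(0, 10000)),
                    tw_shares=int(rng.integers(0, 500)))
        for i in range(250)
    ]
    hm = share_heatmap(corpus)
    assert hm.counts.sum() == len(corpus)


def test_all_zero_shares_land_in_zero_zero_cell():
    corpus = [make_record(rid=str(i)) for i in range(7)]
    hm = share_heatmap(corpus)
    assert hm.counts[0, 0] == 7
    assert hm.counts.sum() == 7


# ---------------------------------------------------------------- assoc tests


def test_perfect_linear_correlation():
    corpus = [
        make_record(rid=str(i), fb_shares=10 * (i + 1), tw_shares=i + 1,
                    source_class="mainstream" if i % 2 else "alternative")
        for i in range(10)
    ]
    res = association_tests(corpus)
    assert res.pearson_r == pytest.approx(1.0)


def test_pearson_matches_textbook_formula():
    fb = [12, 40, 7, 55, 23, 9, 31, 18, 66, 5]
    tw = [3, 10, 2, 9, 8, 1, 6, 4, 12, 2]
    corpus = [
        make_record(rid=str(i), fb_shares=f, tw_shares=t,
                    source_class="mainstream" if i % 2 else "alternative")
        for i, (f, t) in enumerate(zip(fb, tw))
    ]
    x, y = np.array(fb, float), np.array(tw, float)
    expected = (((x - x.mean()) * (y - y.mean())).sum()
                / math.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
    res = association_tests(corpus)
    assert res.pearson_r == pytest.approx(expected)


def test_constant_shares_flag_undefined_correlation():
    corpus = [make_record(rid=str(i), fb_shares=5, tw_shares=i + 1,
                          source_class="mainstream" if i % 2 else "alternative")
              for i in range(5)]
    res = association_tests(corpus)
    assert not res.pearson_defined and res.pearson_r is None


def test_identical_class_distributions_not_rejected():
    """Same like-ratio distribution in both classes: rank-sum p is large."""
    rng = np.random.default_rng(77)
    corpus = []
    for i in range(600):
        shares = int(rng.integers(10, 1000))
        likes = int(rng.poisson(0.6 * shares))
        corpus.append(make_record(
            rid=str(i), fb_shares=shares, fb_likes=likes,
            tw_shares=shares, tw_likes=likes,
            source_class="mainstream" if i % 2 else "alternative"))
    res = association_tests(corpus)
    assert res.ranksum["facebook"]["p_value"] > 0.05


def test_too_small_corpus_rejected():
    with pytest.raises(ValueError):
        association_tests([make_record()])
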