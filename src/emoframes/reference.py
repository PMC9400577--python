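"""Reference data for the Italian COVID-19 vaccine news study corpus.

The corpus this package was designed around covers vaccine-related articles
from Italian news outlets between October 2020 and May 2021, labelled
mainstream or alternative by third-party fact-checker listings.  The full
article data lives in an external OSF deposit; what is recorded here are the
published summary facts needed to validate pipeline outputs without it: the
outlet table and the aggregate engagement counts.
"""

from __future__ import annotations

import datetime as dt

#: outlet web domains and their source-class label (fact-checker listings)
OUTLETS: tuple[tuple[str, str], ...] = (
    ("ilfattoquotidiano.it", "mainstream"),
    ("repubblica.it", "mainstream"),
    ("lastampa.it", "mainstream"),
    ("imolaoggi.it", "alternative"),
    ("voxnews.info", "alternative"),
    ("renovatio21.com", "alternative"),
    ("byoblu.com", "alternative"),
    ("maurizioblondet.it", "alternative"),
    ("scenarieconomici.it", "alternative"),
    ("mag24.es", "alternative"),
    ("irresponsabile.com", "alternative"),
    ("disinformazione.it", "alternative"),
    ("internapoli.it", "alternative"),
    ("centrometeoitaliano.it", "alternative"),
    ("essere-informati.it", "alternative"),
    ("dionidream.com", "alternative"),
    ("fonteverificata.it", "alternative"),
)

#: articles retained after scraping and filtering, per source class
ARTICLE_COUNTS = {"mainstream": 3447, "alternative": 2298}

#: aggregate engagement across the whole corpus
ENGAGEMENT_TOTALS = {
    "facebook": {"shares": 5_300_000, "likes": 3_400_000},
    "twitter": {"shares": 192_000, "likes": 336_000},
}

#: observation window of the corpus
STUDY_WINDOW = (dt.date(2020, 10, 1), dt.date(2021, 5, 31))

#: day the AstraZeneca administration was temporarily suspended in Italy
SUSPENSION_DATE = dt.date(2021, 3, 15)

#: stems the analyses target
TARGET_STEMS = ("vaccin", "astrazenec", "pfizer", "mort", "trombos")
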