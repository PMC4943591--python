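"""Arithmetic over classification count tables.

The same summaries apply to a pipeline run on a synthetic corpus and to the
published count tables shipped as fixtures (``vapewatch/data/reported_*``):
category shares, the discarded fraction, automated-URL share and per-topic
percentages of the yearly automated totals.

Denominator conventions (derivable from the published tables' own
arithmetic, and documented here once):

* the **automated share** is automated / (automated + organic) — discarded
  tweets, being unclassifiable, are excluded from the denominator;
* the **discarded share** uses all collected tweets as denominator;
* a **topic percentage** uses that year's automated tweet total.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reported_tweet_counts",
    "load_reported_subcategory_counts",
    "REPORTED_AUTOMATED_URL_COUNT",
    "automated_share",
    "discarded_share",
    "automated_url_share",
    "subcategory_percentages",
    "cessation_totals",
]

# Published aggregate: automated tweets carrying a URL, 2012-2014 pooled.
REPORTED_AUTOMATED_URL_COUNT = 607_446


def _read_data_csv(name: str) -> pd.DataFrame:
    ref = resources.files("vapewatch.data").joinpath(name)
    with ref.open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_reported_tweet_counts() -> pd.DataFrame:
    """Published yearly tweet-category and account-classification counts."""
    return _read_data_csv("reported_tweet_counts.csv")


def load_reported_subcategory_counts() -> pd.DataFrame:
    """Published per-topic automated tweet counts and impressions (millions)."""
    return _read_data_csv("reported_subcategory_counts.csv")


def automated_share(counts: pd.DataFrame) -> float:
    """Automated percentage of classified (automated + organic) tweets."""
    auto = counts["automated"].sum()
    org = counts["organic"].sum()
    return round(100.0 * auto / (auto + org), 2)


def discarded_share(counts: pd.DataFrame) -> float:
    """Discarded percentage of all collected tweets."""
    return round(100.0 * counts["discarded"].sum() / counts["total"].sum(), 2)


def automated_url_share(n_automated_with_url: int, n_automated: int) -> float:
    """Percentage of automated tweets that carry a hyperlink."""
    if n_automated <= 0:
        raise ValueError("no automated tweets")
    return round(100.0 * n_automated_with_url / n_automated, 2)


def subcategory_percentages(
    subcounts: pd.DataFrame, counts: pd.DataFrame
) -> pd.DataFrame:
    """Attach each topic-year count's share of that year's automated total."""
    totals = counts.set_index("year")["automated"]
    out = subcounts.copy()
    out["percentage"] = [
        round(100.0 * row["count"] / totals[row["year"]], 2)
        for _, row in out.iterrows()
    ]
    return out


def cessation_totals(subcounts: pd.DataFrame) -> tuple[int, float]:
    """Pooled cessation tweet count and impressions (millions) across years."""
    ces = subcounts[subcounts["topic"] == "cessation"]
    return int(ces["count"].sum()), float(round(ces["impressions_millions"].sum(), 2))
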