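#!/usr/bin/env python
"""Re-derive the published summary percentages from the count tables.

Feeds the shipped fixture tables (yearly tweet-category counts and
per-topic automated counts) through the reporting arithmetic and prints
each derived share: the overall automated share of classified tweets, the
discarded and automated-URL shares, per-topic yearly percentages, and the
pooled cessation totals.
"""

from pathlib import Path

from vapewatch.reporting import (
    REPORTED_AUTOMATED_URL_COUNT,
    automated_share,
    automated_url_share,
    cessation_totals,
    discarded_share,
    load_reported_subcategory_counts,
    load_reported_tweet_counts,
    subcategory_percentages,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = load_reported_tweet_counts()
    subcounts = load_reported_subcategory_counts()
    print(f"automated share of classified tweets: {automated_share(counts):.2f}%")
    print(f"discarded share of all tweets:        {discarded_share(counts):.2f}%")
    url_share = automated_url_share(
        REPORTED_AUTOMATED_URL_COUNT, counts["automated"].sum()
    )
    print(f"automated tweets carrying a URL:      {url_share:.2f}%")
    shares = subcategory_percentages(subcounts, counts)
    print(shares.to_string(index=False))
    n, impressions_m = cessation_totals(subcounts)
    print(f"cessation pooled: {n} tweets, {impressions_m:.2f}M impressions")
    RESULTS.mkdir(exist_ok=True)
    shares.to_csv(RESULTS / "published_topic_shares.csv", index=False)


if __name__ == "__main__":
    main()
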