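#!/usr/bin/env python
"""Sub-categorize automated tweets by topic and estimate social reach.

Automated-labeled tweets are tallied into the four (overlapping) topics —
commercial, cessation, discount, flavor — per local-time year, with
impressions (summed follower counts) per cell.  Cyborg testimonial
templates are counted separately.  For comparison, the same percentage
arithmetic applied to the published count tables is written alongside.
"""

from pathlib import Path

import pandas as pd

from vapewatch.corpus_io import default_keyword_config, read_corpus
from vapewatch.reporting import (
    load_reported_subcategory_counts,
    load_reported_tweet_counts,
    subcategory_percentages,
)
from vapewatch.topics import cyborg_match, default_cyborg_templates, topic_year_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tweets = {t.tweet_id: t for t in read_corpus(RESULTS / "corpus" / "corpus.jsonl")}
    labels = pd.read_csv(RESULTS / "tweet_labels.csv")
    automated = [tweets[tid] for tid in labels[labels.label == "automated"].tweet_id]
    config = default_keyword_config()

    summary = topic_year_summary(automated, config)
    summary.to_csv(RESULTS / "topic_summary.csv", index=False)
    print("synthetic automated tweets by topic and year:")
    print(summary.to_string(index=False))

    templates = default_cyborg_templates()
    n_cyborg = sum(1 for t in automated if cyborg_match(t.text, templates)[0])
    print(f"\n{n_cyborg} automated tweets instantiate a cyborg testimonial template")

    published = subcategory_percentages(
        load_reported_subcategory_counts(), load_reported_tweet_counts()
    )
    published.to_csv(RESULTS / "published_topic_shares.csv", index=False)
    print("\npublished subcategory shares re-derived from the count tables:")
    print(published.to_string(index=False))


if __name__ == "__main__":
    main()
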