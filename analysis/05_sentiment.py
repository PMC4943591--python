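#!/usr/bin/env python
"""Hedonometric sentiment of organic vs automated tweets over time.

Scores each label class against a seeded synthetic happiness lexicon:
monthly average-happiness series per class, then a word-shift decomposition
of the organic→automated happiness gap showing which words drive it.
"""

from pathlib import Path

import pandas as pd

from vapewatch.hedonometrics import count_words, monthly_series, word_shift
from vapewatch.corpus_io import read_corpus
from vapewatch.synthetic import generate_lexicon

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tweets = {t.tweet_id: t for t in read_corpus(RESULTS / "corpus" / "corpus.jsonl")}
    labels = pd.read_csv(RESULTS / "tweet_labels.csv").set_index("tweet_id")["label"]
    lexicon = generate_lexicon(5000, seed=3)
    lexicon.save(RESULTS / "synthetic_lexicon.tsv")

    frames = []
    for cls in ("organic", "automated"):
        group = [t for tid, t in tweets.items() if labels[tid] == cls]
        series = monthly_series(group, lexicon)
        series["class"] = cls
        frames.append(series)
        if not series.empty:
            print(
                f"{cls}: {len(group)} tweets, mean monthly happiness "
                f"{series.h_avg.mean():.3f} "
                f"({series.month.iloc[0]}..{series.month.iloc[-1]})"
            )
    pd.concat(frames).to_csv(RESULTS / "monthly_happiness.csv", index=False)

    organic = [t for tid, t in tweets.items() if labels[tid] == "organic"]
    automated = [t for tid, t in tweets.items() if labels[tid] == "automated"]
    ws = word_shift(
        count_words(t.text for t in organic),
        count_words(t.text for t in automated),
        lexicon,
        k=25,
    )
    (RESULTS / "word_shift_organic_vs_automated.txt").write_text(
        ws.render(), encoding="utf-8"
    )
    print("\nword shift, organic (reference) → automated (comparison):")
    print(ws.render())


if __name__ == "__main__":
    main()
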