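#!/usr/bin/env python
"""Calibrate the organic feature box and classify the corpus.

Calibration uses 752 fresh synthetic organic accounts (the size of the human
training class of the original detector) at the 99th-percentile setting.
The full cascade then labels every tweet (keyword tier → marketing-user flag
→ box classifier → default/discard rules) and the account-level confusion
against the generator's ground truth is reported.
"""

from pathlib import Path

import pandas as pd

from vapewatch.benchmark import train_calibration
from vapewatch.classifier import classify_corpus, label_counts
from vapewatch.corpus_io import default_keyword_config, read_corpus

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tweets = read_corpus(RESULTS / "corpus" / "corpus.jsonl")
    truth = pd.read_csv(RESULTS / "corpus" / "truth.csv")
    acct_truth = truth[truth.kind == "account"].set_index("id")["label"]

    cal = train_calibration(seed=11)
    cal.save(RESULTS / "calibration.yaml")
    tweet_labels, acct_labels = classify_corpus(tweets, default_keyword_config(), cal)

    pd.DataFrame(
        [(l.tweet_id, l.label, l.source) for l in tweet_labels.values()],
        columns=["tweet_id", "label", "source"],
    ).to_csv(RESULTS / "tweet_labels.csv", index=False)
    pd.DataFrame(
        [(l.account_id, l.label, acct_truth.get(l.account_id, "?"))
         for l in acct_labels.values()],
        columns=["account_id", "label", "true_class"],
    ).to_csv(RESULTS / "account_labels.csv", index=False)

    counts = label_counts(tweet_labels)
    print("tweet label partition:", counts, "| total", len(tweets))
    # account-level confusion: cyborgs count as automated ground truth
    tp = fn = fp = tn = 0
    for aid, got in acct_labels.items():
        want = "automated" if acct_truth[aid] in ("automated", "cyborg") else "organic"
        if want == "automated":
            tp += got.label == "automated"
            fn += got.label == "organic"
        else:
            fp += got.label == "automated"
            tn += got.label == "organic"
    print(f"account-level: TP rate {tp / (tp + fn):.3f}, FP rate {fp / (fp + tn):.3f}")
    print(f"wrote {RESULTS / 'tweet_labels.csv'} and {RESULTS / 'account_labels.csv'}")


if __name__ == "__main__":
    main()
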