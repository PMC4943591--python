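"""The synthetic automation-detection benchmark, end to end.

Bundles the study conditions under which the detection cascade is evaluated:
calibrate the organic feature box on a training set of 752 trusted organic
accounts (the size of the human class the original detector was trained on),
then classify a fresh mixed corpus of 100 automated + 100 organic accounts
and score account-level recovery against the generator's ground truth.
Both the test suite and the acceptance script run exactly this code.
"""

from __future__ import annotations



import numpy as np

from .classifier import BoxCalibration, calibrate, classify_corpus, label_counts
from .corpus_io import default_keyword_config
from .synthetic import GeneratorConfig, generate_account, generate_corpus

__all__ = ["train_calibration", "automation_benchmark"]

N_TRAINING_ORGANIC = 752


def train_calibration(
    seed: int = 11,
    n_train: int = N_TRAINING_ORGANIC,
    percentile: float = 99.0,
    config: GeneratorConfig | None = None,
) -> BoxCalibration:
    """Calibrate the organic box on a seeded synthetic organic training set."""
    cfg = config or GeneratorConfig(seed=seed)
    rng = np.random.default_rng(seed)
    train = [
        generate_account(
            "organic",
            cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
            account_id=f"train{i:05d}",
        )[0]
        for i in range(n_train)
    ]
    return calibrate(train, percentile=percentile, seed=seed)


def automation_benchmark(
    seed: int = 7,
    cal: BoxCalibration | None = None,
    n_per_class: int = 100,
) -> dict:
    """Account-level recovery of the generator's labels by the full cascade.

    Returns true/false-positive rates (automated = positive class) plus the
    tweet-level label partition of the evaluation corpus.
    """
    if cal is None:
        cal = train_calibration(seed=seed + 4)
    cfg = GeneratorConfig(
        n_organic=n_per_class, n_automated=n_per_class, n_cyborg=0, seed=seed
    )
    tweets, acct_truth, _ = generate_corpus(cfg)
    tweet_labels, acct_labels = classify_corpus(
        tweets, default_keyword_config(), cal
    )
    tp = fn = fp = tn = 0
    for aid, truth in acct_truth.items():
        got = acct_labels[aid].label
        if truth == "automated":
            if got == "automated":
                tp += 1
            elif got == "organic":
                fn += 1
        elif truth == "organic":
            if got == "automated":
                fp += 1
            elif got == "organic":
                tn += 1
    counts = label_counts(tweet_labels)
    return {
        "tp_rate": tp / (tp + fn) if tp + fn else float("nan"),
        "fp_rate": fp / (fp + tn) if fp + tn else float("nan"),
        "n_automated_true": tp + fn,
        "n_organic_true": fp + tn,
        "tweet_label_counts": counts,
        "n_tweets": len(tweets),
    }
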