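"""Two-tier automation classification of tweets and accounts.

Tier one is a keyword rule: tweets stuffed with advertising jargon (three or
more phrase hits) are automated outright, and accounts that post ten or more
such original tweets are flagged wholesale.  Tier two is the human-detection
box: a region in (URL rate, mean dissimilarity, decay rate) space calibrated
per tweet-sample-size bin on trusted organic accounts; an account whose
feature vector falls outside the box on any axis is classified automated.
Accounts with fewer than 25 sampled tweets cannot be featurized: their plain
tweets default to organic, while their URL-bearing tweets are discarded as
unclassifiable (link spam is too likely).

The full cascade (``classify_corpus``) applies, in order: (1) the keyword
tier per tweet; (2) marketing-user flagging; (3) box classification of
accounts with ≥ 25 tweets, whose remaining tweets inherit the account label;
(4) the default/discard rules for small accounts.  Every tweet receives
exactly one label, so automated + organic + discarded partitions the corpus.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import Account, KeywordConfig, Tweet, count_urls, group_accounts
from .features import MIN_SAMPLE, AccountFeatures, compute_features

__all__ = [
    "TweetLabel",
    "AccountLabel",
    "BoxCalibration",
    "count_jargon_hits",
    "keyword_tier",
    "url_commercial",
    "flag_marketing_users",
    "calibrate",
    "classify_account",
    "classify_corpus",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("url_rate", "mean_dissimilarity", "decay_rate")

JARGON_TIER_THRESHOLD = 3
MARKETING_USER_THRESHOLD = 10
URL_KEYWORD_THRESHOLD = 3


@dataclass(frozen=True)
class TweetLabel:
    tweet_id: str
    label: str  # automated | organic | discarded
    source: str  # keyword_tier | marketing_user | box_classifier | default_organic | discard_rule

    def __post_init__(self) -> None:
        if (self.label == "discarded") != (self.source == "discard_rule"):
            raise ValueError("discarded label must come from the discard rule")


@dataclass(frozen=True)
class AccountLabel:
    account_id: str
    label: str  # automated | organic | not_classified


# --- jargon phrase counting -------------------------------------------------


def _phrase_regex(phrase: str) -> re.Pattern:
    # word-boundary match; whitespace in multi-word phrases matches any run
    parts = [re.escape(w) for w in phrase.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)")


def count_jargon_hits(text: str, phrases: Sequence[str]) -> int:
    """Count jargon phrase occurrences with multiplicity, overlaps disallowed.

    Multi-word phrases are matched before their constituent words, so
    "free trial" counts once rather than as "free" + "trial".
    """
    folded = text.casefold()
    taken: list[tuple[int, int]] = []
    hits = 0
    for phrase in sorted(set(phrases), key=lambda p: (-len(p.split()), -len(p))):
        for m in _phrase_regex(phrase).finditer(folded):
            s, e = m.span()
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                hits += 1
    return hits


def keyword_tier(tweet: Tweet, config: KeywordConfig, threshold: int = JARGON_TIER_THRESHOLD) -> bool:
    """True iff the tweet carries ``threshold`` or more advertising-jargon hits."""
    return count_jargon_hits(tweet.text, config.marketing_jargon) >= threshold


def url_commercial(url: str, config: KeywordConfig, threshold: int = URL_KEYWORD_THRESHOLD) -> bool:
    """True iff the case-folded URL mentions ≥ ``threshold`` marketing keywords.

    URLs have no word boundaries, so matching is substring-level with
    multiplicity, longest keyword first, overlaps disallowed.
    """
    if not url:
        raise ValueError("url must be non-empty")
    folded = url.casefold()
    taken: list[tuple[int, int]] = []
    hits = 0
    for kw in sorted(set(config.marketing_jargon), key=len, reverse=True):
        start = 0
        while (i := folded.find(kw, start)) != -1:
            s, e = i, i + len(kw)
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                hits += 1
                start = e
            else:
                start = i + 1
    return hits >= threshold


def flag_marketing_users(
    tweets: Iterable[Tweet],
    keyword_hits: Mapping[str, bool],
    threshold: int = MARKETING_USER_THRESHOLD,
) -> set[str]:
    """Accounts with ≥ ``threshold`` original keyword-tier tweets.

    Retweets of promotional content stay labeled automated but do not count
    toward the flag: organic users retweet promotions for rewards, and that
    alone must not condemn the account.
    """
    counts: dict[str, int] = {}
    for t in tweets:
        if keyword_hits.get(t.tweet_id, False) and not t.is_retweet:
            counts[t.account_id] = counts.get(t.account_id, 0) + 1
    return {aid for aid, c in counts.items() if c >= threshold}


# --- the organic feature box ------------------------------------------------


@dataclass
class BoxCalibration:
    """Per-bin [lower, upper] cutoffs for the three organic features.

    ``cutoffs[bin][feature] = (lo, hi)``.  Bins never seen in training
    inherit the nearest populated bin's cutoffs at lookup time.
    """

    cutoffs: dict[int, dict[str, tuple[float, float]]]
    percentile: float = 99.0
    n_training_accounts: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b, feats in self.cutoffs.items():
            for f, (lo, hi) in feats.items():
                if lo > hi:
                    raise ValueError(f"bin {b}, feature {f}: lower > upper")

    def for_bin(self, b: int) -> dict[str, tuple[float, float]]:
        if b in self.cutoffs:
            return self.cutoffs[b]
        if not self.cutoffs:
            raise ValueError("empty calibration")
        nearest = min(self.cutoffs, key=lambda k: (abs(k - b), k))
        return self.cutoffs[nearest]

    # -- persistence --

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "n_training_accounts": self.n_training_accounts,
            "seed": self.seed,
            "metadata": self.metadata,
            "cutoffs": {
                str(b): {f: [lo, hi] for f, (lo, hi) in feats.items()}
                for b, feats in sorted(self.cutoffs.items())
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "BoxCalibration":
        return cls(
            cutoffs={
                int(b): {f: (float(v[0]), float(v[1])) for f, v in feats.items()}
                for b, feats in doc["cutoffs"].items()
            },
            percentile=float(doc.get("percentile", 99.0)),
            n_training_accounts=int(doc.get("n_training_accounts", 0)),
            seed=doc.get("seed"),
            metadata=dict(doc.get("metadata", {})),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BoxCalibration":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(doc)


def calibrate(
    organic_accounts: Sequence[Account],
    percentile: float = 99.0,
    seed: int | None = None,
    min_bin_accounts: int = 5,
) -> BoxCalibration:
    """Fit per-bin feature cutoffs from trusted organic accounts.

    For each sample-size bin and feature, the cutoffs are the symmetric
    ``[(100-p)/2, 100-(100-p)/2]`` percentiles of the organic training
    distribution; ``p=100`` degenerates to the training min/max, which by
    construction classifies every training account organic.

    A percentile estimated from a handful of accounts is meaningless (a
    single-account bin would collapse to a point box), so bins with fewer
    than ``min_bin_accounts`` training accounts are pooled with the nearest
    populated bin before the percentiles are taken; a warning is logged.
    """
    if not organic_accounts:
        raise ValueError("calibrate needs at least one organic training account")
    by_bin: dict[int, list[AccountFeatures]] = {}
    for acct in organic_accounts:
        f = compute_features(acct)
        by_bin.setdefault(f.bin, []).append(f)
    # pool sparse bins into their nearest (larger-sample preferred) neighbor
    groups: dict[int, list[int]] = {b: [b] for b in by_bin}
    group_n = {b: len(by_bin[b]) for b in by_bin}
    while len(groups) > 1:
        sparse = [b for b in groups if group_n[b] < min_bin_accounts]
        if not sparse:
            break
        b = min(sparse, key=lambda x: (group_n[x], x))
        log.warning("bin %d has only %d training accounts; pooling", b, group_n[b])
        target = min(
            (t for t in groups if t != b),
            key=lambda t: (abs(t - b), -group_n[t]),
        )
        groups[target].extend(groups.pop(b))
        group_n[target] += group_n.pop(b)
    lo_q = (100.0 - percentile) / 2.0
    hi_q = 100.0 - lo_q
    cutoffs: dict[int, dict[str, tuple[float, float]]] = {}
    for lead, members in groups.items():
        feats = [f for b in members for f in by_bin[b]]
        box: dict[str, tuple[float, float]] = {}
        for name in FEATURE_NAMES:
            vals = np.array([getattr(f, name) for f in feats], dtype=float)
            lo, hi = np.percentile(vals, [lo_q, hi_q])
            box[name] = (float(lo), float(hi))
        for b in members:
            cutoffs[b] = dict(box)
    return BoxCalibration(
        cutoffs=cutoffs,
        percentile=percentile,
        n_training_accounts=len(organic_accounts),
        seed=seed,
    )


def classify_account(features: AccountFeatures, cal: BoxCalibration) -> str:
    """Organic iff every feature lies inside its [lower, upper] cutoffs.

    Boundary values count as inside, so min/max calibration (p = 100) keeps
    all training accounts organic.
    """
    box = cal.for_bin(features.bin)
    for name in FEATURE_NAMES:
        lo, hi = box[name]
        v = getattr(features, name)
        if not (lo <= v <= hi):
            return "automated"
    return "organic"


# --- full cascade -----------------------------------------------------------


def classify_corpus(
    tweets: Sequence[Tweet],
    config: KeywordConfig,
    cal: BoxCalibration,
    accounts: Mapping[str, Account] | None = None,
    jargon_threshold: int = JARGON_TIER_THRESHOLD,
    marketing_user_threshold: int = MARKETING_USER_THRESHOLD,
) -> tuple[dict[str, TweetLabel], dict[str, AccountLabel]]:
    """Label every tweet and account in the corpus.

    Returns ``(tweet_labels, account_labels)`` keyed by id.  The label set
    {automated, organic, discarded} partitions the tweets exactly.
    """
    if accounts is None:
        accounts = group_accounts(tweets)
    else:
        missing = {t.account_id for t in tweets} - set(accounts)
        if missing:
            raise ValueError(f"tweets reference unknown accounts: {sorted(missing)[:5]}")

    # (1) keyword tier
    kw_hit = {t.tweet_id: keyword_tier(t, config, jargon_threshold) for t in tweets}
    # (2) marketing-user flag (original tweets only)
    flagged = flag_marketing_users(tweets, kw_hit, marketing_user_threshold)
    # (3) box classification for accounts with enough sampled tweets
    box_label: dict[str, str] = {}
    for aid, acct in accounts.items():
        if aid not in flagged and len(acct) >= MIN_SAMPLE:
            box_label[aid] = classify_account(compute_features(acct), cal)

    tweet_labels: dict[str, TweetLabel] = {}
    for t in tweets:
        if kw_hit[t.tweet_id]:
            lab = TweetLabel(t.tweet_id, "automated", "keyword_tier")
        elif t.account_id in flagged:
            lab = TweetLabel(t.tweet_id, "automated", "marketing_user")
        elif t.account_id in box_label:
            lab = TweetLabel(t.tweet_id, box_label[t.account_id], "box_classifier")
        elif count_urls(t.text) > 0:
            lab = TweetLabel(t.tweet_id, "discarded", "discard_rule")
        else:
            lab = TweetLabel(t.tweet_id, "organic", "default_organic")
        tweet_labels[t.tweet_id] = lab

    account_labels: dict[str, AccountLabel] = {}
    for aid, acct in accounts.items():
        if aid in flagged:
            account_labels[aid] = AccountLabel(aid, "automated")
        elif aid in box_label:
            account_labels[aid] = AccountLabel(aid, box_label[aid])
        else:
            account_labels[aid] = AccountLabel(aid, "not_classified")
    return tweet_labels, account_labels


def label_counts(tweet_labels: Mapping[str, TweetLabel]) -> dict[str, int]:
    counts = {"automated": 0, "organic": 0, "discarded": 0}
    for lab in tweet_labels.values():
        counts[lab.label] += 1
    return counts
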