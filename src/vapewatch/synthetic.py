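"""Seeded generators for labeled tweet corpora and happiness lexicons.

The generators emulate the statistical structure of an e-cigarette tweet
stream, not its surface realism: what matters is that each account class
occupies the feature region the detection pipeline keys on.

* **organic** — open vocabulary (Zipf-sampled pseudo-words), few links,
  high inter-tweet dissimilarity, occasional promotional retweets, and
  per-month injectable positive/negative sentiment words so time-series
  structure is recoverable.
* **automated** — one fixed word template per account with rare word swaps
  (closed vocabulary, near-duplicate text), a campaign URL attached to 92%
  of tweets (matching the published automated-URL share), trailing topic
  keywords, and occasional jargon bursts that trip the keyword tier.
* **cyborg** — testimonial slot templates instantiated with random handles,
  a fixed brand and varying week counts, one URL per tweet.

Follower counts are Pareto (heavy-tailed), so impressions sums are dominated
by a few large accounts.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Account, KeywordConfig, Tweet, default_keyword_config, write_corpus
from .hedonometrics import HappinessLexicon
from .topics import CyborgTemplate, default_cyborg_templates

__all__ = [
    "GeneratorConfig",
    "generate_account",
    "generate_corpus",
    "generate_lexicon",
    "write_corpus_files",
    "POSITIVE_TOKENS",
    "NEGATIVE_TOKENS",
]

CLASSES = ("organic", "automated", "cyborg")

# Sentiment words the organic generator can inject; the synthetic lexicon
# scores them well outside the neutral window.
POSITIVE_TOKENS = ("love", "haha", "good", "cool", "happy", "fun")
NEGATIVE_TOKENS = ("ban", "tobacco", "poison", "tax", "bad", "hate")

# Generic promo-speak for automated templates; deliberately disjoint from the
# advertising-jargon keyword list so the box classifier, not the keyword
# tier, does the work on plain template tweets.
_PROMO_VOCAB = (
    "check out our new shop juice vapor best quality brand flavors today "
    "online store top rated smooth rich clouds big huge epic great awesome "
    "amazing fresh pure classic original signature ultimate choice range "
    "collection kit batteries charger tank coil mod pen device liquid "
    "nicotine zero blend series limited edition exclusive special featured "
    "popular trending hot arrivals stock order ship fast"
).split()

_SYLLABLES = [c + v for c in "bdklmnprstvz" for v in "aeiou"]  # 60


def _pseudo_word(i: int) -> str:
    """Deterministic pronounceable word for vocabulary index *i* (base-60)."""
    return _SYLLABLES[(i // 3600) % 60] + _SYLLABLES[(i // 60) % 60] + _SYLLABLES[i % 60]


_TZ_OFFSETS = (-480, -420, -360, -300, -240, 0, 60, 120, 330, 540)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults put the classes in well-separated feature regions: automated
    accounts near URL rate 0.9, mean dissimilarity ≤ 0.3 and decay ≤ 0.3;
    organic accounts near URL rate ≤ 0.2, dissimilarity ≥ 0.7, decay ≥ 0.8.
    """

    n_organic: int = 100
    n_automated: int = 80
    n_cyborg: int = 20
    seed: int = 0

    # tweets per account: lognormal, clipped so accounts are classifiable
    tweets_log_mean: float = math.log(60.0)
    tweets_log_sigma: float = 0.45
    min_tweets: int = 25
    max_tweets: int = 300

    # organic class
    vocab_size: int = 30_000
    zipf_exponent: float = 1.05
    organic_url_prob: float = 0.10
    organic_retweet_rate: float = 0.05
    tweet_len_mean: float = 6.0  # Poisson mean on top of 3 mandatory tokens
    sentiment_injection_rate: float = 0.5
    default_negative_rate: float = 0.3
    # month ("YYYY-MM") → probability an injected sentiment token is negative
    monthly_negative_rate: Mapping[str, float] | None = None

    # automated class
    automated_url_prob: float = 0.92  # matches the published automated-URL share
    template_len: int = 10
    word_swap_rate: float = 0.03
    account_vocab_size: int = 20
    topic_injection_rate: float = 0.15
    jargon_injection_rate: float = 0.08
    jargon_burst_rate: float = 0.04  # three-phrase bursts that trip the keyword tier

    # followers: follower = scale * (1 + Pareto(alpha))
    follower_pareto_alpha: float = 1.16
    follower_scale: float = 50.0

    date_start: datetime = datetime(2013, 1, 1)
    date_end: datetime = datetime(2014, 12, 31)

    def __post_init__(self) -> None:
        for name in (
            "organic_url_prob", "automated_url_prob", "word_swap_rate",
            "topic_injection_rate", "jargon_injection_rate", "jargon_burst_rate",
            "organic_retweet_rate", "sentiment_injection_rate",
            "default_negative_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.min_tweets < 1 or self.max_tweets < self.min_tweets:
            raise ValueError("invalid tweets-per-account bounds")
        if self.date_end <= self.date_start:
            raise ValueError("empty date range")


# --- shared helpers ---------------------------------------------------------


def _n_tweets(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    n = int(round(rng.lognormal(cfg.tweets_log_mean, cfg.tweets_log_sigma)))
    return int(np.clip(n, cfg.min_tweets, cfg.max_tweets))


def _timestamps(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> list[datetime]:
    span = (cfg.date_end - cfg.date_start).total_seconds()
    secs = np.sort(rng.uniform(0.0, span, size=n))
    return [cfg.date_start + timedelta(seconds=float(s)) for s in secs]


def _followers(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    return int(cfg.follower_scale * (1.0 + rng.pareto(cfg.follower_pareto_alpha)))


def _tz_offset(rng: np.random.Generator) -> int | None:
    if rng.random() < 0.1:
        return None
    return int(_TZ_OFFSETS[rng.integers(len(_TZ_OFFSETS))])


def _slug(rng: np.random.Generator, n: int = 7) -> str:
    chars = "abcdefghijklmnopqrstuvwxyz0123456789"
    return "".join(chars[rng.integers(len(chars))] for _ in range(n))


def _zipf_probs(cfg: GeneratorConfig) -> np.ndarray:
    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    p = ranks ** (-cfg.zipf_exponent)
    return p / p.sum()


# --- per-class text ---------------------------------------------------------


def _organic_texts(
    cfg: GeneratorConfig, rng: np.random.Generator, times: Sequence[datetime]
) -> list[str]:
    probs = _zipf_probs(cfg)
    texts = []
    for when in times:
        n_tok = 3 + int(rng.poisson(cfg.tweet_len_mean))
        idx = rng.choice(cfg.vocab_size, size=n_tok, p=probs)
        toks = [_pseudo_word(int(i)) for i in idx]
        if rng.random() < cfg.sentiment_injection_rate:
            key = f"{when.year:04d}-{when.month:02d}"
            neg_rate = (cfg.monthly_negative_rate or {}).get(key, cfg.default_negative_rate)
            pool = NEGATIVE_TOKENS if rng.random() < neg_rate else POSITIVE_TOKENS
            toks.append(pool[rng.integers(len(pool))])
        text = " ".join(toks)
        if rng.random() < cfg.organic_url_prob:
            text += f" http://t.co/{_slug(rng)}"
        if rng.random() < cfg.organic_retweet_rate:
            text = f"RT @{_slug(rng, 5)}: {text}"
        texts.append(text)
    return texts


def _automated_texts(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n: int,
    keywords: KeywordConfig,
) -> list[str]:
    vocab = [
        _PROMO_VOCAB[int(i)]
        for i in rng.choice(len(_PROMO_VOCAB), size=cfg.account_vocab_size, replace=False)
    ]
    template = [vocab[int(i)] for i in rng.integers(len(vocab), size=cfg.template_len)]
    url = f"http://bit.ly/{_slug(rng)}"
    # the campaign pushes a couple of fixed topics and slogans
    topic_names = list(keywords.topic_keywords)
    picks = rng.choice(len(topic_names), size=2, replace=False)
    phrase_pool: list[str] = []
    for p in picks:
        tk = keywords.topic_keywords[topic_names[int(p)]]
        phrase_pool.extend(tk[int(i)] for i in rng.integers(len(tk), size=2))
    jargon_pool = [
        keywords.marketing_jargon[int(i)]
        for i in rng.choice(len(keywords.marketing_jargon), size=5, replace=False)
    ]
    texts = []
    for _ in range(n):
        toks = list(template)
        for j in range(len(toks)):
            if rng.random() < cfg.word_swap_rate:
                toks[j] = vocab[rng.integers(len(vocab))]
        text = " ".join(toks)
        if rng.random() < cfg.automated_url_prob:
            text += " " + url
        if rng.random() < cfg.topic_injection_rate:
            text += " " + phrase_pool[rng.integers(len(phrase_pool))]
        if rng.random() < cfg.jargon_injection_rate:
            text += " " + jargon_pool[rng.integers(len(jargon_pool))]
        if rng.random() < cfg.jargon_burst_rate:
            burst = rng.choice(len(jargon_pool), size=3, replace=False)
            text += " " + " ".join(jargon_pool[int(b)] for b in burst)
        texts.append(text)
    return texts


_BRANDS = ("VaporMax", "CloudNine", "Vapo", "PuffPro", "EverMist", "NicoAir")


def _instantiate_template(
    tpl: CyborgTemplate, rng: np.random.Generator, brand: str
) -> str:
    import re as _re

    def fill(m: _re.Match) -> str:
        tok = m.group(0)
        if tok == "@USER":
            return "@" + _slug(rng, 6)
        if tok == "BRAND":
            return brand
        if tok == "URL":
            return f"http://ow.ly/{_slug(rng, 5)}"
        inner = tok[1:-1]
        if tok.startswith("{"):
            if inner.strip() == "#":
                return str(int(rng.integers(2, 13)))
            opts = inner.split(",")
            return opts[int(rng.integers(len(opts)))].strip()
        return inner if rng.random() < 0.5 else ""  # optional (...) fragment

    text = _re.sub(r"@USER|BRAND|URL|\{[^{}]*\}|\([^()]*\)", fill, tpl.pattern)
    return " ".join(text.split())


def _cyborg_texts(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n: int,
    templates: Sequence[CyborgTemplate],
) -> list[str]:
    brand = _BRANDS[int(rng.integers(len(_BRANDS)))]
    k = min(2, len(templates))
    mine = [templates[int(i)] for i in rng.choice(len(templates), size=k, replace=False)]
    return [
        _instantiate_template(mine[int(rng.integers(len(mine)))], rng, brand)
        for _ in range(n)
    ]


# --- public API -------------------------------------------------------------


def generate_account(
    kind: str,
    config: GeneratorConfig,
    seed: int,
    account_id: str | None = None,
    tweet_id_start: int = 0,
    keywords: KeywordConfig | None = None,
    templates: Sequence[CyborgTemplate] | None = None,
) -> tuple[Account, str]:
    """One synthetic account of the given class, with its ground-truth label."""
    if kind not in CLASSES:
        raise ValueError(f"unknown class: {kind}")
    rng = np.random.default_rng(seed)
    if account_id is None:
        account_id = f"{kind[:3]}{seed:08d}"
    n = _n_tweets(config, rng)
    times = _timestamps(config, rng, n)
    if kind == "organic":
        texts = _organic_texts(config, rng, times)
    elif kind == "automated":
        texts = _automated_texts(config, rng, n, keywords or default_keyword_config())
    else:
        texts = _cyborg_texts(config, rng, n, templates or default_cyborg_templates())
    followers = _followers(config, rng)
    tz = _tz_offset(rng)
    tweets = [
        Tweet(
            tweet_id=f"t{tweet_id_start + i:08d}",
            account_id=account_id,
            utc_time=when,
            tz_offset_minutes=tz,
            text=text,
            follower_count=followers,
            language="en",
            is_retweet=text.startswith("RT @"),
        )
        for i, (when, text) in enumerate(zip(times, texts))
    ]
    return Account(account_id, tweets), kind


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[Tweet], dict[str, str], dict[str, str]]:
    """A shuffled multi-class corpus with per-account and per-tweet truth.

    Returns ``(tweets, account_truth, tweet_truth)``; deterministic down to
    the byte for a fixed config (the config carries the seed).
    """
    rng = np.random.default_rng(config.seed)
    keywords = default_keyword_config()
    templates = default_cyborg_templates()
    plan = (
        [("organic", i) for i in range(config.n_organic)]
        + [("automated", i) for i in range(config.n_automated)]
        + [("cyborg", i) for i in range(config.n_cyborg)]
    )
    tweets: list[Tweet] = []
    account_truth: dict[str, str] = {}
    tweet_truth: dict[str, str] = {}
    next_id = 0
    for kind, i in plan:
        child_seed = int(rng.integers(0, 2**31 - 1))
        acct, label = generate_account(
            kind,
            config,
            seed=child_seed,
            account_id=f"{kind[:3]}{i:05d}",
            tweet_id_start=next_id,
            keywords=keywords,
            templates=templates,
        )
        next_id += len(acct)
        account_truth[acct.account_id] = label
        for t in acct.tweets:
            tweet_truth[t.tweet_id] = label
        tweets.extend(acct.tweets)
    order = rng.permutation(len(tweets))
    return [tweets[int(i)] for i in order], account_truth, tweet_truth


def generate_lexicon(
    n_words: int,
    score_distribution: str = "uniform",
    seed: int = 0,
    stop_fraction: float | None = None,
    words: Sequence[str] | None = None,
    include_sentiment_words: bool = True,
) -> HappinessLexicon:
    """Synthetic labMT-style lexicon over the generator's vocabulary.

    ``score_distribution``: "uniform" on [1, 9] or "normal" (mean 5, sd 1.5,
    truncated).  ``stop_fraction`` forces that share of words into the
    neutral [4, 6] window (the rest outside it).  The organic generator's
    sentiment tokens get fixed, strongly valenced scores so injected
    time-series structure is recoverable.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    rng = np.random.default_rng(seed)
    if words is None:
        words = [_pseudo_word(i) for i in range(n_words)]
    elif len(words) < n_words:
        raise ValueError("fewer candidate words than n_words")
    scores: dict[str, float] = {}
    for w in list(words)[:n_words]:
        if stop_fraction is not None:
            if rng.random() < stop_fraction:
                h = rng.uniform(4.0, 6.0)
            else:
                h = rng.uniform(1.0, 4.0) if rng.random() < 0.5 else rng.uniform(6.0, 9.0)
        elif score_distribution == "uniform":
            h = rng.uniform(1.0, 9.0)
        elif score_distribution == "normal":
            h = float(np.clip(rng.normal(5.0, 1.5), 1.0, 9.0))
        else:
            raise ValueError(f"unknown score distribution: {score_distribution}")
        scores[w] = float(h)
    if include_sentiment_words:
        for i, w in enumerate(POSITIVE_TOKENS):
            scores[w] = 7.4 + 0.1 * i
        for i, w in enumerate(NEGATIVE_TOKENS):
            scores[w] = 2.6 - 0.1 * i
    return HappinessLexicon(scores=scores)


def write_corpus_files(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a corpus and write tweets (jsonl) plus a truth-label table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tweets, account_truth, tweet_truth = generate_corpus(config)
    corpus_path = outdir / "corpus.jsonl"
    write_corpus(tweets, corpus_path, dialect="jsonl")
    truth_path = outdir / "truth.csv"
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("kind,id,label\n")
        for aid in sorted(account_truth):
            fh.write(f"account,{aid},{account_truth[aid]}\n")
        for tid in sorted(tweet_truth):
            fh.write(f"tweet,{tid},{tweet_truth[tid]}\n")
    return {"corpus": corpus_path, "truth": truth_path}
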