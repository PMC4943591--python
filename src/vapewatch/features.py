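"""Per-account linguistic features for automation detection.

Three features characterize how "organic" an account's tweet stream looks:

* **URL rate** — mean number of hyperlinks per tweet; promotional robots
  almost always attach a link.
* **Mean pairwise dissimilarity** — for tweets ``t_i, t_j`` of combined
  length ``|t_i| + |t_j|`` sharing a longest common contiguous character run
  of length ``L``::

      D(t_i, t_j) = (|t_i| + |t_j| - 2 L) / (|t_i| + |t_j|)

  averaged over all unordered pairs.  Near-duplicate template output scores
  close to 0; diverse human text close to 1.
* **Word-introduction decay rate** — the Heaps-law exponent γ of vocabulary
  growth: with ``u(n)`` the number of distinct words among the first *n*
  tokens of the concatenated stream, γ is the least-squares slope of
  ``log u(n)`` against ``log n`` for ``n ≥ 10``.  γ ≈ 1 means continually new
  vocabulary (organic); γ ≈ 0 a closed template vocabulary (automated).

Features are computed on the first ``bin`` tweets of the ordinal stream,
where ``bin`` rounds the sample size down to a multiple of 25, capped at 500.
Accounts under 25 tweets cannot be featurized and are routed to default
rules by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .corpus_io import Account, Tweet, count_urls, tokenize, _URL_RE

__all__ = [
    "AccountFeatures",
    "lcs_length",
    "dissimilarity_from_lengths",
    "pairwise_dissimilarity",
    "mean_dissimilarity",
    "url_rate",
    "decay_rate",
    "compute_features",
]

MIN_SAMPLE = 25
MAX_SAMPLE = 500
DECAY_FIT_START = 10  # first token index of the log-log fit range


@dataclass(frozen=True)
class AccountFeatures:
    account_id: str
    url_rate: float
    mean_dissimilarity: float
    decay_rate: float
    n_tweets: int
    bin: int


@njit(cache=False)
def _lcs_substring_kernel(a: np.ndarray, b: np.ndarray) -> int:  # pragma: no cover
    best = 0
    prev = np.zeros(b.size + 1, dtype=np.int64)
    cur = np.zeros(b.size + 1, dtype=np.int64)
    for i in range(a.size):
        for j in range(b.size):
            if a[i] == b[j]:
                cur[j + 1] = prev[j] + 1
                if cur[j + 1] > best:
                    best = cur[j + 1]
            else:
                cur[j + 1] = 0
        prev, cur = cur, prev
    return best


@njit(cache=False)
def _lcs_subsequence_kernel(a: np.ndarray, b: np.ndarray) -> int:  # pragma: no cover
    prev = np.zeros(b.size + 1, dtype=np.int64)
    cur = np.zeros(b.size + 1, dtype=np.int64)
    for i in range(a.size):
        for j in range(b.size):
            if a[i] == b[j]:
                cur[j + 1] = prev[j] + 1
            else:
                cur[j + 1] = max(cur[j], prev[j + 1])
        prev, cur = cur, prev
    return prev[b.size]


def _encode(s: str) -> np.ndarray:
    return np.array([ord(c) for c in s], dtype=np.int32)


def lcs_length(a: str, b: str, mode: str = "substring") -> int:
    """Length in characters (whitespace included) of the longest common run.

    ``mode="substring"`` (default) requires the run to be contiguous in both
    strings; ``mode="subsequence"`` relaxes contiguity (classic LCS), kept for
    sensitivity analysis.
    """
    if not a or not b:
        return 0
    if mode == "substring":
        return int(_lcs_substring_kernel(_encode(a), _encode(b)))
    if mode == "subsequence":
        return int(_lcs_subsequence_kernel(_encode(a), _encode(b)))
    raise ValueError(f"unknown mode: {mode}")


def dissimilarity_from_lengths(len_a: int, len_b: int, lcs: int) -> float:
    """D = (|a| + |b| - 2·LCS) / (|a| + |b|) from pre-computed lengths."""
    total = len_a + len_b
    if total <= 0:
        raise ValueError("undefined dissimilarity: both strings empty")
    return (total - 2 * lcs) / total


def pairwise_dissimilarity(a: str, b: str, mode: str = "substring") -> float:
    """Normalized character-level dissimilarity of two tweets, in [0, 1]."""
    return dissimilarity_from_lengths(len(a), len(b), lcs_length(a, b, mode=mode))


@njit(cache=False)
def _mean_dissim_kernel(flat: np.ndarray, offsets: np.ndarray) -> float:  # pragma: no cover
    n = offsets.size - 1
    max_len = 0
    for i in range(n):
        L = offsets[i + 1] - offsets[i]
        if L > max_len:
            max_len = L
    prev = np.zeros(max_len + 1, dtype=np.int64)
    cur = np.zeros(max_len + 1, dtype=np.int64)
    total = 0.0
    for i in range(n):
        ai, aj = offsets[i], offsets[i + 1]
        la = aj - ai
        for k in range(i + 1, n):
            bi, bj = offsets[k], offsets[k + 1]
            lb = bj - bi
            for j in range(lb + 1):
                prev[j] = 0
                cur[j] = 0
            best = 0
            for p in range(la):
                c = flat[ai + p]
                for q in range(lb):
                    if c == flat[bi + q]:
                        cur[q + 1] = prev[q] + 1
                        if cur[q + 1] > best:
                            best = cur[q + 1]
                    else:
                        cur[q + 1] = 0
                tmp = prev
                prev = cur
                cur = tmp
            total += (la + lb - 2.0 * best) / (la + lb)
    return total / (n * (n - 1) / 2.0)


def mean_dissimilarity(texts: Sequence[str]) -> float:
    """Mean pairwise dissimilarity over all unordered pairs of tweets.

    Exact (no sampling); O(n²·len²) in the sample size and tweet length,
    which stays tractable because samples are capped at 500 tweets of at
    most 280 characters.
    """
    if len(texts) < 2:
        raise ValueError("mean_dissimilarity needs at least 2 tweets")
    for t in texts:
        if len(t) == 0:
            raise ValueError("undefined dissimilarity: empty tweet text")
    offsets = np.zeros(len(texts) + 1, dtype=np.int64)
    for i, t in enumerate(texts):
        offsets[i + 1] = offsets[i] + len(t)
    flat = np.empty(int(offsets[-1]), dtype=np.int32)
    for i, t in enumerate(texts):
        flat[offsets[i]: offsets[i + 1]] = _encode(t) if t else ()
    return float(_mean_dissim_kernel(flat, offsets))


def url_rate(tweets: Sequence[Tweet]) -> float:
    """Arithmetic mean URL count per tweet."""
    if not tweets:
        raise ValueError("url_rate needs at least 1 tweet")
    return float(np.mean([count_urls(t.text) for t in tweets]))


def _vocab_growth(tokens: Sequence[str]) -> np.ndarray:
    """u(n): number of distinct words among the first n tokens, n = 1..N."""
    seen: set[str] = set()
    u = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        seen.add(tok)
        u[i] = len(seen)
    return u


def decay_rate(texts: Sequence[str], fit_start: int = DECAY_FIT_START) -> float:
    """Heaps-law exponent of vocabulary growth over the concatenated stream.

    Tweets are tokenized in ordinal order; the slope of ``log u(n)`` versus
    ``log n`` is fit by least squares over ``n = fit_start .. N``.
    """
    tokens: list[str] = []
    for t in texts:
        tokens.extend(tokenize(t))
    if len(tokens) < fit_start:
        raise ValueError(f"decay_rate needs at least {fit_start} tokens")
    u = _vocab_growth(tokens)
    n = np.arange(1, len(tokens) + 1)
    x = np.log(n[fit_start - 1:])
    y = np.log(u[fit_start - 1:])
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        raise ValueError("decay_rate fit range is degenerate")
    return float(np.dot(xc, y - y.mean()) / denom)


def sample_bin(n_tweets: int) -> int:
    """Ordinal sample size: multiples of 25 from 25 up to 500."""
    if n_tweets < MIN_SAMPLE:
        raise ValueError("insufficient sample")
    return min(MAX_SAMPLE, MIN_SAMPLE * (n_tweets // MIN_SAMPLE))


def compute_features(
    account: Account,
    lowercase: bool = False,
    strip_urls: bool = False,
) -> AccountFeatures:
    """Featurize an account on the first ``bin`` tweets of its ordinal stream.

    ``lowercase`` / ``strip_urls`` control optional text normalization before
    the character-level dissimilarity (both off by default so lengths are
    byte-faithful); the URL rate always sees the raw text.
    """
    n = len(account)
    b = sample_bin(n)  # raises "insufficient sample" under 25 tweets
    sample = account.tweets[:b]
    texts = [t.text for t in sample]
    if lowercase:
        texts = [t.casefold() for t in texts]
    if strip_urls:
        texts = [_URL_RE.sub("", t).strip() or " " for t in texts]
    return AccountFeatures(
        account_id=account.account_id,
        url_rate=url_rate(sample),
        mean_dissimilarity=mean_dissimilarity(texts),
        decay_rate=decay_rate(texts),
        n_tweets=n,
        bin=b,
    )
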