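"""Lexicon-based corpus happiness, word-shift decomposition, time series.

A crowd-scored happiness lexicon assigns each word ``w`` a score ``h_w`` on a
1–9 scale (1 extremely negative, 9 extremely positive).  The happiness of a
corpus with word frequencies ``f_w`` is the frequency-weighted mean

    h̄ = Σ f_w · h_w / Σ f_w

over words found in the lexicon whose score lies OUTSIDE the neutral
stop-word window (4 ≤ h ≤ 6, inclusive); dropping tepid words sharpens the
emotional signal.

A word-shift decomposes the happiness difference between a comparison and a
reference corpus into per-word contributions.  With normalized scored-word
frequencies ``p_w`` per corpus,

    δ_w = (h_w − h̄_ref) · (p_w^comp − p_w^ref)

which sums exactly to ``h̄_comp − h̄_ref``.  Words are ranked by |δ_w|; an
arrow marks whether the word got more (↑) or less (↓) frequent and a sign
whether it sits above (+) or below (−) the reference mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus_io import Tweet, tokenize

__all__ = [
    "HappinessLexicon",
    "CorpusSentiment",
    "WordShiftEntry",
    "WordShift",
    "load_labmt_lexicon",
    "count_words",
    "corpus_happiness",
    "word_shift",
    "monthly_series",
]

STOP_WINDOW = (4.0, 6.0)


@dataclass(frozen=True)
class HappinessLexicon:
    """word → happiness score map with a neutral exclusion window."""

    scores: Mapping[str, float]
    stop_window: tuple[float, float] = STOP_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.stop_window
        if lo > hi:
            raise ValueError("stop window lower bound exceeds upper bound")
        for w, h in self.scores.items():
            if not (1.0 <= h <= 9.0):
                raise ValueError(f"score for {w!r} outside [1, 9]: {h}")

    def is_scored(self, word: str) -> bool:
        """In the lexicon and outside the neutral stop-word window."""
        h = self.scores.get(word)
        if h is None:
            return False
        lo, hi = self.stop_window
        return not (lo <= h <= hi)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("word\thappiness\n")
            for w, h in sorted(self.scores.items()):
                fh.write(f"{w}\t{h}\n")


def load_labmt_lexicon(
    path: str | Path, stop_window: tuple[float, float] = STOP_WINDOW
) -> HappinessLexicon:
    """Read a labMT-style tab-delimited lexicon.

    Accepts both the bare two-column (word, score) layout and the published
    multi-column layout whose first two data columns are the word and its
    mean happiness; a header row is detected and skipped.
    """
    scores: dict[str, float] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"line {lineno}: expected ≥2 tab-separated columns")
            try:
                score = float(cols[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"line {lineno}: non-numeric score {cols[1]!r}")
            scores[cols[0].casefold()] = score
    return HappinessLexicon(scores=scores, stop_window=stop_window)


@dataclass(frozen=True)
class CorpusSentiment:
    freqs: Mapping[str, int]  # scored words only
    h_avg: float
    n_scored_tokens: int

    def p(self, word: str) -> float:
        return self.freqs.get(word, 0) / self.n_scored_tokens


def count_words(texts: Iterable[str]) -> Counter:
    c: Counter = Counter()
    for t in texts:
        c.update(tokenize(t))
    return c


def corpus_happiness(
    freqs: Mapping[str, int],
    lexicon: HappinessLexicon,
    exclude: Sequence[str] = (),
) -> CorpusSentiment:
    """Frequency-weighted mean happiness of scored words.

    Out-of-lexicon and stop-window words are ignored; ``exclude`` removes
    further words (e.g. campaign-dominating 'free'/'trial') before scoring.
    """
    excluded = {w.casefold() for w in exclude}
    scored = {
        w: int(f)
        for w, f in freqs.items()
        if f > 0 and w not in excluded and lexicon.is_scored(w)
    }
    n = sum(scored.values())
    if n == 0:
        raise ValueError("no scorable words")
    h = sum(f * lexicon.scores[w] for w, f in scored.items()) / n
    return CorpusSentiment(freqs=scored, h_avg=h, n_scored_tokens=n)


@dataclass(frozen=True)
class WordShiftEntry:
    word: str
    delta: float
    freq_direction: str  # "↑" (more frequent in comparison) or "↓"
    sign: str  # "+" (h_w above reference mean) or "−"


@dataclass(frozen=True)
class WordShift:
    reference: CorpusSentiment
    comparison: CorpusSentiment
    entries: tuple[WordShiftEntry, ...]  # top k by |delta|
    total_shift: float  # h̄_comp − h̄_ref
    delta_sum: float  # Σ δ_w over ALL words (= total_shift, identity)

    def to_records(self) -> list[dict]:
        return [
            {
                "word": e.word,
                "delta": e.delta,
                "freq_direction": e.freq_direction,
                "sign": e.sign,
            }
            for e in self.entries
        ]

    def render(self, width: int = 40) -> str:
        """Plain-text bar chart of the ranked word contributions."""
        if not self.entries:
            return "(no shift)\n"
        peak = max(abs(e.delta) for e in self.entries) or 1.0
        lines = [
            f"happiness shift: {self.reference.h_avg:.4f} → "
            f"{self.comparison.h_avg:.4f} (Δ = {self.total_shift:+.4f})"
        ]
        for rank, e in enumerate(self.entries, start=1):
            bar = "█" * max(1, round(abs(e.delta) / peak * width))
            lines.append(
                f"{rank:3d}. {e.word:>16s} {e.sign}{e.freq_direction} "
                f"{e.delta:+.5f} {bar}"
            )
        return "\n".join(lines) + "\n"


def word_shift(
    ref_freqs: Mapping[str, int],
    comp_freqs: Mapping[str, int],
    lexicon: HappinessLexicon,
    k: int = 50,
    exclude: Sequence[str] = (),
) -> WordShift:
    """Decompose the happiness difference between two corpora word by word."""
    ref = corpus_happiness(ref_freqs, lexicon, exclude=exclude)
    comp = corpus_happiness(comp_freqs, lexicon, exclude=exclude)
    deltas: dict[str, float] = {}
    for w in set(ref.freqs) | set(comp.freqs):
        deltas[w] = (lexicon.scores[w] - ref.h_avg) * (comp.p(w) - ref.p(w))
    ranked = sorted(deltas.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    entries = tuple(
        WordShiftEntry(
            word=w,
            delta=d,
            freq_direction="↑" if comp.p(w) > ref.p(w) else "↓",
            sign="+" if lexicon.scores[w] > ref.h_avg else "−",
        )
        for w, d in ranked[:k]
    )
    return WordShift(
        reference=ref,
        comparison=comp,
        entries=entries,
        total_shift=comp.h_avg - ref.h_avg,
        delta_sum=sum(deltas.values()),
    )


def monthly_series(
    tweets: Sequence[Tweet], lexicon: HappinessLexicon
) -> pd.DataFrame:
    """Average happiness per local calendar month.

    Months in which no word scores are absent from the result (missing, not
    zero).  Columns: month (pandas Period), h_avg, n_tweets, n_scored_tokens.
    """
    buckets: dict[pd.Period, list[Tweet]] = {}
    for t in tweets:
        month = pd.Period(t.local_time, freq="M")
        buckets.setdefault(month, []).append(t)
    rows = []
    for month in sorted(buckets):
        group = buckets[month]
        freqs = count_words(t.text for t in group)
        try:
            cs = corpus_happiness(freqs, lexicon)
        except ValueError:
            continue  # nothing scorable this month
        rows.append(
            {
                "month": month,
                "h_avg": cs.h_avg,
                "n_tweets": len(group),
                "n_scored_tokens": cs.n_scored_tokens,
            }
        )
    return pd.DataFrame(rows, columns=["month", "h_avg", "n_tweets", "n_scored_tokens"])
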