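"""Sub-categorization of automated tweets, social reach, cyborg detection.

Automated (promotional) tweets are tallied into four overlapping topics —
commercial, cessation, discount, flavor — by case-insensitive phrase
matching; a tweet whose embedded URL alone mentions three or more marketing
keywords also counts as commercial.  Social reach ("impressions") is the sum
of follower counts over a tweet set: an upper bound on the number of
timelines the messages could have crossed, counted per tweet so a prolific
account contributes once per post.

Cyborg testimonials — human-assisted bots impersonating satisfied quitters —
follow rigid slot templates ("@USER {I,We} {tried,pursued} to {give up,quit}
smoking. Discovered BRAND electronic cigarettes and quit in {#} weeks. ...").
Templates are configuration data; the matcher compiles each into a
punctuation-tolerant regular expression with wildcard slots for the handle,
brand name, week count and URL.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .classifier import url_commercial, _phrase_regex
from .corpus_io import KeywordConfig, Tweet, find_urls, _URL_RE

__all__ = [
    "TopicLabel",
    "CyborgTemplate",
    "classify_topics",
    "impressions",
    "cyborg_match",
    "load_cyborg_templates",
    "default_cyborg_templates",
    "topic_year_summary",
]

TOPICS = ("commercial", "cessation", "discount", "flavor")


@dataclass(frozen=True)
class TopicLabel:
    tweet_id: str
    topics: frozenset[str]
    matched_keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if bool(self.topics) != bool(self.matched_keywords):
            raise ValueError("matched_keywords must be non-empty iff topics are")


def classify_topics(tweet: Tweet, config: KeywordConfig) -> TopicLabel:
    """Assign every topic with at least one phrase hit (topics may overlap).

    A single phrase suffices — the ≥3 rule belongs to the automation keyword
    tier and to URL scanning, not to topic tallies.  For the commercial topic
    only, a URL carrying ≥3 marketing keywords also fires.
    """
    folded = tweet.text.casefold()
    topics: set[str] = set()
    matched: list[str] = []
    for topic in TOPICS:
        for phrase in config.topic_keywords[topic]:
            if _phrase_regex(phrase).search(folded):
                topics.add(topic)
                if phrase not in matched:
                    matched.append(phrase)
    if "commercial" not in topics:
        for url in find_urls(tweet.text):
            if url_commercial(url, config):
                topics.add("commercial")
                matched.append(url)
                break
    return TopicLabel(tweet.tweet_id, frozenset(topics), tuple(matched))


def impressions(tweets: Iterable[Tweet]) -> int:
    """Summed follower counts — potential timeline appearances, per tweet."""
    return int(sum(t.follower_count for t in tweets))


# --- cyborg slot templates --------------------------------------------------

_URL_SENTINEL = "urlplaceholdertoken"
_KEEP_RE = re.compile(r"[^a-z0-9@_]")


def _norm(text: str) -> str:
    """Casefold, collapse punctuation to spaces, URLs to a sentinel token."""
    text = _URL_RE.sub(f" {_URL_SENTINEL} ", text)
    text = text.casefold()
    text = _KEEP_RE.sub(" ", text)
    return " ".join(text.split())


def _literal_rx(fragment: str) -> str:
    toks = _norm(fragment).split()
    return r"\s+".join(re.escape(t) for t in toks)


_SLOT_RE = re.compile(r"@USER|BRAND|URL|\{[^{}]*\}|\([^()]*\)")

_WILDCARDS = {
    "@USER": r"@[a-z0-9_]+",
    "BRAND": r"[a-z0-9_]+(?:\s+[a-z0-9_]+){0,2}?",
    "URL": re.escape(_URL_SENTINEL),
}


@dataclass(frozen=True)
class CyborgTemplate:
    """A slot template with alternation ``{a,b}``, optional ``(...)`` groups
    and the wildcards ``@USER``, ``BRAND``, ``URL`` and ``{#}``."""

    template_id: str
    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_rx", _compile_template(self.pattern))
        if not _norm(_SLOT_RE.sub(" ", self.pattern)).strip():
            raise ValueError(f"template {self.template_id}: no literal words")

    def matches(self, text: str) -> bool:
        return self._rx.fullmatch(" " + _norm(text)) is not None


def _compile_template(pattern: str) -> re.Pattern:
    parts: list[str] = []
    pos = 0
    for m in _SLOT_RE.finditer(pattern):
        if m.start() > pos:
            lit = _literal_rx(pattern[pos: m.start()])
            if lit:
                parts.append(r"\s+" + lit)
        tok = m.group(0)
        if tok in _WILDCARDS:
            parts.append(r"\s+" + _WILDCARDS[tok])
        elif tok.startswith("{"):
            inner = tok[1:-1]
            if inner.strip() == "#":
                parts.append(r"\s+[0-9]+")
            else:
                opts = [_literal_rx(o) for o in inner.split(",")]
                opts = [o for o in opts if o]
                if not opts:
                    raise ValueError(f"empty alternation in template: {tok}")
                parts.append(r"\s+(?:" + "|".join(opts) + r")")
        else:  # optional "(...)" fragment
            lit = _literal_rx(tok[1:-1])
            if lit:
                parts.append(r"(?:\s+" + lit + r")?")
        pos = m.end()
    if pos < len(pattern):
        lit = _literal_rx(pattern[pos:])
        if lit:
            parts.append(r"\s+" + lit)
    return re.compile("".join(parts) + r"\s*")


def cyborg_match(
    text: str, templates: Sequence[CyborgTemplate]
) -> tuple[bool, str | None]:
    """Whether *text* instantiates any template; returns (hit, template id)."""
    for tpl in templates:
        if tpl.matches(text):
            return True, tpl.template_id
    return False, None


def load_cyborg_templates(path: str | Path) -> list[CyborgTemplate]:
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [CyborgTemplate(str(d["id"]), d["pattern"]) for d in doc["templates"]]


def default_cyborg_templates() -> list[CyborgTemplate]:
    ref = resources.files("vapewatch.data").joinpath("cyborg_templates.yaml")
    with ref.open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return [CyborgTemplate(str(d["id"]), d["pattern"]) for d in doc["templates"]]


# --- yearly summary ---------------------------------------------------------


def topic_year_summary(
    automated_tweets: Sequence[Tweet],
    config: KeywordConfig,
) -> pd.DataFrame:
    """Per-topic, per-year counts, share of automated tweets, and impressions.

    The percentage denominator is the year's automated tweet total (the
    convention that reproduces the published subcategory shares).  Years are
    taken from each tweet's local post time.
    """
    rows = []
    labels = {t.tweet_id: classify_topics(t, config) for t in automated_tweets}
    years = sorted({t.local_time.year for t in automated_tweets})
    for year in years:
        in_year = [t for t in automated_tweets if t.local_time.year == year]
        for topic in TOPICS:
            hits = [t for t in in_year if topic in labels[t.tweet_id].topics]
            rows.append(
                {
                    "topic": topic,
                    "year": year,
                    "count": len(hits),
                    "automated_total": len(in_year),
                    "percentage": round(100.0 * len(hits) / len(in_year), 2)
                    if in_year
                    else float("nan"),
                    "impressions": impressions(hits),
                }
            )
    return pd.DataFrame(rows)
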