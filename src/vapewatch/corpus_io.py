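"""Tweet corpus data model, I/O, tokenization, keyword matching and time handling.

A corpus is a flat sequence of :class:`Tweet` records; :func:`group_accounts`
assembles per-account ordinal tweet streams.  Two on-disk dialects are
supported: record-per-line JSON (``jsonl``) and a delimited CSV table with
header (``csv``).  Keyword configuration (e-cigarette patterns, marketing
jargon, per-topic phrase lists) lives in a YAML document; the package ships a
default under ``vapewatch/data/keywords.yaml``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Tweet",
    "Account",
    "KeywordConfig",
    "tokenize",
    "expand_pattern",
    "match_ecig",
    "count_urls",
    "find_urls",
    "localize",
    "read_corpus",
    "write_corpus",
    "group_accounts",
    "load_keyword_config",
    "default_keyword_config",
]

TOPIC_NAMES = ("commercial", "cessation", "discount", "flavor")

_REQUIRED_FIELDS = ("tweet_id", "account_id", "utc_time", "text", "follower_count")


@dataclass(frozen=True)
class Tweet:
    """One message with its author metadata.

    ``tz_offset_minutes`` is the signed minutes to add to UTC to obtain the
    author's local wall-clock time; ``None`` when Twitter reported no zone.
    """

    tweet_id: str
    account_id: str
    utc_time: datetime
    text: str
    follower_count: int
    tz_offset_minutes: int | None = None
    language: str | None = None
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"tweet {self.tweet_id}: empty text")
        if self.follower_count < 0:
            raise ValueError(f"tweet {self.tweet_id}: negative follower_count")

    @property
    def local_time(self) -> datetime:
        return localize(self.utc_time, self.tz_offset_minutes)[0]


@dataclass
class Account:
    """Ordinal tweet stream of a single author, non-decreasing in post time."""

    account_id: str
    tweets: list[Tweet] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.tweets:
            if t.account_id != self.account_id:
                raise ValueError(
                    f"tweet {t.tweet_id} belongs to {t.account_id}, "
                    f"not {self.account_id}"
                )
        self.tweets.sort(key=lambda t: t.utc_time)

    def __len__(self) -> int:
        return len(self.tweets)

    def texts(self) -> list[str]:
        return [t.text for t in self.tweets]


@dataclass(frozen=True)
class KeywordConfig:
    """Phrase lists driving keyword classification.

    All phrases are stored lowercase.  ``ecig_patterns`` may use the
    ``e(-)cig`` hyphen-optional notation; ``topic_keywords`` maps each of the
    four fixed topics (commercial, cessation, discount, flavor) to its phrase
    list, with ``(...)`` optional fragments already expanded by the loader.
    """

    ecig_patterns: tuple[str, ...]
    marketing_jargon: tuple[str, ...]
    topic_keywords: Mapping[str, tuple[str, ...]]
    flavor_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.topic_keywords) != set(TOPIC_NAMES):
            raise ValueError(
                f"topic_keywords must cover exactly {TOPIC_NAMES}, "
                f"got {tuple(self.topic_keywords)}"
            )
        for name, phrases in [
            ("ecig_patterns", self.ecig_patterns),
            ("marketing_jargon", self.marketing_jargon),
            ("flavor_list", self.flavor_list),
            *[(f"topic_keywords[{t}]", p) for t, p in self.topic_keywords.items()],
        ]:
            if not phrases:
                raise ValueError(f"{name} must be non-empty")
            for p in phrases:
                if p != p.lower():
                    raise ValueError(f"{name}: phrase {p!r} is not lowercase")


# --- tokenization -----------------------------------------------------------

# Punctuation other than #, @ and in-word apostrophes becomes a space before
# splitting; hashtag/mention sigils are semantic on Twitter and kept attached.
_PUNCT_RE = re.compile(r"[^a-z0-9#@']")
_TOKEN_STRIP_RE = re.compile(r"^'+|'+$")


def tokenize(text: str, keep_sigils: bool = True) -> list[str]:
    """Case-fold *text* and split into tokens.

    Punctuation (everything outside word characters, ``#``, ``@`` and
    apostrophes) is replaced by a space, the result is split on whitespace and
    stray apostrophes are stripped from token edges (``don't`` keeps its
    in-word apostrophe).  With ``keep_sigils=False`` the ``#``/``@`` markers
    are dropped too (strict punctuation removal).
    """
    folded = text.casefold()
    if not keep_sigils:
        folded = folded.replace("#", " ").replace("@", " ")
    spaced = _PUNCT_RE.sub(" ", folded)
    toks = [_TOKEN_STRIP_RE.sub("", tok) for tok in spaced.split()]
    return [t for t in toks if t]


# --- keyword matching -------------------------------------------------------


def expand_pattern(pattern: str) -> list[str]:
    """Expand hyphen-optional and optional-fragment notation to literals.

    ``e(-)cig`` → ``ecig``, ``e-cig``, ``e cig``; a general ``(frag)`` expands
    to presence/absence of *frag*.  Expansion is mechanical and exhaustive, so
    matching downstream is plain substring search.
    """
    m = re.search(r"\(([^)]*)\)", pattern)
    if m is None:
        return [pattern]
    head, frag, tail = pattern[: m.start()], m.group(1), pattern[m.end() :]
    if frag == "-":
        stems = [head + "-" + tail, head + tail, head + " " + tail]
    else:
        stems = [head + frag + tail, head + tail]
    out: list[str] = []
    for s in stems:
        for e in expand_pattern(s):
            if e not in out:
                out.append(e)
    return out


def match_ecig(text: str, patterns: Sequence[str]) -> bool:
    """True iff any e-cigarette pattern occurs in the case-folded text.

    Matching is substring-level, so ``e(-)cig`` also fires on ``ecigs`` and
    ``e-cigarette``.
    """
    folded = text.casefold()
    for pat in patterns:
        for variant in expand_pattern(pat):
            if variant in folded:
                return True
    return False


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", flags=re.IGNORECASE)


def find_urls(text: str) -> list[str]:
    """Non-overlapping URL-like substrings: ``http(s)://`` or ``www.`` up to whitespace."""
    return _URL_RE.findall(text)


def count_urls(text: str) -> int:
    return len(_URL_RE.findall(text))


# --- time handling ----------------------------------------------------------


def localize(utc_time: datetime, tz_offset_minutes: int | None) -> tuple[datetime, bool]:
    """Convert a UTC timestamp to the author's local wall-clock time.

    Returns ``(local_naive_datetime, localized_flag)``; with a missing offset
    the UTC time is passed through and the flag is False.
    """
    base = utc_time
    if base.tzinfo is not None:
        base = base.astimezone(timezone.utc).replace(tzinfo=None)
    if tz_offset_minutes is None:
        return base, False
    return base + timedelta(minutes=int(tz_offset_minutes)), True


# --- corpus I/O -------------------------------------------------------------

_ISO = "%Y-%m-%dT%H:%M:%S"


def _tweet_to_record(t: Tweet) -> dict:
    return {
        "tweet_id": t.tweet_id,
        "account_id": t.account_id,
        "utc_time": t.utc_time.strftime(_ISO),
        "tz_offset_minutes": t.tz_offset_minutes,
        "text": t.text,
        "follower_count": t.follower_count,
        "language": t.language,
        "is_retweet": t.is_retweet,
    }


def _record_to_tweet(rec: Mapping, lineno: int) -> Tweet:
    for f in _REQUIRED_FIELDS:
        if f not in rec or rec[f] in (None, ""):
            raise ValueError(f"line {lineno}: missing field: {f}")
    off = rec.get("tz_offset_minutes")
    if off in ("", None):
        off = None
    else:
        off = int(off)
    lang = rec.get("language") or None
    rt = rec.get("is_retweet", False)
    if isinstance(rt, str):
        rt = rt.strip().lower() in ("1", "true", "t", "yes")
    try:
        when = datetime.strptime(str(rec["utc_time"]), _ISO)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad utc_time {rec['utc_time']!r}") from exc
    return Tweet(
        tweet_id=str(rec["tweet_id"]),
        account_id=str(rec["account_id"]),
        utc_time=when,
        tz_offset_minutes=off,
        text=str(rec["text"]),
        follower_count=int(rec["follower_count"]),
        language=lang,
        is_retweet=bool(rt),
    )


_FIELD_ORDER = [
    "tweet_id", "account_id", "utc_time", "tz_offset_minutes",
    "text", "follower_count", "language", "is_retweet",
]


def write_corpus(tweets: Iterable[Tweet], path: str | Path, dialect: str = "jsonl") -> None:
    path = Path(path)
    if dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for t in tweets:
                fh.write(json.dumps(_tweet_to_record(t), ensure_ascii=False) + "\n")
    elif dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_FIELD_ORDER)
            w.writeheader()
            for t in tweets:
                rec = _tweet_to_record(t)
                rec["tz_offset_minutes"] = "" if rec["tz_offset_minutes"] is None else rec["tz_offset_minutes"]
                rec["language"] = rec["language"] or ""
                w.writerow(rec)
    else:
        raise ValueError(f"unknown dialect: {dialect}")


def read_corpus(path: str | Path, dialect: str | None = None) -> list[Tweet]:
    """Read a corpus file; dialect inferred from suffix when not given.

    Malformed records raise ``ValueError`` naming the offending line; duplicate
    tweet ids raise too (ids must be unique within a corpus).
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    tweets: list[Tweet] = []
    if dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"line {lineno}: malformed JSON record") from exc
                tweets.append(_record_to_tweet(rec, lineno))
    elif dialect == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                tweets.append(_record_to_tweet(rec, lineno))
    else:
        raise ValueError(f"unknown dialect: {dialect}")
    seen: set[str] = set()
    for t in tweets:
        if t.tweet_id in seen:
            raise ValueError(f"duplicate tweet_id: {t.tweet_id}")
        seen.add(t.tweet_id)
    return tweets


def group_accounts(tweets: Iterable[Tweet]) -> dict[str, Account]:
    """Assemble per-account ordinal streams (sorted by UTC post time)."""
    by_acct: dict[str, list[Tweet]] = {}
    for t in tweets:
        by_acct.setdefault(t.account_id, []).append(t)
    return {aid: Account(aid, tw) for aid, tw in by_acct.items()}


# --- keyword config ---------------------------------------------------------


def load_keyword_config(path: str | Path) -> KeywordConfig:
    """Load a keyword YAML document.

    Expected keys: ``ecig_patterns``, ``marketing_jargon``, ``topics`` (map of
    the four topic names to phrase lists) and ``flavors``.  Optional fragments
    in phrases are expanded here so downstream matching is literal.
    """
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _config_from_doc(doc)


def _expand_all(phrases: Sequence[str]) -> tuple[str, ...]:
    out: list[str] = []
    for p in phrases:
        for v in expand_pattern(str(p).casefold()):
            if v not in out:
                out.append(v)
    return tuple(out)


def _config_from_doc(doc: Mapping) -> KeywordConfig:
    flavors = _expand_all(doc["flavors"])
    topics = {name: _expand_all(doc["topics"][name]) for name in TOPIC_NAMES}
    # flavor phrases include the flavor-name list itself
    topics["flavor"] = tuple(dict.fromkeys(topics["flavor"] + flavors))
    return KeywordConfig(
        ecig_patterns=tuple(str(p).casefold() for p in doc["ecig_patterns"]),
        marketing_jargon=_expand_all(doc["marketing_jargon"]),
        topic_keywords=topics,
        flavor_list=flavors,
    )


def default_keyword_config() -> KeywordConfig:
    """The keyword configuration shipped with the package."""
    ref = resources.files("vapewatch.data").joinpath("keywords.yaml")
    with ref.open(encoding="utf-8") as fh:
        return _config_from_doc(yaml.safe_load(fh))
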