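"""Corpus data model: accounts, tweets, profile search, and the harvest cap.

An :class:`Account` is the unit over which co-occurrence is later counted:
a free-text user profile (searched for disease names) plus an ordered list
of timestamped tweets, newest first.  Corpora are serialized as JSON-Lines
(UTF-8, one account object per line) so they stream and diff cleanly.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Tweet",
    "Account",
    "Corpus",
    "QueryTermSet",
    "CorpusFormatError",
    "ValidationError",
    "normalize",
    "read_corpus",
    "write_corpus",
    "load_query_terms",
    "search_profiles",
    "cap_latest_tweets",
    "TWEET_CHAR_LIMIT",
    "DEFAULT_TWEET_CAP",
]

#: Platform character limit for a single tweet (classic short-message limit).
TWEET_CHAR_LIMIT = 140

#: Default number of latest tweets retained per account at harvest time.
DEFAULT_TWEET_CAP = 200


class CorpusFormatError(ValueError):
    """A serialized corpus record could not be parsed."""


class ValidationError(ValueError):
    """A corpus violates a structural invariant (e.g. duplicate account ids)."""


def normalize(text: str) -> str:
    """Unicode NFKC normalization followed by case folding.

    All profile matching and lemma comparison goes through this, so
    half-width/full-width script variants and case differences collapse
    onto one canonical string.
    """
    return unicodedata.normalize("NFKC", text).casefold()


@dataclass(frozen=True)
class Tweet:
    text: str
    posted_at: datetime

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError("tweet text must be non-empty after stripping")
        if self.posted_at.tzinfo is None:
            object.__setattr__(
                self, "posted_at", self.posted_at.replace(tzinfo=timezone.utc)
            )


@dataclass
class Account:
    """A user account: profile text plus tweets ordered newest-first."""

    account_id: str
    profile_text: str
    tweets: list[Tweet] = field(default_factory=list)

    def sorted_newest_first(self) -> "Account":
        """Return a copy whose tweets are stably sorted by descending time.

        Python's sort is stable and ``reverse=True`` preserves the original
        order of equal timestamps, which makes the downstream harvest cap
        deterministic.
        """
        tweets = sorted(self.tweets, key=lambda t: t.posted_at, reverse=True)
        return Account(self.account_id, self.profile_text, tweets)


@dataclass
class Corpus:
    accounts: list[Account] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for a in self.accounts:
            if a.account_id in seen:
                raise ValidationError(f"duplicate account_id: {a.account_id!r}")
            seen.add(a.account_id)

    def __len__(self) -> int:
        return len(self.accounts)

    def __iter__(self) -> Iterator[Account]:
        return iter(self.accounts)


@dataclass
class QueryTermSet:
    """A disease name and its script/spelling variants for profile search."""

    canonical_name: str
    variants: list[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("QueryTermSet requires at least one variant")

    def matches(self, profile_text: str) -> bool:
        folded = normalize(profile_text)
        return any(normalize(v) in folded for v in self.variants)


# ---------------------------------------------------------------------------
# Serialization (JSON-Lines dialect)
# ---------------------------------------------------------------------------

def _tweet_to_obj(t: Tweet) -> dict:
    return {"text": t.text, "posted_at": t.posted_at.isoformat()}


def _account_record(a: Account) -> str:
    obj = {
        "account_id": a.account_id,
        "profile": a.profile_text,
        "tweets": [_tweet_to_obj(t) for t in a.tweets],
    }
    return json.dumps(obj, ensure_ascii=False, separators=(",", ":"))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write one JSON record per account; deterministic byte-for-byte."""
    corpus.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for a in corpus.accounts:
            fh.write(_account_record(a))
            fh.write("\n")


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-Lines corpus; tweet lists are re-sorted newest-first.

    Raises :class:`CorpusFormatError` naming the offending line on malformed
    records, and :class:`ValidationError` on duplicate account ids.
    """
    path = Path(path)
    accounts: list[Account] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                obj = json.loads(raw)
                tweets = [
                    Tweet(t["text"], datetime.fromisoformat(t["posted_at"]))
                    for t in obj["tweets"]
                ]
                account = Account(obj["account_id"], obj["profile"], tweets)
            except ValidationError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise CorpusFormatError(
                    f"{path.name}: malformed account record at line {lineno}: {exc}"
                ) from exc
            accounts.append(account.sorted_newest_first())
    return Corpus(accounts)


def load_query_terms(path: str | Path, canonical_name: str | None = None) -> QueryTermSet:
    """Load a query-term file: one variant per line, ``#`` comments allowed."""
    path = Path(path)
    variants = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            variants.append(line)
    name = canonical_name if canonical_name is not None else path.stem.replace("_", " ")
    return QueryTermSet(name, variants)


# ---------------------------------------------------------------------------
# Harvest emulation
# ---------------------------------------------------------------------------

def search_profiles(corpus: Corpus, query: QueryTermSet) -> Corpus:
    """Select the accounts whose profile mentions any query variant.

    Matching is substring containment after NFKC normalization and case
    folding; account order is preserved, so the operation is idempotent.
    """
    matched = [a for a in corpus.accounts if query.matches(a.profile_text)]
    meta = dict(corpus.metadata)
    meta["query"] = query.canonical_name
    return Corpus(matched, meta)


def cap_latest_tweets(account: Account, cap: int = DEFAULT_TWEET_CAP) -> Account:
    """Keep only the ``cap`` newest tweets of an account.

    Emulates harvesting "the latest tweets" of each matched account.  Ties in
    timestamp are broken by the account's original record order (stable sort).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    sorted_account = account.sorted_newest_first()
    sorted_account.tweets = sorted_account.tweets[:cap]
    return sorted_account
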