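"""Tweets -> per-account noun lines.

The stages mirror a classic Japanese text-mining pipeline: each tweet is
split into lines at sentence-final periods, each line is broken into
morpheme-like tokens carrying a lemma ("original form") and a coarse
part-of-speech tag, nouns are kept (verbs and adjectives are deliberately
discarded: negation scoping is unreliable and they are a small fraction of
tokens), and synonymous noun lemmas are merged onto one canonical lemma.

Morphological analysis itself is behind a contract: any callable mapping a
line to ``list[Token]`` can be plugged in (e.g. a MeCab wrapper).  The
default backend is a greedy longest-match dictionary tokenizer, which is
exact on the space-delimited synthetic corpora and on any text covered by
its term dictionary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import Account, ValidationError, normalize

__all__ = [
    "Token",
    "TermDictionary",
    "SynonymMap",
    "NounLines",
    "Tokenizer",
    "split_lines",
    "tokenize",
    "extract_nouns",
    "merge_synonyms",
    "process_account",
    "NounLineTransformer",
    "read_noun_lines",
    "write_noun_lines",
]

POS = Literal["noun", "verb", "adjective", "other"]
_POS_TAGS = ("noun", "verb", "adjective", "other")

#: Sentence-final delimiters: ASCII period and the ideographic full stop.
DEFAULT_LINE_DELIMITERS = ".。"


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: POS

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValidationError("token lemma must be non-empty")
        if self.pos not in _POS_TAGS:
            raise ValidationError(f"unknown pos tag {self.pos!r}")


#: Contract for pluggable morphological analyzers.
Tokenizer = Callable[[str], "list[Token]"]


class TermDictionary:
    """Surface form -> (lemma, pos) with longest-match lookup priority.

    Surfaces and lemmas are NFKC-normalized and case-folded, so "CT" and
    "ct" share one entry.  Surfaces may contain spaces; the longest-match
    tokenizer then recognises multi-word terms ("tumor marker") as one token.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]] | None = None):
        self._entries: dict[str, tuple[str, POS]] = {}
        if entries:
            for surface, (lemma, pos) in entries.items():
                self.add(surface, lemma, pos)

    def add(self, surface: str, lemma: str, pos: str) -> None:
        key = normalize(surface)
        if not key:
            raise ValidationError("empty dictionary surface")
        if pos not in _POS_TAGS:
            raise ValidationError(f"unknown pos tag {pos!r} for surface {surface!r}")
        existing = self._entries.get(key)
        entry = (normalize(lemma), pos)
        if existing is not None and existing != entry:
            raise ValidationError(f"conflicting entries for surface {surface!r}")
        self._entries[key] = entry

    def lookup(self, surface: str) -> tuple[str, POS] | None:
        return self._entries.get(normalize(surface))

    @property
    def max_surface_length(self) -> int:
        return max((len(s) for s in self._entries), default=0)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, surface: str) -> bool:
        return normalize(surface) in self._entries

    def items(self):
        return self._entries.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermDictionary":
        """Load ``surface<TAB>lemma<TAB>pos`` (UTF-8, ``#`` comments)."""
        d = cls()
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise _format_error(path, lineno, "expected 3 tab-separated fields")
            d.add(*parts)
        return d

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{surface}\t{lemma}\t{pos}"
            for surface, (lemma, pos) in sorted(self._entries.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _format_error(path, lineno, msg) -> ValidationError:
    return ValidationError(f"{Path(path).name}: line {lineno}: {msg}")


class SynonymMap:
    """Variant lemma -> canonical lemma, validated to be single-step.

    Canonical forms must be fixed points: a canonical lemma never maps
    elsewhere, so there are no chains (a->b->c) or cycles, and applying the
    map is idempotent by construction.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._entries: dict[str, str] = {}
        if entries:
            for variant, canonical in entries.items():
                self._entries[normalize(variant)] = normalize(canonical)
        self.validate()

    def validate(self) -> None:
        for variant, canonical in self._entries.items():
            target = self._entries.get(canonical)
            if target is not None and target != canonical:
                raise ValidationError(
                    f"synonym chain: {variant!r} -> {canonical!r} -> {target!r}"
                )

    def canonical(self, lemma: str) -> str:
        key = normalize(lemma)
        return self._entries.get(key, key)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymMap":
        """Load ``variant<TAB>canonical`` (UTF-8, ``#`` comments)."""
        entries: dict[str, str] = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise _format_error(path, lineno, "expected 2 tab-separated fields")
            entries[parts[0]] = parts[1]
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{v}\t{c}" for v, c in sorted(self._entries.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class NounLines:
    """Per-account noun lines: one inner list of canonical lemmas per tweet line."""

    account_id: str
    lines: list[list[str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def split_lines(text: str, delimiters: str = DEFAULT_LINE_DELIMITERS) -> list[str]:
    """Split tweet text into lines at sentence-final periods.

    Both the ASCII period and the ideographic full stop terminate a line;
    delimiters are dropped and whitespace-only segments removed.
    """
    pattern = "[" + re.escape(delimiters) + "]"
    return [seg.strip() for seg in re.split(pattern, text) if seg.strip()]


def tokenize(line: str, dictionary: TermDictionary) -> list[Token]:
    """Greedy longest-match dictionary tokenization.

    The line is NFKC-normalized and case-folded, then scanned left to right:
    at each position the longest dictionary surface wins; where nothing
    matches, the maximal whitespace-delimited chunk becomes a fallback token
    with ``lemma == surface`` and ``pos == "other"``.
    """
    text = normalize(line)
    tokens: list[Token] = []
    i, n = 0, len(text)
    max_len = dictionary.max_surface_length
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        match = None
        for length in range(min(max_len, n - i), 0, -1):
            candidate = text[i : i + length]
            entry = dictionary.lookup(candidate)
            if entry is not None:
                match = (candidate, entry)
                break
        if match is not None:
            surface, (lemma, pos) = match
            tokens.append(Token(surface, lemma, pos))
            i += len(surface)
        else:
            j = i
            while j < n and not text[j].isspace():
                j += 1
            chunk = text[i:j]
            tokens.append(Token(chunk, chunk, "other"))
            i = j
    return tokens


def extract_nouns(tokens: Sequence[Token]) -> list[str]:
    """Keep noun lemmas only, order and within-line duplicates preserved."""
    return [t.lemma for t in tokens if t.pos == "noun"]


def merge_synonyms(nouns: Sequence[str], synonyms: SynonymMap) -> list[str]:
    """Replace each lemma by its canonical form; idempotent."""
    return [synonyms.canonical(n) for n in nouns]


def process_account(
    account: Account,
    dictionary: TermDictionary,
    synonyms: SynonymMap,
    *,
    tokenizer: Tokenizer | None = None,
    delimiters: str = DEFAULT_LINE_DELIMITERS,
) -> NounLines:
    """Full per-account stage composition; empty noun lines are dropped."""
    tok = tokenizer if tokenizer is not None else (lambda line: tokenize(line, dictionary))
    lines: list[list[str]] = []
    for tweet in account.tweets:
        for line in split_lines(tweet.text, delimiters):
            nouns = merge_synonyms(extract_nouns(tok(line)), synonyms)
            if nouns:
                lines.append(nouns)
    return NounLines(account.account_id, lines)


class NounLineTransformer(BaseEstimator, TransformerMixin):
    """Stateless transformer from accounts to per-account noun lines.

    Parameters
    ----------
    dictionary : TermDictionary
        Term dictionary for the default longest-match tokenizer (and the
        POS source for any backend that consults it).
    synonyms : SynonymMap
        Variant -> canonical lemma map applied after noun extraction.
    tokenizer : callable, optional
        Pluggable morphological-analyzer backend, ``line -> list[Token]``.
        When given it replaces the dictionary tokenizer.
    delimiters : str
        Characters treated as sentence-final line delimiters.
    """

    def __init__(
        self,
        dictionary: TermDictionary | None = None,
        synonyms: SynonymMap | None = None,
        tokenizer: Tokenizer | None = None,
        delimiters: str = DEFAULT_LINE_DELIMITERS,
    ):
        self.dictionary = dictionary
        self.synonyms = synonyms
        self.tokenizer = tokenizer
        self.delimiters = delimiters

    def fit(self, X: Iterable[Account] | None = None, y=None):
        return self

    def transform(self, X: Iterable[Account]) -> list[NounLines]:
        dictionary = self.dictionary if self.dictionary is not None else TermDictionary()
        synonyms = self.synonyms if self.synonyms is not None else SynonymMap()
        return [
            process_account(
                account,
                dictionary,
                synonyms,
                tokenizer=self.tokenizer,
                delimiters=self.delimiters,
            )
            for account in X
        ]


# ---------------------------------------------------------------------------
# Intermediate-format I/O (JSON-Lines: {"account_id": ..., "lines": [[...]]})
# ---------------------------------------------------------------------------

def write_noun_lines(noun_lines: Sequence[NounLines], path: str | Path) -> None:
    import json

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for nl in noun_lines:
            fh.write(
                json.dumps(
                    {"account_id": nl.account_id, "lines": nl.lines},
                    ensure_ascii=False,
                    separators=(",", ":"),
                )
            )
            fh.write("\n")


def read_noun_lines(path: str | Path) -> list[NounLines]:
    import json

    out: list[NounLines] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.strip():
            obj = json.loads(raw)
            out.append(NounLines(obj["account_id"], [list(l) for l in obj["lines"]]))
    return out
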