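"""Shared fixtures: tiny hand-built accounts and small generator configs."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from cooctweets.corpus import Account, Corpus, Tweet
from cooctweets.simulate import GeneratorConfig, TopicSpec
from cooctweets.text import NounLines, SynonymMap, TermDictionary

BASE = datetime(2013, 8, 18, tzinfo=timezone.utc)


def make_account(account_id: str, texts: list[str], profile: str = "") -> Account:
    """Account whose i-th text is the i-th newest tweet (minutes apart)."""
    tweets = [Tweet(t, BASE - timedelta(minutes=i)) for i, t in enumerate(texts)]
    return Account(account_id, profile, tweets)


def make_noun_lines(account_id: str, lines: list[list[str]]) -> NounLines:
    return NounLines(account_id, lines)


@pytest.fixture
def toy_dictionary() -> TermDictionary:
    return TermDictionary(
        {
            "went": ("go", "verb"),
            "ct": ("ct", "noun"),
            "scan": ("scan", "noun"),
            "home": ("home", "noun"),
            "sore": ("sore", "adjective"),
            "tumor marker": ("tumor marker", "noun"),
            "tumor": ("tumor", "noun"),
        }
    )


@pytest.fixture
def toy_synonyms() -> SynonymMap:
    return SynonymMap({"tumour": "tumor", "ct scan": "ct"})


def two_topic_config(**overrides) -> GeneratorConfig:
    """Two planted topics over a shared noise vocabulary."""
    defaults = dict(
        topics=[
            TopicSpec(
                name="breast cancer",
                profile_variants=["breast cancer", "乳がん"],
                keywords=[(w, 1.0) for w in
                          ("metastasis", "lymphedema", "chemotherapy",
                           "hormonal treatment", "palliative care", "pink ribbon")],
                keyword_line_rate=0.8,
            ),
            TopicSpec(
                name="stomach cancer",
                profile_variants=["stomach cancer", "胃がん"],
                keywords=[(w, 1.0) for w in
                          ("ct", "mri", "tumor marker", "lumbago", "ts-1",
                           "anti-cancer drug")],
                keyword_line_rate=0.8,
            ),
        ],
        accounts_per_topic=50,
        tweets_per_account=(10, 30),
        lines_per_tweet=(1, 3),
        words_per_line=(2, 6),
        noise_vocab_size=300,
        noise_rate=0.3,
        synonym_variants={"chemotherapy": ["chemo"], "ct": ["ct scan"]},
        synonym_rate=0.3,
        seed=20130818,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return two_topic_config(accounts_per_topic=8, tweets_per_account=(5, 10))


def naive_pair_counts(all_noun_lines) -> dict:
    """Triple-loop account/line/pair oracle for the co-occurrence statistic."""
    counts: dict = {}
    for nl in all_noun_lines:
        seen = set()
        for line in nl.lines:
            for i in range(len(line)):
                for j in range(len(line)):
                    if i < j and line[i] != line[j]:
                        seen.add(tuple(sorted((line[i], line[j]))))
        for p in seen:
            counts[p] = counts.get(p, 0) + 1
    return counts
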