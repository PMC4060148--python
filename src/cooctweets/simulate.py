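"""Seeded synthetic tweet corpora with planted co-occurrence structure.

The generator emulates the kind of data a profile-search harvest yields:
per-disease account populations whose profiles mention the disease name (in
one of several script/spelling variants), up to 200 tweets per account, each
tweet at most 140 characters and made of period-terminated lines.  A line is
"topical" with a per-topic probability, in which case it carries at least
two of the topic's keywords — planting elevated pair co-occurrence rates —
and is otherwise drawn from a noise vocabulary.  Keyword occurrences are
sometimes written as a synonym surface variant, so the downstream synonym
integration step has real work to undo.

Generation is a pure function of the configuration (which includes the
seed): the same config always yields a byte-identical corpus.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import (
    Account,
    Corpus,
    QueryTermSet,
    Tweet,
    TWEET_CHAR_LIMIT,
    DEFAULT_TWEET_CAP,
    normalize,
)
from .text import SynonymMap, TermDictionary

__all__ = [
    "TopicSpec",
    "GeneratorConfig",
    "ConfigurationError",
    "generate_corpus",
    "planted_pairs",
    "default_study_config",
]

#: Reference "now" for synthetic timestamps (start of the emulated harvest).
_BASE_TIME = datetime(2013, 8, 18, 0, 0, 0, tzinfo=timezone.utc)


class ConfigurationError(ValueError):
    """The generator configuration is infeasible or inconsistent."""


@dataclass
class TopicSpec:
    """One planted topic: a disease population and its keyword vocabulary."""

    name: str
    profile_variants: list[str]
    keywords: list[tuple[str, float]]
    keyword_line_rate: float = 0.6
    accounts: int | None = None  # overrides GeneratorConfig.accounts_per_topic

    def validate(self) -> None:
        if not self.profile_variants:
            raise ConfigurationError(f"topic {self.name!r}: no profile variants")
        if len(self.keywords) < 2:
            raise ConfigurationError(f"topic {self.name!r}: needs >=2 keywords")
        if any(w <= 0 for _, w in self.keywords):
            raise ConfigurationError(f"topic {self.name!r}: keyword weights must be >0")
        if not 0.0 <= self.keyword_line_rate <= 1.0:
            raise ConfigurationError(f"topic {self.name!r}: keyword_line_rate not in [0,1]")
        if self.accounts is not None and self.accounts < 0:
            raise ConfigurationError(f"topic {self.name!r}: negative account count")


@dataclass
class GeneratorConfig:
    topics: list[TopicSpec]
    accounts_per_topic: int = 50
    tweets_per_account: tuple[int, int] = (20, 60)
    lines_per_tweet: tuple[int, int] = (1, 3)
    words_per_line: tuple[int, int] = (2, 6)
    noise_vocab_size: int = 300
    noise_rate: float = 0.3
    synonym_variants: dict[str, list[str]] = field(default_factory=dict)
    synonym_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.accounts_per_topic < 0:
            raise ConfigurationError("accounts_per_topic must be >= 0")
        for name, (lo, hi) in (
            ("tweets_per_account", self.tweets_per_account),
            ("lines_per_tweet", self.lines_per_tweet),
            ("words_per_line", self.words_per_line),
        ):
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name}: need 0 < min <= max, got ({lo}, {hi})")
        if self.tweets_per_account[1] > DEFAULT_TWEET_CAP:
            raise ConfigurationError(
                f"tweets_per_account max exceeds the harvest cap of {DEFAULT_TWEET_CAP}"
            )
        if self.words_per_line[0] < 2:
            raise ConfigurationError("words_per_line min must be >= 2 (a pair per topical line)")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigurationError("noise_rate not in [0,1]")
        if not 0.0 <= self.synonym_rate <= 1.0:
            raise ConfigurationError("synonym_rate not in [0,1]")
        if self.noise_vocab_size < 0:
            raise ConfigurationError("noise_vocab_size must be >= 0")
        for topic in self.topics:
            topic.validate()

    # -- companion resources ------------------------------------------------

    def noise_vocabulary(self) -> list[str]:
        return [f"filler{i:03d}" for i in range(self.noise_vocab_size)]

    def term_dictionary(self) -> TermDictionary:
        """Dictionary covering every surface the generator can emit (all nouns)."""
        d = TermDictionary()
        for topic in self.topics:
            for word, _ in topic.keywords:
                d.add(word, word, "noun")
        for canonical, variants in self.synonym_variants.items():
            for v in variants:
                d.add(v, v, "noun")
        for w in self.noise_vocabulary():
            d.add(w, w, "noun")
        return d

    def synonym_map(self) -> SynonymMap:
        entries = {
            v: canonical
            for canonical, variants in self.synonym_variants.items()
            for v in variants
        }
        return SynonymMap(entries)

    def query_term_sets(self) -> list[QueryTermSet]:
        return [QueryTermSet(t.name, list(t.profile_variants)) for t in self.topics]

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "topics": [
                {
                    "name": t.name,
                    "profile_variants": t.profile_variants,
                    "keywords": [[w, wt] for w, wt in t.keywords],
                    "keyword_line_rate": t.keyword_line_rate,
                    **({"accounts": t.accounts} if t.accounts is not None else {}),
                }
                for t in self.topics
            ],
            "accounts_per_topic": self.accounts_per_topic,
            "tweets_per_account": list(self.tweets_per_account),
            "lines_per_tweet": list(self.lines_per_tweet),
            "words_per_line": list(self.words_per_line),
            "noise_vocab_size": self.noise_vocab_size,
            "noise_rate": self.noise_rate,
            "synonym_variants": self.synonym_variants,
            "synonym_rate": self.synonym_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "GeneratorConfig":
        topics = [
            TopicSpec(
                name=t["name"],
                profile_variants=list(t["profile_variants"]),
                keywords=[(w, float(wt)) for w, wt in t["keywords"]],
                keyword_line_rate=float(t.get("keyword_line_rate", 0.6)),
                accounts=t.get("accounts"),
            )
            for t in obj["topics"]
        ]
        cfg = cls(
            topics=topics,
            accounts_per_topic=int(obj.get("accounts_per_topic", 50)),
            tweets_per_account=tuple(obj.get("tweets_per_account", (20, 60))),
            lines_per_tweet=tuple(obj.get("lines_per_tweet", (1, 3))),
            words_per_line=tuple(obj.get("words_per_line", (2, 6))),
            noise_vocab_size=int(obj.get("noise_vocab_size", 300)),
            noise_rate=float(obj.get("noise_rate", 0.3)),
            synonym_variants={
                k: list(v) for k, v in obj.get("synonym_variants", {}).items()
            },
            synonym_rate=float(obj.get("synonym_rate", 0.3)),
            seed=int(obj.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), ensure_ascii=False, indent=2) + "\n",
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_PROFILE_TEMPLATES = (
    "living with {v} since my diagnosis",
    "{v} survivor sharing everyday notes",
    "diary of a {v} patient",
    "fighting {v} one day at a time",
)


def _weighted_pair(rng: random.Random, words: Sequence[str], weights: Sequence[float]) -> tuple[str, str]:
    """Two distinct weighted draws (rejection on the second)."""
    first = rng.choices(words, weights=weights)[0]
    second = first
    while second == first:
        second = rng.choices(words, weights=weights)[0]
    return first, second


def _realize(rng: random.Random, word: str, variants: Mapping[str, list[str]], rate: float) -> str:
    vs = variants.get(word)
    if vs and rng.random() < rate:
        return rng.choice(vs)
    return word


def _fit_line(words: list[str], minimum: int) -> list[str] | None:
    """Drop trailing words until the rendered line fits the char limit.

    Returns None when even the minimal core cannot fit.
    """
    while words:
        if len(" ".join(words)) + 1 <= TWEET_CHAR_LIMIT:  # +1 for the period
            return words
        if len(words) <= minimum:
            return None
        words = words[:-1]
    return None


def _make_line(
    rng: random.Random,
    topic: TopicSpec,
    config: GeneratorConfig,
    noise: Sequence[str],
) -> list[str]:
    kw_words = [w for w, _ in topic.keywords]
    kw_weights = [wt for _, wt in topic.keywords]
    w = rng.randint(*config.words_per_line)
    topical = rng.random() < topic.keyword_line_rate and len(kw_words) >= 2
    if topical:
        a, b = _weighted_pair(rng, kw_words, kw_weights)
        words = [a, b]
        for _ in range(w - 2):
            if noise and rng.random() < config.noise_rate:
                words.append(rng.choice(noise))
            else:
                words.append(rng.choices(kw_words, weights=kw_weights)[0])
        rng.shuffle(words)
        minimum = 2
    else:
        if not noise:
            # no noise vocabulary: fall back to a topical line
            a, b = _weighted_pair(rng, kw_words, kw_weights)
            words, minimum = [a, b], 2
        else:
            words = [rng.choice(noise) for _ in range(w)]
            minimum = 1
    words = [_realize(rng, x, config.synonym_variants, config.synonym_rate) for x in words]
    fitted = _fit_line(words, minimum)
    if fitted is None:
        raise ConfigurationError(
            "generated line cannot fit the "
            f"{TWEET_CHAR_LIMIT}-character tweet limit (keywords too long?)"
        )
    return fitted


def _make_tweet_text(
    rng: random.Random,
    topic: TopicSpec,
    config: GeneratorConfig,
    noise: Sequence[str],
) -> str:
    n_lines = rng.randint(*config.lines_per_tweet)
    rendered: list[str] = []
    total = 0
    for i in range(n_lines):
        line = " ".join(_make_line(rng, topic, config, noise)) + "."
        extra = len(line) + (1 if rendered else 0)  # joining space
        if rendered and total + extra > TWEET_CHAR_LIMIT:
            break
        rendered.append(line)
        total += extra
    return " ".join(rendered)


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate a corpus; deterministic in ``config`` (including its seed)."""
    config.validate()
    rng = random.Random(config.seed)
    noise = config.noise_vocabulary()
    accounts: list[Account] = []
    for ti, topic in enumerate(config.topics):
        n_accounts = topic.accounts if topic.accounts is not None else config.accounts_per_topic
        slug = normalize(topic.name).replace(" ", "-")
        for ai in range(n_accounts):
            variant = rng.choice(topic.profile_variants)
            profile = rng.choice(_PROFILE_TEMPLATES).format(v=variant)
            n_tweets = rng.randint(*config.tweets_per_account)
            tweets = [
                Tweet(
                    _make_tweet_text(rng, topic, config, noise),
                    _BASE_TIME - timedelta(minutes=k),
                )
                for k in range(n_tweets)  # k=0 is the newest
            ]
            accounts.append(Account(f"{slug}-{ai:04d}", profile, tweets))
    return Corpus(
        accounts,
        metadata={"seed": config.seed, "generator": "cooctweets.simulate"},
    )


def planted_pairs(config: GeneratorConfig) -> dict[str, set[tuple[str, str]]]:
    """Ground truth: per topic, every unordered pair of its canonical keywords.

    These are the pairs generated at elevated rate; lemmas are normalized the
    same way the text pipeline normalizes them, so the sets compare directly
    with pair-count keys.
    """
    out: dict[str, set[tuple[str, str]]] = {}
    for topic in config.topics:
        lemmas = [normalize(w) for w, _ in topic.keywords]
        out[topic.name] = {
            tuple(sorted(p)) for p in itertools.combinations(lemmas, 2)
        }
    return out


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

def default_study_config(seed: int = 0) -> GeneratorConfig:
    """Six cancer-patient populations emulating the published study's scale.

    Population sizes follow the reported profile-search counts (313 breast
    cancer, 158 leukemia, 134 uterine/cervical, 87 lung, 64 colon/colorectal,
    44 stomach); each topic's keyword vocabulary is the published per-cancer
    keyword set, and profile variants include Japanese-script disease names.
    """

    def kws(*words: str) -> list[tuple[str, float]]:
        return [(w, 1.0) for w in words]

    topics = [
        TopicSpec(
            name="breast cancer",
            profile_variants=["breast cancer", "乳がん", "乳癌"],
            keywords=kws(
                "self-diagnosis", "metastasis", "lymphedema", "chemotherapy",
                "hormonal treatment", "palliative care", "pink ribbon",
            ),
            accounts=313,
        ),
        TopicSpec(
            name="leukemia",
            profile_variants=["leukemia", "白血病"],
            keywords=kws(
                "liver function test", "foot pain", "immunosuppression", "gvhd",
                "chemotherapy", "steroid treatment", "transfusion",
                "platelet transfusion", "aml", "stem cell transplantation",
            ),
            accounts=158,
        ),
        TopicSpec(
            name="uterine and cervical cancer",
            profile_variants=[
                "uterine cancer", "cervical cancer", "子宮がん", "子宮頸がん",
            ],
            keywords=kws(
                "lymphedema", "educational activity", "screening",
                "vaccination", "official support", "health insurance",
            ),
            accounts=134,
        ),
        TopicSpec(
            name="lung cancer",
            profile_variants=["lung cancer", "肺がん"],
            keywords=kws(
                "ct", "metastasis", "shoulder pain", "back pain", "iressa",
                "side effects", "anti-cancer drug", "tarceva", "palliative care",
            ),
            accounts=87,
        ),
        TopicSpec(
            name="colon and colorectal cancer",
            profile_variants=["colon cancer", "colorectal cancer", "大腸がん"],
            keywords=kws(
                "ct", "pet", "elplat", "side effects", "chemotherapy", "diet",
                "nursing care",
            ),
            accounts=64,
        ),
        TopicSpec(
            name="stomach cancer",
            profile_variants=["stomach cancer", "胃がん"],
            keywords=kws(
                "ct", "mri", "tumor marker", "lumbago", "ts-1", "side effects",
                "anti-cancer drug", "administration of iron",
            ),
            accounts=44,
        ),
    ]
    return GeneratorConfig(
        topics=topics,
        accounts_per_topic=50,
        tweets_per_account=(20, 60),
        lines_per_tweet=(1, 3),
        words_per_line=(2, 6),
        noise_vocab_size=300,
        noise_rate=0.3,
        synonym_variants={
            "chemotherapy": ["chemo"],
            "metastasis": ["metastases"],
            "tumor marker": ["tumour marker"],
            "ct": ["ct scan"],
        },
        synonym_rate=0.3,
        seed=seed,
    )
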