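"""End-to-end driver: corpus -> per-disease networks, layouts and reports.

For each disease query the driver selects accounts by profile search, caps
each account to its latest tweets, extracts per-account noun lines, counts
account-level pair co-occurrence, keeps the top-k pairs as a network,
relaxes the spring layout, and writes the exports (edge list TSV, GraphML
with coordinates, category report TSV) plus a machine-readable run manifest
with per-stage counts.  The whole run is a pure function of its inputs and
the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .corpus import (
    Corpus,
    QueryTermSet,
    DEFAULT_TWEET_CAP,
    cap_latest_tweets,
    load_query_terms,
    normalize,
    read_corpus,
    search_profiles,
)
from .layout import Layout, LayoutParams, reduce_overlap, relax
from .network import DEFAULT_TOP_K, CooccurrenceNetwork
from .report import (
    CategoryDictionary,
    categorize_keywords,
    export_graphml,
    load_default_categories,
)
from .text import NounLineTransformer, SynonymMap, TermDictionary

__all__ = ["RunConfig", "QueryResult", "run_query", "run_pipeline"]

logger = logging.getLogger("cooctweets")


@dataclass
class RunConfig:
    """File-level configuration of a full pipeline run."""

    corpus: Path
    queries: dict[str, Path]
    dictionary: Path
    synonyms: Path
    categories: Path | None = None
    k: int = DEFAULT_TOP_K
    tweet_cap: int = DEFAULT_TWEET_CAP
    ties: str = "cut"
    layout: dict = field(default_factory=dict)
    min_separation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for label, path in [("corpus", self.corpus), ("dictionary", self.dictionary),
                            ("synonyms", self.synonyms), ("categories", self.categories),
                            *[(f"query {name!r}", p) for name, p in self.queries.items()]]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: no such file: {path}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def resolve(p):
            return (base / p) if p is not None and not Path(p).is_absolute() else (
                Path(p) if p is not None else None
            )

        return cls(
            corpus=resolve(obj["corpus"]),
            queries={name: resolve(p) for name, p in obj["queries"].items()},
            dictionary=resolve(obj["dictionary"]),
            synonyms=resolve(obj["synonyms"]),
            categories=resolve(obj.get("categories")),
            k=int(obj.get("k", DEFAULT_TOP_K)),
            tweet_cap=int(obj.get("tweet_cap", DEFAULT_TWEET_CAP)),
            ties=obj.get("ties", "cut"),
            layout=dict(obj.get("layout", {})),
            min_separation=float(obj.get("min_separation", 0.05)),
            seed=int(obj.get("seed", 0)),
        )


@dataclass
class QueryResult:
    """Everything computed for one disease query."""

    name: str
    graph: nx.Graph
    layout: Layout | None
    report: pd.DataFrame
    counts: dict


def run_query(
    corpus: Corpus,
    query: QueryTermSet,
    dictionary: TermDictionary,
    synonyms: SynonymMap,
    categories: CategoryDictionary | None = None,
    *,
    k: int = DEFAULT_TOP_K,
    tweet_cap: int = DEFAULT_TWEET_CAP,
    ties: str = "cut",
    layout_params: LayoutParams | None = None,
    min_separation: float | None = 0.05,
) -> QueryResult:
    """Run the full analysis for one disease query, in memory."""
    matched = search_profiles(corpus, query)
    logger.info("stage=search query=%s accounts_in=%d accounts_matched=%d",
                query.canonical_name, len(corpus), len(matched))
    capped = [cap_latest_tweets(a, tweet_cap) for a in matched]
    noun_lines = NounLineTransformer(dictionary, synonyms).transform(capped)
    n_lines = sum(len(nl.lines) for nl in noun_lines)
    logger.info("stage=process query=%s noun_lines=%d", query.canonical_name, n_lines)

    net = CooccurrenceNetwork(k=k, ties=ties).fit(noun_lines)
    logger.info("stage=network query=%s distinct_pairs=%d edges=%d nodes=%d",
                query.canonical_name, len(net.pair_counts_),
                net.graph_.number_of_edges(), net.graph_.number_of_nodes())

    layout: Layout | None = None
    if net.graph_.number_of_nodes() > 0:
        params = layout_params if layout_params is not None else LayoutParams()
        layout = relax(net.graph_, params)
        if min_separation is not None:
            layout = reduce_overlap(layout, net.graph_, min_separation, seed=params.seed)
        logger.info("stage=layout query=%s iterations=%d residual=%.3g",
                    query.canonical_name, layout.iterations_used, layout.residual)
    else:
        logger.warning("stage=layout query=%s skipped (empty network)", query.canonical_name)

    cats = categories if categories is not None else load_default_categories()
    report = categorize_keywords(net.graph_, cats, disease=query.canonical_name)

    accounts_with_pairs = sum(1 for nl in noun_lines if any(len(set(l)) > 1 for l in nl.lines))
    counts = {
        "accounts_matched": len(matched),
        "accounts_with_pairs": accounts_with_pairs,
        "noun_lines": n_lines,
        "distinct_pairs": len(net.pair_counts_),
        "nodes": net.graph_.number_of_nodes(),
        "edges": net.graph_.number_of_edges(),
        "layout_iterations": layout.iterations_used if layout else 0,
        "layout_residual": layout.residual if layout else 0.0,
    }
    return QueryResult(query.canonical_name, net.graph_, layout, report, counts)


def _slug(name: str) -> str:
    return normalize(name).replace(" ", "_")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, QueryResult]:
    """Run every configured query and write exports plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    corpus = read_corpus(config.corpus)
    dictionary = TermDictionary.from_tsv(config.dictionary)
    synonyms = SynonymMap.from_tsv(config.synonyms)
    categories = (
        CategoryDictionary.from_tsv(config.categories)
        if config.categories is not None
        else load_default_categories()
    )
    layout_params = LayoutParams(**{"seed": config.seed, **config.layout})

    results: dict[str, QueryResult] = {}
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "k": config.k,
            "tweet_cap": config.tweet_cap,
            "ties": config.ties,
            "min_separation": config.min_separation,
            "layout": {k: v for k, v in sorted(vars(layout_params).items())},
        },
        "queries": {},
    }
    for name, query_path in config.queries.items():
        query = load_query_terms(query_path, canonical_name=name)
        result = run_query(
            corpus, query, dictionary, synonyms, categories,
            k=config.k, tweet_cap=config.tweet_cap, ties=config.ties,
            layout_params=layout_params, min_separation=config.min_separation,
        )
        sub = out_dir / _slug(name)
        sub.mkdir(parents=True, exist_ok=True)
        from .network import write_edge_list

        edges = [
            ((u, v) if u <= v else (v, u), d["account_count"])
            for u, v, d in result.graph.edges(data=True)
        ]
        edges.sort(key=lambda item: (-item[1], item[0]))
        write_edge_list(edges, sub / "edges.tsv")
        export_graphml(result.graph, result.layout, sub / "network.graphml")
        result.report.to_csv(sub / "categories.tsv", sep="\t", index=False)
        manifest["queries"][name] = result.counts
        results[name] = result

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, ensure_ascii=False, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return results
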