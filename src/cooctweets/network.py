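"""Account-level word co-occurrence counting and top-k network construction.

The co-occurrence weight of a word pair is deliberately the number of
*accounts* in which the two words appear together on at least one tweet
line — not the number of co-occurring lines.  Counting accounts instead of
occurrences keeps a single hyper-active user (or a highly specialized
recurring phrase) from dominating the network: an account contributes each
pair at most once, however often it repeats it.

The network keeps only the top-k pairs by account count (k=100 by default),
drawn as an undirected graph with words as nodes and pairs as weighted
links.
"""

from __future__ import annotations

import itertools
from collections import Counter
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
from sklearn.base import BaseEstimator

from .corpus import ValidationError
from .text import NounLines

__all__ = [
    "DEFAULT_TOP_K",
    "account_pair_set",
    "count_pair_accounts",
    "select_top_k",
    "build_graph",
    "CooccurrenceNetwork",
    "write_edge_list",
    "read_edge_list",
]

#: Number of most frequent pairs retained as network links by default.
DEFAULT_TOP_K = 100

Pair = tuple[str, str]


def account_pair_set(noun_lines: NounLines) -> set[Pair]:
    """All unordered pairs of distinct lemmas co-occurring on any line.

    Set semantics: an account contributes each pair at most once no matter
    how many of its lines repeat it.  A word repeated on one line forms no
    self-pair.  Pairs are stored sorted lexicographically.
    """
    pairs: set[Pair] = set()
    for line in noun_lines.lines:
        distinct = sorted(set(line))
        pairs.update(itertools.combinations(distinct, 2))
    return pairs


def count_pair_accounts(all_noun_lines: Sequence[NounLines]) -> dict[Pair, int]:
    """Number of accounts in which each pair co-occurs at least once.

    Pairs seen in no account are absent from the result.  Account ids must
    be distinct — each account is one counting unit.
    """
    seen: set[str] = set()
    counts: Counter[Pair] = Counter()
    for nl in all_noun_lines:
        if nl.account_id in seen:
            raise ValidationError(f"duplicate account_id: {nl.account_id!r}")
        seen.add(nl.account_id)
        counts.update(account_pair_set(nl))
    return dict(counts)


def select_top_k(
    counts: Mapping[Pair, int],
    k: int = DEFAULT_TOP_K,
    ties: Literal["cut", "include"] = "cut",
) -> list[tuple[Pair, int]]:
    """The k most frequent pairs, sorted by (count desc, pair lexicographic).

    With ``ties="cut"`` exactly ``min(k, len(counts))`` pairs are returned,
    a tie at the rank-k boundary being cut deterministically by the
    lexicographic order; ``ties="include"`` additionally keeps every pair
    tied with the k-th count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    if ties == "include" and len(ranked) > k:
        boundary = ranked[k - 1][1]
        cut = k
        while cut < len(ranked) and ranked[cut][1] == boundary:
            cut += 1
        return ranked[:cut]
    return ranked[:k]


def build_graph(edges: Sequence[tuple[Pair, int]], k: int = DEFAULT_TOP_K) -> nx.Graph:
    """Build the undirected weighted network from a selected edge list.

    Nodes are the words incident to a selected pair; edge attribute
    ``account_count`` carries the weight.  ``k`` is recorded in the graph
    metadata as the selection threshold used.
    """
    graph = nx.Graph(k=k)
    seen: set[Pair] = set()
    for (u, v), weight in edges:
        pair = (u, v) if u <= v else (v, u)
        if u == v:
            raise ValidationError(f"self-pair {u!r} is not a valid edge")
        if pair in seen:
            raise ValidationError(f"duplicate pair in edge list: {pair!r}")
        seen.add(pair)
        graph.add_edge(u, v, account_count=int(weight))
    return graph


class CooccurrenceNetwork(BaseEstimator):
    """Estimator computing the account-level co-occurrence network.

    Parameters
    ----------
    k : int, default=100
        Number of most frequent pairs kept as links.
    ties : {"cut", "include"}, default="cut"
        Boundary-tie policy at rank k.

    Attributes
    ----------
    pair_counts_ : dict[(str, str), int]
        Account count for every pair observed at least once.
    edges_ : list[((str, str), int)]
        The selected edge list, sorted by (count desc, pair).
    graph_ : networkx.Graph
        The weighted undirected network over the selected pairs.
    n_accounts_ : int
        Number of accounts counted.
    """

    def __init__(self, k: int = DEFAULT_TOP_K, ties: Literal["cut", "include"] = "cut"):
        self.k = k
        self.ties = ties

    def fit(self, X: Iterable[NounLines], y=None) -> "CooccurrenceNetwork":
        noun_lines = list(X)
        self.pair_counts_ = count_pair_accounts(noun_lines)
        self.edges_ = select_top_k(self.pair_counts_, k=self.k, ties=self.ties)
        self.graph_ = build_graph(self.edges_, k=self.k)
        self.graph_.graph["ties"] = self.ties
        self.n_accounts_ = len(noun_lines)
        return self

    def fit_transform(self, X: Iterable[NounLines], y=None) -> nx.Graph:
        return self.fit(X).graph_


# ---------------------------------------------------------------------------
# Edge-list I/O (TSV: word1 <TAB> word2 <TAB> account_count, selection order)
# ---------------------------------------------------------------------------

def write_edge_list(edges: Sequence[tuple[Pair, int]], path) -> None:
    from pathlib import Path

    lines = [f"{u}\t{v}\t{w}" for (u, v), w in edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_edge_list(path) -> list[tuple[Pair, int]]:
    from pathlib import Path

    edges: list[tuple[Pair, int]] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if raw.strip():
            u, v, w = raw.split("\t")
            edges.append(((u, v), int(w)))
    return edges
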