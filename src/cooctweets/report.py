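"""Keyword categorization and GraphML export.

The category report mirrors the way published keyword summaries are laid
out: each network keyword is assigned to one of four columns — Diagnosis,
Symptoms, Treatments, Others — from a dictionary of per-disease
assignments.  The shipped fixture encodes the published per-cancer
assignments (a matter of the original authors' judgment, hence data, not
code); a keyword may legitimately appear under more than one column (e.g.
a drug that is both a treatment and a source of symptoms).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .corpus import ValidationError, normalize
from .layout import Layout

__all__ = [
    "CATEGORY_ORDER",
    "CategoryDictionary",
    "load_default_categories",
    "categorize_keywords",
    "export_graphml",
    "import_graphml",
]

#: Report column order.
CATEGORY_ORDER = ("diagnosis", "symptoms", "treatments", "others")


class CategoryDictionary:
    """Per-disease keyword -> category assignments.

    Entries are keyed by (disease, lemma); a disease of ``"*"`` applies to
    every disease.  A lemma may carry several categories for one disease;
    :meth:`categories` returns all of them in report column order and
    :meth:`category` the first.
    """

    def __init__(self, rows: list[tuple[str, str, str]] | None = None):
        # (disease, lemma) -> list of categories in insertion order
        self._entries: dict[tuple[str, str], list[str]] = {}
        for disease, lemma, category in rows or []:
            self.add(disease, lemma, category)

    def add(self, disease: str, lemma: str, category: str) -> None:
        category = category.strip().lower()
        if category not in CATEGORY_ORDER:
            raise ValidationError(
                f"unknown category {category!r}; expected one of {CATEGORY_ORDER}"
            )
        key = (normalize(disease), normalize(lemma))
        cats = self._entries.setdefault(key, [])
        if category not in cats:
            cats.append(category)

    def categories(self, lemma: str, disease: str | None = None) -> list[str]:
        lemma = normalize(lemma)
        found: list[str] = []
        keys = []
        if disease is not None:
            keys.append((normalize(disease), lemma))
        keys.append(("*", lemma))
        if disease is None:
            keys.extend(k for k in self._entries if k[1] == lemma)
        for key in keys:
            for cat in self._entries.get(key, []):
                if cat not in found:
                    found.append(cat)
        return sorted(found, key=CATEGORY_ORDER.index)

    def category(self, lemma: str, disease: str | None = None) -> str:
        cats = self.categories(lemma, disease)
        return cats[0] if cats else "unclassified"

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryDictionary":
        """Load ``disease<TAB>keyword<TAB>category`` (UTF-8, ``#`` comments)."""
        rows: list[tuple[str, str, str]] = []
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{Path(path).name}: line {lineno}: expected 3 tab-separated fields"
                )
            rows.append((parts[0], parts[1], parts[2]))
        return cls(rows)


def load_default_categories() -> CategoryDictionary:
    """The packaged per-cancer keyword category fixture."""
    ref = importlib.resources.files("cooctweets") / "data" / "keyword_categories.tsv"
    with importlib.resources.as_file(ref) as path:
        return CategoryDictionary.from_tsv(path)


def categorize_keywords(
    graph: nx.Graph,
    categories: CategoryDictionary,
    disease: str | None = None,
) -> pd.DataFrame:
    """Assign every network keyword to its report column.

    Returns a DataFrame with columns ``keyword`` and ``category``, rows
    grouped by category in report column order (unclassified last) and
    alphabetical within a category.  A keyword listed under several columns
    is reported under each.
    """
    rows: list[tuple[str, str]] = []
    for node in graph.nodes:
        cats = categories.categories(str(node), disease)
        if not cats:
            rows.append((str(node), "unclassified"))
        else:
            rows.extend((str(node), c) for c in cats)
    order = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    rows.sort(key=lambda r: (order.get(r[1], len(order)), r[0]))
    return pd.DataFrame(rows, columns=["keyword", "category"])


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------

def export_graphml(graph: nx.Graph, layout: Layout | None, path: str | Path) -> None:
    """Write the network (with coordinates) as undirected GraphML.

    Edge attribute ``account_count`` is an integer; node attributes ``x``
    and ``y`` are decimals.  The writer output is deterministic for a given
    graph, so repeated exports of one run are byte-identical.
    """
    out = nx.Graph(**{k: v for k, v in graph.graph.items()})
    for node, data in graph.nodes(data=True):
        attrs = dict(data)
        if layout is not None:
            if node not in layout.positions:
                raise ValidationError(f"layout is missing node {node!r}")
            x, y = layout.positions[node]
            attrs["x"], attrs["y"] = float(x), float(y)
        out.add_node(node, **attrs)
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, account_count=int(data["account_count"]))
    nx.write_graphml(out, str(path), encoding="utf-8", prettyprint=True)


def import_graphml(path: str | Path) -> tuple[nx.Graph, Layout | None]:
    """Read a network written by :func:`export_graphml`.

    Returns the weighted graph (coordinates stripped from node data) and
    the embedded layout, or ``None`` when no coordinates are present.
    """
    raw = nx.read_graphml(str(path))
    graph = nx.Graph(**{k: v for k, v in raw.graph.items()})
    positions: dict[object, tuple[float, float]] = {}
    has_coords = True
    for node, data in raw.nodes(data=True):
        data = dict(data)
        if "x" in data and "y" in data:
            positions[node] = (float(data.pop("x")), float(data.pop("y")))
        else:
            has_coords = False
        graph.add_node(node, **data)
    for u, v, data in raw.edges(data=True):
        graph.add_edge(u, v, account_count=int(data["account_count"]))
    return graph, (Layout(positions) if has_coords and positions else None)
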