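"""Category reports, GraphML export, the pipeline driver, and the CLI."""

from __future__ import annotations

import json
import random

import networkx as nx
import pytest
from click.testing import CliRunner
from lxml import etree

from cooctweets.cli import main as cli_main
from cooctweets.corpus import ValidationError, write_corpus
from cooctweets.layout import Layout, LayoutParams
from cooctweets.network import CooccurrenceNetwork, build_graph
from cooctweets.pipeline import RunConfig, run_pipeline, run_query
from cooctweets.report import (
    CategoryDictionary,
    categorize_keywords,
    export_graphml,
    import_graphml,
    load_default_categories,
)
from cooctweets.simulate import generate_corpus
from cooctweets.text import NounLineTransformer

from conftest import make_noun_lines, two_topic_config


class TestCategoryDictionary:
    def test_spot_checks_against_published_assignments(self):
        cats = load_default_categories()
        assert cats.category("CT", "stomach cancer") == "diagnosis"
        assert cats.category("lymphedema", "breast cancer") == "symptoms"

    def test_dual_column_keyword_keeps_both(self):
        cats = load_default_categories()
        assert cats.categories("ts-1", "stomach cancer") == ["symptoms", "treatments"]

    def test_unknown_keyword_unclassified(self):
        cats = load_default_categories()
        assert cats.category("zzz", "stomach cancer") == "unclassified"

    def test_wildcard_disease_entries(self):
        cats = CategoryDictionary([("*", "ct", "diagnosis")])
        assert cats.category("ct", "anything") == "diagnosis"

    def test_invalid_category_rejected(self):
        with pytest.raises(ValidationError, match="category"):
            CategoryDictionary([("x", "ct", "imaging")])

    def test_report_grouped_in_column_order(self):
        g = build_graph([(("ct", "lumbago"), 3), (("lumbago", "ts-1"), 2)])
        report = categorize_keywords(g, load_default_categories(), "stomach cancer")
        assert list(report.columns) == ["keyword", "category"]
        cats = list(report["category"])
        order = ["diagnosis", "symptoms", "treatments", "others", "unclassified"]
        assert cats == sorted(cats, key=order.index)
        assert set(report[report.keyword == "ts-1"]["category"]) == {
            "symptoms", "treatments",
        }


class TestGraphML:
    def test_empty_graph_is_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_graphml(nx.Graph(), None, path)
        graph, layout = import_graphml(path)
        assert graph.number_of_nodes() == 0 and layout is None

    def test_round_trip_preserves_graph_and_layout(self, tmp_path):
        g = build_graph([(("a", "b"), 2), (("b", "c"), 7)])
        layout = Layout({"a": (0.0, 0.0), "b": (1.5, -0.25), "c": (0.5, 2.0)})
        path = tmp_path / "g.graphml"
        export_graphml(g, layout, path)
        g2, layout2 = import_graphml(path)
        assert set(g2.nodes) == set(g.nodes)
        assert {tuple(sorted(e)) for e in g2.edges} == {tuple(sorted(e)) for e in g.edges}
        for u, v, d in g.edges(data=True):
            assert g2.edges[u, v]["account_count"] == d["account_count"]
        assert layout2.positions == layout.positions

    def test_edge_element_count_matches_xml_oracle(self, tmp_path):
        rng = random.Random(8)
        edges, seen = [], set()
        while len(edges) < 100:
            pair = tuple(sorted(rng.sample([f"w{i}" for i in range(40)], 2)))
            if pair not in seen:
                seen.add(pair)
                edges.append((pair, rng.randint(1, 9)))
        g = build_graph(edges)
        path = tmp_path / "big.graphml"
        export_graphml(g, None, path)
        tree = etree.parse(str(path))
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        assert len(tree.findall(".//g:edge", ns)) == 100
        assert len(tree.findall(".//g:node", ns)) == g.number_of_nodes()

    def test_missing_layout_node_rejected(self, tmp_path):
        g = build_graph([(("a", "b"), 1)])
        with pytest.raises(ValidationError, match="missing"):
            export_graphml(g, Layout({"a": (0, 0)}), tmp_path / "x.graphml")


@pytest.fixture(scope="module")
def pipeline_setup(tmp_path_factory):
    """A small synthetic corpus with its resource files and run config."""
    root = tmp_path_factory.mktemp("pipeline")
    config = two_topic_config(accounts_per_topic=12, tweets_per_account=(5, 15))
    corpus = generate_corpus(config)
    write_corpus(corpus, root / "corpus.jsonl")
    config.term_dictionary().to_tsv(root / "terms.tsv")
    config.synonym_map().to_tsv(root / "synonyms.tsv")
    queries = {}
    for qts in config.query_term_sets():
        path = root / f"{qts.canonical_name.replace(' ', '_')}.txt"
        path.write_text("\n".join(qts.variants) + "\n", encoding="utf-8")
        queries[qts.canonical_name] = path
    run_config = {
        "corpus": "corpus.jsonl",
        "queries": {name: p.name for name, p in queries.items()},
        "dictionary": "terms.tsv",
        "synonyms": "synonyms.tsv",
        "k": 30,
        "tweet_cap": 200,
        "layout": {"max_iterations": 300},
        "seed": 9,
    }
    (root / "run.json").write_text(json.dumps(run_config), encoding="utf-8")
    return root, config


class TestPipeline:
    def test_run_twice_is_byte_identical(self, pipeline_setup):
        root, _ = pipeline_setup
        config = RunConfig.from_json(root / "run.json")
        run_pipeline(config, root / "out1")
        run_pipeline(config, root / "out2")
        for rel in [
            "manifest.json",
            "breast_cancer/edges.tsv",
            "breast_cancer/network.graphml",
            "breast_cancer/categories.tsv",
            "stomach_cancer/edges.tsv",
            "stomach_cancer/network.graphml",
        ]:
            assert (root / "out1" / rel).read_bytes() == (root / "out2" / rel).read_bytes(), rel

    def test_manifest_counts_are_consistent(self, pipeline_setup):
        root, config = pipeline_setup
        run_config = RunConfig.from_json(root / "run.json")
        run_pipeline(run_config, root / "out_manifest")
        manifest = json.loads((root / "out_manifest" / "manifest.json").read_text())
        assert manifest["seed"] == 9
        for name, c in manifest["queries"].items():
            assert c["accounts_matched"] == 12
            assert c["accounts_with_pairs"] <= c["accounts_matched"]
            assert c["edges"] <= run_config.k
            assert c["nodes"] <= 2 * c["edges"]

    def test_pipeline_equals_manual_composition(self, pipeline_setup):
        root, config = pipeline_setup
        run_config = RunConfig.from_json(root / "run.json")
        results = run_pipeline(run_config, root / "out_compose")
        from cooctweets.corpus import cap_latest_tweets, read_corpus, search_profiles

        corpus = read_corpus(root / "corpus.jsonl")
        query = config.query_term_sets()[0]
        matched = search_profiles(corpus, query)
        capped = [cap_latest_tweets(a, 200) for a in matched]
        noun_lines = NounLineTransformer(
            config.term_dictionary(), config.synonym_map()
        ).transform(capped)
        net = CooccurrenceNetwork(k=30).fit(noun_lines)
        got = results[query.canonical_name].graph
        assert set(got.edges) == set(net.graph_.edges)
        for u, v, d in net.graph_.edges(data=True):
            assert got.edges[u, v]["account_count"] == d["account_count"]

    def test_no_matching_profiles_is_an_empty_success(self, pipeline_setup, tmp_path):
        root, _ = pipeline_setup
        (root / "nomatch.txt").write_text("no such disease\n", encoding="utf-8")
        obj = json.loads((root / "run.json").read_text())
        obj["queries"] = {"no match": "nomatch.txt"}
        (root / "run_nomatch.json").write_text(json.dumps(obj), encoding="utf-8")
        results = run_pipeline(RunConfig.from_json(root / "run_nomatch.json"), tmp_path / "out")
        result = results["no match"]
        assert result.graph.number_of_edges() == 0
        assert result.layout is None
        assert result.counts["accounts_matched"] == 0


class TestCli:
    def test_stagewise_commands_compose(self, tmp_path, small_config):
        runner = CliRunner()
        cfg_path = tmp_path / "gen.json"
        small_config.to_json(cfg_path)

        r = runner.invoke(cli_main, [
            "simulate", "--config", str(cfg_path), "--out", str(tmp_path / "c.jsonl"),
            "--emit-resources", str(tmp_path / "res"),
        ])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "search", "--corpus", str(tmp_path / "c.jsonl"),
            "--terms", str(tmp_path / "res" / "queries" / "breast_cancer.txt"),
            "--out", str(tmp_path / "matched.jsonl"),
        ])
        assert r.exit_code == 0, r.output
        assert "8/16 accounts matched" in r.output

        r = runner.invoke(cli_main, [
            "process", "--corpus", str(tmp_path / "matched.jsonl"),
            "--dictionary", str(tmp_path / "res" / "terms.tsv"),
            "--synonyms", str(tmp_path / "res" / "synonyms.tsv"),
            "--out", str(tmp_path / "nl.jsonl"),
        ])
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, [
            "network", "--noun-lines", str(tmp_path / "nl.jsonl"),
            "--k", "20", "--out", str(tmp_path / "edges.tsv"),
        ])
        assert r.exit_code == 0, r.output
        assert "kept 20 edges" in r.output

        r = runner.invoke(cli_main, [
            "layout", "--edges", str(tmp_path / "edges.tsv"),
            "--seed", "1", "--out", str(tmp_path / "net.graphml"),
        ])
        assert r.exit_code == 0, r.output
        graph, layout = import_graphml(tmp_path / "net.graphml")
        assert graph.number_of_edges() == 20
        assert layout is not None

    def test_run_command_writes_manifest(self, pipeline_setup, tmp_path):
        root, _ = pipeline_setup
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "run", "--config", str(root / "run.json"), "--out-dir", str(tmp_path / "out"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "manifest.json").exists()
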