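"""Terminology-file readers, graph construction and subgraph induction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from graphsts.errors import RecordFormatError
from graphsts.terminology import (ConceptColumns, RelationColumns,
                                  build_graph, induce_sentence_graph,
                                  read_concept_file, read_induced_graph,
                                  read_relation_file,
                                  read_terminology_graph,
                                  write_induced_graph,
                                  write_terminology_graph)
from conftest import make_term_graph, random_connected_graph

# miniature RRF dialect: cui|_|_|_|_|_|_|_|_|_|_|source|_|_|name|...
def _conso_row(cui, source, name):
    fields = [""] * 18
    fields[0], fields[11], fields[14] = cui, source, name
    return "|".join(fields)


def _rel_row(c1, c2, rel="RO"):
    fields = [""] * 16
    fields[0], fields[3], fields[4] = c1, rel, c2
    return "|".join(fields)


class TestReadConceptFile:
    def test_source_filter_keeps_file_order(self, tmp_path):
        p = tmp_path / "conso.rrf"
        p.write_text("\n".join([
            _conso_row("C1", "SNOMEDCT_US", "alpha"),
            _conso_row("C2", "OTHER", "beta"),
            _conso_row("C3", "SNOMEDCT_US", "gamma"),
        ]) + "\n")
        entries = read_concept_file(p, "SNOMEDCT_US")
        assert [(e.cui, e.preferred_name) for e in entries] == \
            [("C1", "alpha"), ("C3", "gamma")]

    def test_duplicate_cui_first_occurrence_wins(self, tmp_path):
        p = tmp_path / "conso.rrf"
        rows = [_conso_row("C1", "SNOMEDCT_US", "first"),
                _conso_row("C2", "OTHER", "skip"),
                _conso_row("C1", "SNOMEDCT_US", "second")]
        p.write_text("\n".join(rows) + "\n")
        # independent brute-force scan of the same fixture
        expected = {}
        for row in rows:
            cols = row.split("|")
            if cols[11] == "SNOMEDCT_US" and cols[0] not in expected:
                expected[cols[0]] = cols[14]
        entries = read_concept_file(p, "SNOMEDCT_US")
        assert {e.cui: e.preferred_name for e in entries} == expected
        assert len(entries) == 1

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "conso.rrf"
        p.write_text("")
        assert read_concept_file(p, "SNOMEDCT_US") == []

    def test_short_row_raises_with_line_number(self, tmp_path):
        p = tmp_path / "conso.rrf"
        p.write_text(_conso_row("C1", "S", "x") + "\nC2|too|short\n")
        with pytest.raises(RecordFormatError, match=":2:"):
            read_concept_file(p, "S")

    def test_unreadable_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_concept_file(tmp_path / "absent.rrf", "S")

    def test_custom_column_map(self, tmp_path):
        p = tmp_path / "mini.psv"
        p.write_text("C9|myname|SRC|T1;T2\n")
        cols = ConceptColumns(cui=0, name=1, source=2, semtypes=3)
        (entry,) = read_concept_file(p, "SRC", columns=cols)
        assert entry.preferred_name == "myname"
        assert entry.semantic_types == ("T1", "T2")


class TestReadRelationFile:
    def test_self_loop_and_out_of_set_filtering(self, tmp_path):
        p = tmp_path / "rel.rrf"
        p.write_text("\n".join([_rel_row("A", "B"), _rel_row("B", "B"),
                                _rel_row("A", "Z")]) + "\n")
        entries = read_relation_file(p, {"A", "B"})
        assert [(e.cui1, e.cui2) for e in entries] == [("A", "B")]

    def test_reciprocal_rows_both_returned(self, tmp_path):
        p = tmp_path / "rel.rrf"
        p.write_text(_rel_row("A", "B") + "\n" + _rel_row("B", "A") + "\n")
        assert len(read_relation_file(p, {"A", "B"})) == 2

    def test_empty_file(self, tmp_path):
        p = tmp_path / "rel.rrf"
        p.write_text("")
        assert read_relation_file(p, {"A"}) == []

    def test_custom_columns_and_label_retained(self, tmp_path):
        p = tmp_path / "rel.psv"
        p.write_text("A|isa|B\n")
        (entry,) = read_relation_file(
            p, {"A", "B"}, columns=RelationColumns(cui1=0, rel=1, cui2=2))
        assert entry.rel_label == "isa"


class TestBuildGraph:
    def test_reciprocal_and_duplicate_rows_collapse(self):
        tg = make_term_graph([("A", "B"), ("B", "A"), ("A", "B")],
                             extra_nodes=["C"])
        assert tg.graph.number_of_nodes() == 3
        assert tg.graph.number_of_edges() == 1

    def test_no_relations_gives_edgeless_graph(self):
        tg = make_term_graph([], extra_nodes=["A", "B", "C"])
        assert tg.graph.number_of_edges() == 0
        assert set(tg.graph.nodes) == {"A", "B", "C"}

    def test_random_rows_match_pair_normalization_oracle(self):
        rng = np.random.default_rng(5)
        names = [f"C{i}" for i in range(15)]
        raw_pairs = [(names[int(a)], names[int(b)])
                     for a, b in rng.integers(0, 15, size=(30, 2))]
        tg = make_term_graph(raw_pairs, extra_nodes=names)
        oracle = {tuple(sorted(p)) for p in raw_pairs if p[0] != p[1]}
        assert {tuple(sorted(e)) for e in tg.graph.edges} == oracle

    def test_unknown_endpoint_skipped_not_fatal(self, caplog):
        from graphsts.terminology import (ConceptEntry, RelationEntry,
                                          build_graph)
        concepts = [ConceptEntry("A", "a", "S"), ConceptEntry("B", "b", "S")]
        relations = [RelationEntry("A", "B"), RelationEntry("A", "MISSING")]
        with caplog.at_level("WARNING"):
            tg = build_graph(concepts, relations)
        assert tg.graph.number_of_edges() == 1
        assert "MISSING" in caplog.text


class TestInduceSentenceGraph:
    def test_empty_seed_list(self, path_graph):
        induced = induce_sentence_graph(path_graph, [])
        assert induced.n_nodes == 0
        assert induced.adjacency.shape == (0, 0)

    def test_path_endpoints_pull_in_whole_path(self, path_graph):
        induced = induce_sentence_graph(path_graph, ["A", "E"])
        assert induced.node_ids == ["A", "B", "C", "D", "E"]
        assert induced.adjacency.sum() == 2 * 4  # 4 undirected edges

    def test_star_leaves_route_through_hub(self, star_graph):
        induced = induce_sentence_graph(star_graph, ["L1", "L2"])
        assert induced.node_ids == ["H", "L1", "L2"]
        assert induced.adjacency.sum() == 2 * 2

    def test_disconnected_seeds_stay_isolated(self):
        tg = make_term_graph([("A", "B"), ("X", "Y")])
        induced = induce_sentence_graph(tg, ["A", "X"])
        assert induced.node_ids == ["A", "X"]
        assert induced.adjacency.sum() == 0

    def test_seeds_missing_from_graph_dropped(self, path_graph, caplog):
        with caplog.at_level("WARNING"):
            induced = induce_sentence_graph(path_graph, ["A", "NOPE", "C"])
        assert induced.seed_ids == ["A", "C"]
        assert "NOPE" in caplog.text

    def test_duplicate_seeds_collapse(self, path_graph):
        once = induce_sentence_graph(path_graph, ["A", "C"])
        twice = induce_sentence_graph(path_graph, ["A", "C", "A", "C"])
        assert once == twice

    def test_idempotent_on_own_seed_set(self, path_graph):
        first = induce_sentence_graph(path_graph, ["A", "E"])
        again = induce_sentence_graph(path_graph, first.seed_ids)
        assert first == again

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(11)
        tg = random_connected_graph(rng, 18, 8)
        seeds = ["N02", "N07", "N11", "N16"]
        a = induce_sentence_graph(tg, seeds)
        b = induce_sentence_graph(tg, seeds)
        assert a == b and a.node_ids == b.node_ids


def _oracle_induced_nodes_and_edges(g: nx.Graph, seeds):
    """Independent oracle: enumerate ALL shortest paths per seed pair with
    networkx and take the lexicographically smallest sequence."""
    nodes, edges = set(seeds), set()
    for s, t in itertools.combinations(sorted(seeds), 2):
        if not nx.has_path(g, s, t):
            continue
        best = min(nx.all_shortest_paths(g, s, t))
        nodes.update(best)
        edges.update((min(a, b), max(a, b))
                     for a, b in zip(best, best[1:]))
    return nodes, edges


class TestInductionProperties:
    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for trial in range(60):
            n = int(rng.integers(4, 21))
            tg = random_connected_graph(rng, n, int(rng.integers(0, n)))
            all_nodes = sorted(tg.graph.nodes)
            k = int(rng.integers(2, 6))
            seeds = list(rng.choice(all_nodes, size=min(k, n),
                                    replace=False))
            induced = induce_sentence_graph(tg, seeds)
            nodes, edges = _oracle_induced_nodes_and_edges(tg.graph,
                                                           set(seeds))
            assert set(induced.node_ids) == nodes, f"trial {trial}"
            got_edges = {
                (induced.node_ids[i], induced.node_ids[j])
                for i in range(induced.n_nodes)
                for j in range(i + 1, induced.n_nodes)
                if induced.adjacency[i, j]}
            assert got_edges == edges, f"trial {trial}"

    def test_seed_distances_preserved_in_induced_graph(self):
        rng = np.random.default_rng(321)
        for _ in range(40):
            n = int(rng.integers(4, 21))
            tg = random_connected_graph(rng, n, int(rng.integers(0, n)))
            seeds = list(rng.choice(sorted(tg.graph.nodes),
                                    size=min(4, n), replace=False))
            induced = induce_sentence_graph(tg, seeds)
            sub = nx.from_numpy_array(induced.adjacency)
            relabel = {i: cui for i, cui in enumerate(induced.node_ids)}
            sub = nx.relabel_nodes(sub, relabel)
            for s, t in itertools.combinations(sorted(set(seeds)), 2):
                full_d = nx.shortest_path_length(tg.graph, s, t)
                assert nx.shortest_path_length(sub, s, t) == full_d


class TestSerialization:
    def test_induced_graph_round_trip(self, path_graph, tmp_path):
        induced = induce_sentence_graph(path_graph, ["A", "D"])
        write_induced_graph(induced, tmp_path / "g")
        assert read_induced_graph(tmp_path / "g") == induced

    def test_terminology_graph_round_trip(self, tmp_path):
        tg = make_term_graph([("A", "B"), ("B", "C")], extra_nodes=["Z"])
        write_terminology_graph(tg, tmp_path / "t")
        back = read_terminology_graph(tmp_path / "t")
        assert set(back.graph.nodes) == set(tg.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == \
            set(map(frozenset, tg.graph.edges))
        assert back.name_index["A"].preferred_name == "name A"
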