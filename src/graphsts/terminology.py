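"""Terminology graph construction and per-sentence subgraph induction.

A clinical terminology (concept names in an MRCONSO-style file, pairwise
relations in an MRREL-style file) is loaded into an undirected, unweighted
concept graph: relation types carry semantics we deliberately ignore, keeping
only connectivity.  For a sentence whose tagged concepts are a set of CUIs
(concept unique identifiers), the sentence's concept graph is the union of
one shortest path per unordered pair of tagged concepts; among equal-length
paths the lexicographically smallest CUI sequence is chosen, so induction
is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import RecordFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ConceptEntry", "RelationEntry", "TerminologyGraph", "InducedGraph",
    "ConceptColumns", "RelationColumns",
    "read_concept_file", "read_relation_file", "build_graph",
    "induce_sentence_graph", "write_induced_graph", "read_induced_graph",
    "write_terminology_graph", "read_terminology_graph",
]


@dataclass(frozen=True)
class ConceptEntry:
    """One concept row: identifier, preferred name, source vocabulary tag."""
    cui: str
    preferred_name: str
    source_vocab: str
    semantic_types: tuple[str, ...] = ()


@dataclass(frozen=True)
class RelationEntry:
    """One relation row; the label is kept but never affects topology."""
    cui1: str
    cui2: str
    rel_label: str = ""


@dataclass
class ConceptColumns:
    """Column positions in a pipe-delimited concept file.

    Defaults follow the standard MRCONSO layout (CUI in column 0, source
    vocabulary abbreviation in column 11, name string in column 14).  A
    semantic-type column is not part of MRCONSO; ``semtypes`` may point at
    an extra column holding semicolon-joined type names in miniature
    dialects, and is ignored when None.
    """
    cui: int = 0
    source: int = 11
    name: int = 14
    semtypes: int | None = None

    def max_index(self) -> int:
        cols = [self.cui, self.source, self.name]
        if self.semtypes is not None:
            cols.append(self.semtypes)
        return max(cols)


@dataclass
class RelationColumns:
    """Column positions in a pipe-delimited relation file (MRREL layout:
    CUI1 in column 0, relation label in column 3, CUI2 in column 4)."""
    cui1: int = 0
    cui2: int = 4
    rel: int = 3

    def max_index(self) -> int:
        return max(self.cui1, self.cui2, self.rel)


@dataclass
class TerminologyGraph:
    """Undirected unweighted concept graph plus a CUI -> entry index."""
    graph: nx.Graph
    name_index: dict[str, ConceptEntry]

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def __contains__(self, cui: str) -> bool:
        return cui in self.graph


@dataclass
class InducedGraph:
    """Union-of-shortest-paths subgraph for one sentence.

    ``node_ids`` is lexicographically sorted; ``adjacency`` is the binary
    symmetric matrix over that ordering; ``seed_ids`` are the tagged
    concepts retained (present in the terminology graph).
    """
    node_ids: list[str] = field(default_factory=list)
    adjacency: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 0), dtype=np.int8))
    seed_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def __eq__(self, other):
        return (isinstance(other, InducedGraph)
                and self.node_ids == other.node_ids
                and self.seed_ids == other.seed_ids
                and np.array_equal(self.adjacency, other.adjacency))


def _split_row(line: str, path, line_no: int, max_index: int) -> list[str]:
    fields = line.rstrip("\n").split("|")
    if len(fields) <= max_index:
        raise RecordFormatError(
            path, line_no,
            f"expected at least {max_index + 1} pipe-delimited columns, "
            f"got {len(fields)}")
    return fields


def read_concept_file(path, source_filter: str,
                      columns: ConceptColumns | None = None
                      ) -> list[ConceptEntry]:
    """Read concept rows, keeping the first row per CUI whose source
    vocabulary equals ``source_filter``; file order is preserved."""
    columns = columns or ConceptColumns()
    entries: list[ConceptEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_row(line, path, line_no, columns.max_index())
            if fields[columns.source] != source_filter:
                continue
            cui = fields[columns.cui]
            if not cui or cui in seen:
                continue
            seen.add(cui)
            semtypes: tuple[str, ...] = ()
            if columns.semtypes is not None and fields[columns.semtypes]:
                semtypes = tuple(fields[columns.semtypes].split(";"))
            entries.append(ConceptEntry(
                cui=cui,
                preferred_name=fields[columns.name],
                source_vocab=fields[columns.source],
                semantic_types=semtypes))
    return entries


def read_relation_file(path, concept_ids: set[str],
                       columns: RelationColumns | None = None
                       ) -> list[RelationEntry]:
    """Read relation rows whose endpoints both lie in ``concept_ids``,
    dropping self-loops.  Duplicates and reciprocal rows are NOT collapsed
    here; :func:`build_graph` does that."""
    columns = columns or RelationColumns()
    entries: list[RelationEntry] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_row(line, path, line_no, columns.max_index())
            c1, c2 = fields[columns.cui1], fields[columns.cui2]
            if c1 == c2 or c1 not in concept_ids or c2 not in concept_ids:
                continue
            entries.append(RelationEntry(c1, c2, fields[columns.rel]))
    return entries


def build_graph(concepts: list[ConceptEntry],
                relations: list[RelationEntry]) -> TerminologyGraph:
    """All concepts become nodes; each relation contributes one undirected
    edge (reciprocal and duplicate rows collapse).  Relations with an
    endpoint not among the concepts are skipped with a warning."""
    g = nx.Graph()
    index: dict[str, ConceptEntry] = {}
    for entry in concepts:
        if entry.cui not in index:
            index[entry.cui] = entry
            g.add_node(entry.cui)
    for rel in relations:
        if rel.cui1 not in index or rel.cui2 not in index:
            logger.warning("relation (%s, %s) skipped: endpoint not among "
                           "concepts", rel.cui1, rel.cui2)
            continue
        if rel.cui1 != rel.cui2:
            g.add_edge(rel.cui1, rel.cui2)
    return TerminologyGraph(graph=g, name_index=index)


def _lex_shortest_path(g: nx.Graph, source: str, target: str,
                       dist_to_target: dict[str, int] | None = None
                       ) -> list[str] | None:
    """The lexicographically smallest shortest path from source to target
    (as a CUI sequence), or None if they are disconnected.

    Breadth-first distances to the target orient a greedy forward walk: at
    every step the smallest neighbor one step closer to the target is taken,
    which yields exactly the minimum of all shortest paths under sequence
    comparison — a tie-break that is deterministic by construction.
    """
    if source == target:
        return [source]
    if dist_to_target is None:
        dist_to_target = nx.single_source_shortest_path_length(g, target)
    if source not in dist_to_target:
        return None
    path = [source]
    current = source
    while current != target:
        current = min(v for v in g.neighbors(current)
                      if dist_to_target.get(v, -1)
                      == dist_to_target[current] - 1)
        path.append(current)
    return path


def induce_sentence_graph(term_graph: TerminologyGraph,
                          seeds: list[str]) -> InducedGraph:
    """Union of one shortest path per unordered pair of seed concepts.

    Seeds absent from the terminology graph are dropped (logged).  Seed
    pairs in different components contribute nothing, so a seed disconnected
    from every other seed appears as an isolated node.  Duplicate seeds
    collapse (set semantics).
    """
    g = term_graph.graph
    retained = sorted({s for s in seeds if s in g})
    dropped = sorted({s for s in seeds if s not in g})
    if dropped:
        logger.warning("seeds not in terminology graph dropped: %s",
                       ",".join(dropped))
    node_set: set[str] = set(retained)
    edge_set: set[tuple[str, str]] = set()
    dist_maps: dict[str, dict[str, int]] = {}
    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            target = retained[j]
            if target not in dist_maps:
                dist_maps[target] = nx.single_source_shortest_path_length(
                    g, target)
            path = _lex_shortest_path(g, retained[i], target,
                                      dist_maps[target])
            if path is None:
                continue
            node_set.update(path)
            for a, b in zip(path, path[1:]):
                edge_set.add((min(a, b), max(a, b)))
    node_ids = sorted(node_set)
    pos = {cui: k for k, cui in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=np.int8)
    for a, b in edge_set:
        adj[pos[a], pos[b]] = 1
        adj[pos[b], pos[a]] = 1
    return InducedGraph(node_ids=node_ids, adjacency=adj, seed_ids=retained)


# -- plain-text serialization -------------------------------------------


def write_induced_graph(graph: InducedGraph, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` ("cui TAB is_seed") and
    ``<prefix>.edges.tsv`` ("cui1 TAB cui2")."""
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    seeds = set(graph.seed_ids)
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for cui in graph.node_ids:
            fh.write(f"{cui}\t{1 if cui in seeds else 0}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        n = graph.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if graph.adjacency[i, j]:
                    fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\n")
    return nodes_path, edges_path


def read_induced_graph(prefix) -> InducedGraph:
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    node_ids: list[str] = []
    seed_ids: list[str] = []
    with open(nodes_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise RecordFormatError(nodes_path, line_no,
                                        "expected 'cui TAB is_seed'")
            node_ids.append(parts[0])
            if parts[1] == "1":
                seed_ids.append(parts[0])
    pos = {cui: k for k, cui in enumerate(node_ids)}
    adj = np.zeros((len(node_ids), len(node_ids)), dtype=np.int8)
    with open(edges_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[0] not in pos or parts[1] not in pos:
                raise RecordFormatError(edges_path, line_no,
                                        "expected 'cui1 TAB cui2' over "
                                        "manifest nodes")
            adj[pos[parts[0]], pos[parts[1]]] = 1
            adj[pos[parts[1]], pos[parts[0]]] = 1
    return InducedGraph(node_ids=node_ids, adjacency=adj, seed_ids=seed_ids)


def write_terminology_graph(term_graph: TerminologyGraph, prefix
                            ) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` ("cui TAB name TAB source TAB
    semtype[;semtype...]") and ``<prefix>.edges.tsv`` ("cui1 TAB cui2")."""
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for cui in sorted(term_graph.graph.nodes):
            e = term_graph.name_index[cui]
            fh.write(f"{cui}\t{e.preferred_name}\t{e.source_vocab}\t"
                     f"{';'.join(e.semantic_types)}\n")
    with open(edges_path, "w", encoding="utf-8") as fh:
        for a, b in sorted((min(u, v), max(u, v))
                           for u, v in term_graph.graph.edges):
            fh.write(f"{a}\t{b}\n")
    return nodes_path, edges_path


def read_terminology_graph(prefix) -> TerminologyGraph:
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    concepts: list[ConceptEntry] = []
    with open(nodes_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise RecordFormatError(nodes_path, line_no,
                                        "expected 4 tab-separated columns")
            semtypes = tuple(parts[3].split(";")) if parts[3] else ()
            concepts.append(ConceptEntry(parts[0], parts[1], parts[2],
                                         semtypes))
    relations: list[RelationEntry] = []
    with open(edges_path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise RecordFormatError(edges_path, line_no,
                                        "expected 'cui1 TAB cui2'")
            relations.append(RelationEntry(parts[0], parts[1]))
    return build_graph(concepts, relations)
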