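import networkx as nx
import numpy as np
import pytest

from graphsts.tagging import LexiconEntry, build_lexicon
from graphsts.terminology import (ConceptEntry, RelationEntry, build_graph,
                                  TerminologyGraph)


def make_term_graph(edges, extra_nodes=()) -> TerminologyGraph:
    """Terminology graph over string node names with placeholder entries."""
    nodes = sorted({u for e in edges for u in e} | set(extra_nodes))
    concepts = [ConceptEntry(cui=n, preferred_name=f"name {n}",
                             source_vocab="TEST") for n in nodes]
    relations = [RelationEntry(a, b) for a, b in edges]
    return build_graph(concepts, relations)


@pytest.fixture
def path_graph():
    """A — B — C — D — E."""
    return make_term_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def star_graph():
    """Hub H with leaves L1..L4."""
    return make_term_graph([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def clinical_lexicon():
    """Two-surface lexicon around the post-anesthesia care unit example."""
    return build_lexicon([
        LexiconEntry(surface="pacu", cui="C0085556",
                     preferred_name="postoperative anesthesia care unit "
                                    "(PACU)",
                     semantic_types=("Health Care Related Organization",)),
        LexiconEntry(surface="stable condition", cui="C0677946",
                     preferred_name="condition stable",
                     semantic_types=("Finding",)),
    ])


def random_connected_graph(rng: np.random.Generator, n: int,
                           extra_edges: int) -> TerminologyGraph:
    """Random tree plus extra edges over nodes N00..N{n-1}, connected."""
    names = [f"N{i:02d}" for i in range(n)]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((names[i], names[j]))
    for _ in range(extra_edges):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.append((names[int(i)], names[int(j)]))
    return make_term_graph(edges, extra_nodes=names)


def to_networkx(term_graph: TerminologyGraph) -> nx.Graph:
    return term_graph.graph
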