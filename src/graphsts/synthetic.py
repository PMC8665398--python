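"""Self-contained synthetic benchmark for the whole pipeline.

Real clinical sentence-similarity corpora and the terminologies behind them
are license-restricted, so the package generates a statistical stand-in with
the same moving parts: a connected random ontology serialized in the
pipe-delimited terminology dialect, a surface-form lexicon in which several
distinct tokens name the same concept (synonyms), a concept-embedding file
derived from a spectral layout of the ontology (so nearby concepts receive
similar vectors), and a corpus of scored sentence pairs.

The gold score of a pair is a noisy readout of a latent similarity

    latent = w_lex * J + w_graph * G,

where J is the Jaccard overlap of the two sentences' concept-surface token
multisets and G is the mean over cross-sentence concept pairs of the
proximity kernel 1/(1 + d), with d the shortest-path distance in the
ontology.  Because synonym surfaces are distinct tokens mapped to one
concept, and because G rewards concepts that are near each other without
sharing any token, a large w_graph plants a signal that text alone cannot
fully recover — recovering it requires the terminology graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ConfigurationError
from .graph_encoder import EmbeddingTable, write_embedding_file
from .tagging import LexiconEntry, write_lexicon_file

__all__ = [
    "SyntheticConfig", "SyntheticCorpus", "Ontology",
    "generate_ontology", "generate_lexicon", "generate_embeddings",
    "generate_pairs", "generate_corpus", "latent_similarity",
    "write_rrf_files",
]

SOURCE_TAG = "SYNTHCT"
SEMANTIC_TYPES = ("Clinical Finding", "Procedure", "Body Structure",
                  "Pharmacologic Substance")
CATEGORY_CYCLE = ("status", "education", "meds", "miscellaneous")


@dataclass
class SyntheticConfig:
    n_concepts: int = 200
    extra_edge_fraction: float = 0.3
    n_surface_forms: int = 2
    n_filler_tokens: int = 40
    n_pairs: int = 2000
    concepts_per_sentence: tuple[int, int] = (2, 4)
    w_lex: float = 0.3
    w_graph: float = 0.7
    noise_sigma: float = 0.3
    embedding_dim: int = 16
    seed: int = 0

    def __post_init__(self):
        for name in ("n_concepts", "n_surface_forms", "n_filler_tokens",
                     "n_pairs", "embedding_dim"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if abs(self.w_lex + self.w_graph - 1.0) > 1e-9:
            raise ConfigurationError("w_lex + w_graph must equal 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        lo, hi = self.concepts_per_sentence
        if not 1 <= lo <= hi:
            raise ConfigurationError("invalid concepts_per_sentence range")


@dataclass
class Ontology:
    cuis: list[str]
    graph: nx.Graph
    preferred_names: dict[str, str]
    semantic_types: dict[str, str]


@dataclass
class SyntheticCorpus:
    concepts_path: Path
    relations_path: Path
    lexicon_path: Path
    embeddings_path: Path
    dataset_path: Path
    manifest_path: Path
    ontology: Ontology = None
    lexicon: list[LexiconEntry] = field(default_factory=list)


def _cui(i: int) -> str:
    return f"C{i:07d}"


def generate_ontology(config: SyntheticConfig) -> Ontology:
    """Uniform random spanning tree (Prüfer decoding) over the concepts,
    plus ``round(extra_edge_fraction * n)`` random extra edges — connected
    by construction."""
    rng = np.random.default_rng((config.seed, 1))
    n = config.n_concepts
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if n == 2:
        g.add_edge(0, 1)
    elif n > 2:
        prufer = rng.integers(0, n, size=n - 2).tolist()
        g.add_edges_from(nx.from_prufer_sequence(prufer).edges)
    n_extra = round(config.extra_edge_fraction * n)
    added = 0
    while added < n_extra and g.number_of_edges() < n * (n - 1) // 2:
        u, v = rng.integers(0, n, size=2)
        if u != v and not g.has_edge(u, v):
            g.add_edge(int(u), int(v))
            added += 1
    cuis = [_cui(i) for i in range(n)]
    relabeled = nx.relabel_nodes(g, {i: cuis[i] for i in range(n)})
    names = {cui: f"{cui.lower()} canonical form" for cui in cuis}
    semtypes = {cui: SEMANTIC_TYPES[i % len(SEMANTIC_TYPES)]
                for i, cui in enumerate(cuis)}
    return Ontology(cuis=cuis, graph=relabeled, preferred_names=names,
                    semantic_types=semtypes)


def write_rrf_files(ontology: Ontology, concepts_path, relations_path):
    """Serialize in the standard pipe-delimited layout (concept identifier
    in column 0, source tag in column 11, name string in column 14;
    relation endpoints in columns 0 and 4)."""
    with open(concepts_path, "w", encoding="utf-8") as fh:
        for cui in ontology.cuis:
            fields = [""] * 18
            fields[0] = cui
            fields[11] = SOURCE_TAG
            fields[14] = ontology.preferred_names[cui]
            fh.write("|".join(fields) + "\n")
    with open(relations_path, "w", encoding="utf-8") as fh:
        for a, b in sorted((min(u, v), max(u, v))
                           for u, v in ontology.graph.edges):
            fields = [""] * 16
            fields[0] = a
            fields[3] = "RO"
            fields[4] = b
            fh.write("|".join(fields) + "\n")


def generate_lexicon(config: SyntheticConfig,
                     ontology: Ontology) -> list[LexiconEntry]:
    """``n_surface_forms`` distinct single-token surfaces per concept; all
    surfaces of a concept share its identifier, so a text-only model sees
    unrelated tokens where the graph sees one node."""
    entries = []
    for i, cui in enumerate(ontology.cuis):
        for j in range(config.n_surface_forms):
            entries.append(LexiconEntry(
                surface=f"c{i:04d}s{j}", cui=cui,
                preferred_name=ontology.preferred_names[cui],
                semantic_types=(ontology.semantic_types[cui],)))
    return entries


def generate_embeddings(config: SyntheticConfig,
                        ontology: Ontology) -> EmbeddingTable:
    """Spectral layout of the ontology: the eigenvectors of the symmetric
    normalized Laplacian for the smallest nonzero eigenvalues, sign-fixed
    and scaled, so graph-proximal concepts get nearby vectors."""
    n = len(ontology.cuis)
    k = config.embedding_dim
    a = nx.to_numpy_array(ontology.graph, nodelist=ontology.cuis)
    deg = a.sum(axis=1)
    d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-12)), 0)
    lap = np.eye(n) - a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(lap)
    coords = np.zeros((n, k))
    take = min(k, n - 1)
    for j in range(take):
        v = eigvecs[:, j + 1]  # skip the trivial constant eigenvector
        pivot = int(np.argmax(np.abs(v)))
        if v[pivot] < 0:
            v = -v
        coords[:, j] = v * np.sqrt(n)
    vectors = {cui: coords[i].copy() for i, cui in enumerate(ontology.cuis)}
    return EmbeddingTable(dim=k, vectors=vectors)


def latent_similarity(surfaces1: list[str], surfaces2: list[str],
                      concepts1: list[str], concepts2: list[str],
                      distances: dict[str, dict[str, int]],
                      w_lex: float, w_graph: float) -> tuple[float, float,
                                                             float]:
    """Return (latent, J, G) for one pair.

    J is the multiset Jaccard overlap of the concept-surface tokens; G is
    the mean over cross-sentence concept pairs of 1/(1 + d), with d the
    shortest-path distance (disconnected pairs contribute 0).
    """
    from collections import Counter
    c1, c2 = Counter(surfaces1), Counter(surfaces2)
    inter = sum((c1 & c2).values())
    union = sum((c1 | c2).values())
    j = inter / union if union else 0.0
    kernel_sum, count = 0.0, 0
    for a in concepts1:
        for b in concepts2:
            count += 1
            d = distances.get(a, {}).get(b)
            if d is not None:
                kernel_sum += 1.0 / (1.0 + d)
    g = kernel_sum / count if count else 0.0
    return w_lex * j + w_graph * g, j, g


def generate_pairs(config: SyntheticConfig, ontology: Ontology,
                   lexicon: list[LexiconEntry]
                   ) -> tuple[list[tuple], list[dict]]:
    """Sample scored sentence pairs and the ground-truth manifest.

    Per pair: a relatedness level r ~ U(0,1) controls both how many
    concepts the two sentences share and how close the remaining concepts
    lie (related pairs draw partner concepts from a small graph
    neighborhood; unrelated pairs draw them uniformly).  Each concept is
    rendered by one of its surface forms chosen at random and interleaved
    with filler tokens; the gold score is clamp(5*latent + N(0, sigma),
    0, 5).  Categories cycle round-robin.
    """
    rng = np.random.default_rng((config.seed, 2))
    surfaces_by_cui: dict[str, list[str]] = {}
    for e in lexicon:
        surfaces_by_cui.setdefault(e.cui, []).append(e.surface)
    distances = {cui: dict(nx.single_source_shortest_path_length(
        ontology.graph, cui)) for cui in ontology.cuis}
    fillers = [f"w{i:03d}" for i in range(config.n_filler_tokens)]
    lo, hi = config.concepts_per_sentence
    n = len(ontology.cuis)
    rows, manifest = [], []
    for k in range(config.n_pairs):
        s1 = int(rng.integers(lo, hi + 1))
        s2 = int(rng.integers(lo, hi + 1))
        set1 = [ontology.cuis[i]
                for i in rng.choice(n, size=s1, replace=False)]
        r = float(rng.uniform())
        n_shared = round(r * min(s1, s2))
        shared = list(rng.choice(set1, size=n_shared, replace=False))
        set2 = list(shared)
        # partners for related pairs come from a 2-hop ball around set1
        if r > 0.5:
            ball = sorted({c for a in set1 for c, d in distances[a].items()
                           if d <= 2})
        else:
            ball = ontology.cuis
        candidates = [c for c in ball if c not in set2]
        while len(set2) < s2 and candidates:
            pick = candidates.pop(int(rng.integers(len(candidates))))
            set2.append(pick)

        def render(concepts):
            surfaces = [surfaces_by_cui[c][int(rng.integers(
                len(surfaces_by_cui[c])))] for c in concepts]
            n_fill = int(rng.integers(2, 5))
            fill = [fillers[int(rng.integers(len(fillers)))]
                    for _ in range(n_fill)]
            tokens = surfaces + fill
            rng.shuffle(tokens)
            return " ".join(tokens), surfaces

        text1, surf1 = render(set1)
        text2, surf2 = render(set2)
        latent, j, g = latent_similarity(surf1, surf2, set1, set2,
                                         distances, config.w_lex,
                                         config.w_graph)
        gold = float(np.clip(5.0 * latent + rng.normal(0, config.noise_sigma),
                             0.0, 5.0))
        category = CATEGORY_CYCLE[k % len(CATEGORY_CYCLE)]
        rows.append((text1, text2, gold, category))
        manifest.append({"record_id": f"r{k + 1:04d}", "latent": latent,
                         "jaccard": j, "graph_proximity": g,
                         "concepts1": set1, "concepts2": set2})
    return rows, manifest


def generate_corpus(config: SyntheticConfig, outdir) -> SyntheticCorpus:
    """Generate and write every benchmark artifact; byte-identical output
    for identical configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology = generate_ontology(config)
    lexicon = generate_lexicon(config, ontology)
    table = generate_embeddings(config, ontology)
    rows, manifest = generate_pairs(config, ontology, lexicon)
    corpus = SyntheticCorpus(
        concepts_path=outdir / "concepts.rrf",
        relations_path=outdir / "relations.rrf",
        lexicon_path=outdir / "lexicon.tsv",
        embeddings_path=outdir / "embeddings.txt",
        dataset_path=outdir / "dataset.tsv",
        manifest_path=outdir / "manifest.json",
        ontology=ontology, lexicon=lexicon)
    write_rrf_files(ontology, corpus.concepts_path, corpus.relations_path)
    write_lexicon_file(lexicon, corpus.lexicon_path)
    write_embedding_file(table, corpus.embeddings_path)
    with open(corpus.dataset_path, "w", encoding="utf-8") as fh:
        for text1, text2, gold, category in rows:
            fh.write(f"{text1}\t{text2}\t{gold:.4f}\t{category}\n")
    with open(corpus.manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return corpus
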