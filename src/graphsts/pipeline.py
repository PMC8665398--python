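"""End-to-end orchestration: corpus files in, evaluation report out.

This module strings the stages together the way the CLI and the benchmark
use them — read the terminology files and build the concept graph, tag every
sentence with the lexicon, induce one concept subgraph per sentence, build
the token vocabulary, then train fusion models and score them — and defines
the package's standard benchmark: a synthetic corpus with a strong planted
graph signal on which the full model, its text-only ablation, its
random-initialization variant, and a seed-varied ensemble are compared by
held-out Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as M
from .augmentation import SentenceRecord, read_dataset, reverse_pair_double
from .evaluation import evaluate, split_dataset
from .graph_encoder import EmbeddingTable, read_embedding_file
from .synthetic import SyntheticConfig, generate_corpus
from .tagging import Lexicon, build_lexicon, read_lexicon_file, tag_sentence
from .terminology import (InducedGraph, TerminologyGraph, build_graph,
                          induce_sentence_graph, read_concept_file,
                          read_relation_file)
from .text_encoder import TextEncoderConfig, TokenVocab, build_vocab

__all__ = ["PreparedCorpus", "BenchmarkResult", "prepare_corpus",
           "attach_graphs", "train_model", "run_benchmark",
           "BENCHMARK_TRAIN_CONFIG"]

# Training setup for the built-in small encoder, which learns from scratch
# rather than fine-tuning a pretrained checkpoint: both parameter groups
# use the rate tuned for the graph side (1e-3), with more epochs than the
# fine-tuning recipe since all weights start cold.
BENCHMARK_TRAIN_CONFIG = M.TrainConfig(lr_text=1e-3, lr_graph=1e-3,
                                       epochs=14, batch_size=16)

BENCHMARK_TEXT_CONFIG = TextEncoderConfig(output_dim=64, embedding_dim=64,
                                          n_blocks=1, max_len=32)


@dataclass
class PreparedCorpus:
    """Everything the model stage needs, with per-record concept graphs."""
    records: list[SentenceRecord]
    items: list[tuple[SentenceRecord, InducedGraph, InducedGraph]]
    term_graph: TerminologyGraph
    lexicon: Lexicon
    vocab: TokenVocab
    embedding_table: EmbeddingTable | None = None


@dataclass
class BenchmarkResult:
    full_r: float
    text_only_r: float
    random_init_r: float
    member_rs: list[float] = field(default_factory=list)
    ensemble_r: float = 0.0
    per_category_r: dict[str, float | None] = field(default_factory=dict)


def attach_graphs(records: list[SentenceRecord],
                  term_graph: TerminologyGraph, lexicon: Lexicon
                  ) -> list[tuple[SentenceRecord, InducedGraph,
                                  InducedGraph]]:
    """Tag both sentences of every record and induce their concept graphs.
    Duplicate concepts within a sentence collapse to one seed."""
    cache: dict[tuple[str, ...], InducedGraph] = {}

    def graph_for(text: str) -> InducedGraph:
        seeds = tuple(sorted({m.cui for m in tag_sentence(text, lexicon)}))
        if seeds not in cache:
            cache[seeds] = induce_sentence_graph(term_graph, list(seeds))
        return cache[seeds]

    return [(r, graph_for(r.text1), graph_for(r.text2)) for r in records]


def prepare_corpus(concepts_path, relations_path, lexicon_path,
                   dataset_path, embeddings_path=None,
                   source_filter: str = "SYNTHCT") -> PreparedCorpus:
    concepts = read_concept_file(concepts_path, source_filter)
    relations = read_relation_file(relations_path,
                                   {c.cui for c in concepts})
    term_graph = build_graph(concepts, relations)
    lexicon = build_lexicon(read_lexicon_file(lexicon_path))
    records = read_dataset(dataset_path)
    items = attach_graphs(records, term_graph, lexicon)
    vocab = build_vocab([t for r in records for t in (r.text1, r.text2)])
    table = (read_embedding_file(embeddings_path)
             if embeddings_path is not None else None)
    return PreparedCorpus(records=records, items=items,
                          term_graph=term_graph, lexicon=lexicon,
                          vocab=vocab, embedding_table=table)


def _split_items(items, seed: int, test_frac: float = 0.2,
                 val_frac: float = 0.15):
    records = [r for r, _, _ in items]
    by_id = {r.record_id: item for item, r in zip(items, records)}
    n = len(records)
    n_test = round(n * test_frac)
    n_val = round(n * val_frac)
    trainval, test = split_dataset(records, n - n_test, n_test, seed)
    train, val = split_dataset(trainval, len(trainval) - n_val, n_val,
                               seed + 1)
    pick = lambda rs: [by_id[r.record_id] for r in rs]
    return pick(train), pick(val), pick(test)


def train_model(prepared: PreparedCorpus, train_items, seed: int,
                graph_enabled: bool = True, feature_mode: str = "pretrained",
                train_config: M.TrainConfig | None = None,
                use_reverse_double: bool = True) -> M.FusionModel:
    """Build and train one fusion model on the given items."""
    table = prepared.embedding_table if feature_mode == "pretrained" else None
    feature_dim = table.dim if table is not None else 16
    model = M.create_fusion_model(
        vocab=prepared.vocab, text_config=BENCHMARK_TEXT_CONFIG,
        gcn_dims=[feature_dim, 32, 32], head_hidden=32,
        feature_mode=feature_mode, feature_dim=feature_dim,
        embedding_table=table, graph_enabled=graph_enabled, seed=seed)
    if use_reverse_double:
        records = [r for r, _, _ in train_items]
        graphs = {r.record_id: (g1, g2) for r, g1, g2 in train_items}
        doubled = reverse_pair_double(records)
        train_items = []
        for r in doubled:
            base_id = r.record_id[:-4] if r.record_id.endswith("_rev") \
                else r.record_id
            g1, g2 = graphs[base_id]
            if r.record_id.endswith("_rev"):
                g1, g2 = g2, g1
            train_items.append((r, g1, g2))
    config = train_config or BENCHMARK_TRAIN_CONFIG
    config = M.TrainConfig(lr_text=config.lr_text, lr_graph=config.lr_graph,
                           epochs=config.epochs,
                           batch_size=config.batch_size,
                           shuffle_seed=seed)
    M.train(model, train_items, config)
    return model


def _test_r(model: M.FusionModel, test_items) -> float:
    preds = M.predict(model, test_items)
    report = evaluate(preds, [r for r, _, _ in test_items])
    return report.overall_r


def run_benchmark(seed: int, config: SyntheticConfig | None = None,
                  outdir=None, n_ensemble: int = 5) -> BenchmarkResult:
    """Generate the benchmark corpus for ``seed`` and measure the model
    variants.

    Trains ``n_ensemble`` seed-varied full models (pretrained node
    features), one random-initialization variant and one text-only
    ablation; reports each member's held-out Pearson r, the ensemble's,
    and the ablations'.  ``full_r`` is the mean over the members, i.e. the
    full model's expected performance with training-seed noise averaged
    out.
    """
    import tempfile

    config = config or SyntheticConfig(seed=seed)
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            corpus = generate_corpus(config, tmp)
            prepared = prepare_corpus(corpus.concepts_path,
                                      corpus.relations_path,
                                      corpus.lexicon_path,
                                      corpus.dataset_path,
                                      corpus.embeddings_path)
    else:
        corpus = generate_corpus(config, outdir)
        prepared = prepare_corpus(corpus.concepts_path,
                                  corpus.relations_path,
                                  corpus.lexicon_path, corpus.dataset_path,
                                  corpus.embeddings_path)
    train_items, _val_items, test_items = _split_items(prepared.items, seed)

    members = [train_model(prepared, train_items, seed=seed * 100 + k)
               for k in range(n_ensemble)]
    member_rs = [_test_r(m, test_items) for m in members]
    ens_preds = M.ensemble_predict(members, test_items)
    ens_report = evaluate(ens_preds, [r for r, _, _ in test_items])

    random_model = train_model(prepared, train_items, seed=seed * 100,
                               feature_mode="random")
    text_model = train_model(prepared, train_items, seed=seed * 100,
                             graph_enabled=False)
    return BenchmarkResult(
        full_r=float(np.mean(member_rs)),
        text_only_r=_test_r(text_model, test_items),
        random_init_r=_test_r(random_model, test_items),
        member_rs=member_rs,
        ensemble_r=ens_report.overall_r,
        per_category_r=ens_report.per_category_r)
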