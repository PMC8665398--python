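"""Fusion of text and graph representations into a similarity score.

One text encoder consumes the sentence pair jointly; one graph encoder with
shared weights encodes each sentence's concept graph separately.  The three
vectors are concatenated and passed to a small feed-forward scoring head
(one hidden rectified-linear layer, then a linear map to a single real
score).  The hidden layer matters: similarity between the two graph
representations is a symmetric interaction, which a purely linear map on a
concatenation cannot express, while one hidden layer can realize distances
such as |u·(g1 − g2)|.

Training minimizes mean squared error on the raw 0-5 rubric scale with two
learning-rate groups (text encoder vs graph encoder + head).  Knowledge
distillation replaces the loss with a teacher-bounded regression loss: the
teacher-imitation term is active only while the student's squared error
(plus a margin) exceeds the teacher's.  Ensembles average member scores in
the model's native output space and clamp to [0, 5] afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Adam, Tensor, concat
from .augmentation import SentenceRecord
from .errors import ConfigurationError, InputError
from .graph_encoder import (EmbeddingTable, GCNParams, encode_graph,
                            init_node_features)
from .terminology import InducedGraph
from .text_encoder import (TextEncoderConfig, TextEncoderParams,
                           TokenVocab, create_text_params, encode_ids_batch,
                           pair_ids)

__all__ = [
    "FusionModel", "TrainConfig", "DistillConfig", "Prediction",
    "create_fusion_model", "forward", "train", "distill",
    "bounded_regression_loss", "predict", "ensemble_predict",
    "save_model", "load_model",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    """Defaults follow the tuned values of the reference setup: 1e-4 for
    the text encoder, 1e-3 for the graph encoder and head, 4 epochs."""
    lr_text: float = 1e-4
    lr_graph: float = 1e-3
    epochs: int = 4
    batch_size: int = 16
    shuffle_seed: int = 0

    def __post_init__(self):
        if self.lr_text <= 0 or self.lr_graph <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


@dataclass
class DistillConfig:
    """Teacher-bounded regression loss constants and the teacher's
    per-record soft labels."""
    teacher_predictions: dict[str, float]
    margin: float = 0.0
    nu: float = 0.5

    def __post_init__(self):
        if self.margin < 0 or self.nu < 0:
            raise ConfigurationError("margin and nu must be >= 0")


@dataclass(frozen=True)
class Prediction:
    record_id: str
    score: float


@dataclass
class FusionModel:
    text_config: TextEncoderConfig
    text_params: TextEncoderParams
    gcn_params: GCNParams
    vocab: TokenVocab
    head_w1: Tensor
    head_b1: Tensor
    head_w2: Tensor
    head_b2: Tensor
    feature_mode: str = "random"       # node-feature init for the GCN
    feature_dim: int = 16
    feature_seed: int = 0
    embedding_table: EmbeddingTable | None = None
    graph_enabled: bool = True         # False = text-only ablation

    def graph_output_dim(self) -> int:
        return self.gcn_params.output_dim

    def concat_dim(self) -> int:
        return self.text_config.output_dim + 2 * self.graph_output_dim()

    def text_tensors(self) -> list[Tensor]:
        return self.text_params.all_tensors()

    def graph_and_head_tensors(self) -> list[Tensor]:
        out = [w for w in self.gcn_params.layer_weights]
        if self.gcn_params.input_projection is not None:
            out.append(self.gcn_params.input_projection)
        out += [self.head_w1, self.head_b1, self.head_w2, self.head_b2]
        return out

    def node_features(self, graph: InducedGraph) -> np.ndarray:
        return init_node_features(graph, mode=self.feature_mode,
                                  table=self.embedding_table,
                                  dim=self.feature_dim,
                                  seed=self.feature_seed)


def create_fusion_model(vocab: TokenVocab,
                        text_config: TextEncoderConfig | None = None,
                        gcn_dims: list[int] | None = None,
                        head_hidden: int = 32,
                        feature_mode: str = "random",
                        feature_dim: int = 16,
                        embedding_table: EmbeddingTable | None = None,
                        graph_enabled: bool = True,
                        seed: int = 0) -> FusionModel:
    """Freshly initialized model; ``gcn_dims`` is the layer-width chain of
    the graph encoder (first entry = layer-1 input width; a projection from
    ``feature_dim`` is prepended automatically when the two differ)."""
    text_config = text_config or TextEncoderConfig()
    gcn_dims = gcn_dims or [feature_dim, 64, 64]
    rng = np.random.default_rng(seed)
    text_params = create_text_params(text_config, vocab.size,
                                     seed=int(rng.integers(2 ** 31)))

    def glorot(d_in, d_out):
        scale = np.sqrt(6.0 / (d_in + d_out))
        return Tensor(rng.uniform(-scale, scale, size=(d_in, d_out)))

    layer_weights = [glorot(a, b) for a, b in zip(gcn_dims, gcn_dims[1:])]
    projection = None
    if feature_dim != gcn_dims[0]:
        projection = glorot(feature_dim, gcn_dims[0])
    gcn_params = GCNParams(layer_weights=layer_weights,
                           input_projection=projection)
    concat_dim = text_config.output_dim + 2 * gcn_dims[-1]
    model = FusionModel(
        text_config=text_config, text_params=text_params,
        gcn_params=gcn_params, vocab=vocab,
        head_w1=glorot(concat_dim, head_hidden),
        head_b1=Tensor(np.zeros(head_hidden)),
        head_w2=glorot(head_hidden, 1),
        head_b2=Tensor(np.array([2.5])),  # start at the rubric midpoint
        feature_mode=feature_mode, feature_dim=feature_dim,
        feature_seed=seed, embedding_table=embedding_table,
        graph_enabled=graph_enabled)
    return model


# -- forward ---------------------------------------------------------------


def _graph_vector(model: FusionModel, graph: InducedGraph,
                  features: np.ndarray | None = None) -> Tensor:
    d = model.graph_output_dim()
    if not model.graph_enabled or graph.n_nodes == 0:
        return Tensor(np.zeros(d))
    if features is None:
        features = model.node_features(graph)
    vec = encode_graph(graph, Tensor(features), model.gcn_params)
    return vec if isinstance(vec, Tensor) else Tensor(vec)


def _batch_forward(model: FusionModel, ids: np.ndarray,
                   graphs: list[tuple[InducedGraph, InducedGraph]],
                   feats: list[tuple[np.ndarray | None, np.ndarray | None]]
                   | None = None) -> Tensor:
    """Scores for a batch: (B,) tensor."""
    if feats is None:
        feats = [(None, None)] * len(graphs)
    text_vecs = encode_ids_batch(ids, model.text_params, model.text_config,
                                 pad_id=model.vocab.pad_id)
    g1_rows = [_graph_vector(model, g1, f1).reshape(1, -1)
               for (g1, _), (f1, _) in zip(graphs, feats)]
    g2_rows = [_graph_vector(model, g2, f2).reshape(1, -1)
               for (_, g2), (_, f2) in zip(graphs, feats)]
    fused = concat([text_vecs,
                    concat(g1_rows, axis=0),
                    concat(g2_rows, axis=0)], axis=-1)
    hidden = (fused @ model.head_w1 + model.head_b1).relu()
    scores = hidden @ model.head_w2 + model.head_b2
    return scores.reshape(-1)


def forward(model: FusionModel, record: SentenceRecord,
            graph1: InducedGraph, graph2: InducedGraph) -> float:
    """Raw (unclamped) similarity score for one record."""
    ids = pair_ids(record.text1, record.text2, model.vocab,
                   model.text_config.max_len)[None, :]
    return float(_batch_forward(model, ids, [(graph1, graph2)]).data[0])


# -- losses ----------------------------------------------------------------


def bounded_regression_loss(student: float, teacher: float, gold: float,
                            m: float = 0.0, nu: float = 0.5) -> float:
    """(student - gold)^2 + nu * B, with B = (student - teacher)^2 while
    (student - gold)^2 + m > (teacher - gold)^2 and B = 0 otherwise."""
    if m < 0 or nu < 0:
        raise ConfigurationError("margin and nu must be >= 0")
    student_err = (student - gold) ** 2
    teacher_err = (teacher - gold) ** 2
    bound = (student - teacher) ** 2 if student_err + m > teacher_err else 0.0
    return student_err + nu * bound


def _mse_loss(scores: Tensor, golds: np.ndarray,
              _teachers: np.ndarray | None, _cfg) -> Tensor:
    return ((scores - Tensor(golds)) ** 2).mean()


def _bounded_loss(scores: Tensor, golds: np.ndarray,
                  teachers: np.ndarray, cfg: DistillConfig) -> Tensor:
    # The bound indicator is evaluated on current values; no gradient
    # flows through the switching condition itself.
    student_err = (scores.data - golds) ** 2
    teacher_err = (teachers - golds) ** 2
    active = (student_err + cfg.margin > teacher_err).astype(np.float64)
    sq_gold = (scores - Tensor(golds)) ** 2
    sq_teacher = (scores - Tensor(teachers)) ** 2
    return (sq_gold + cfg.nu * (sq_teacher * Tensor(active))).mean()


# -- training --------------------------------------------------------------


TrainItem = tuple[SentenceRecord, InducedGraph, InducedGraph]


def _prepare_items(model: FusionModel, dataset: list[TrainItem]):
    ids = np.stack([
        pair_ids(r.text1, r.text2, model.vocab, model.text_config.max_len)
        for r, _, _ in dataset])
    graphs = [(g1, g2) for _, g1, g2 in dataset]
    # node features are fixed inputs; compute them once per record
    feats = []
    if model.graph_enabled:
        for g1, g2 in graphs:
            feats.append((
                model.node_features(g1) if g1.n_nodes else None,
                model.node_features(g2) if g2.n_nodes else None))
    else:
        feats = [(None, None)] * len(graphs)
    return ids, graphs, feats


def _train_loop(model: FusionModel, dataset: list[TrainItem],
                config: TrainConfig, loss_fn, teachers: np.ndarray | None,
                loss_cfg) -> list[float]:
    if not dataset:
        raise InputError("training dataset is empty")
    for record, _, _ in dataset:
        if record.score is None:
            raise InputError(f"record {record.record_id} has no gold score")
    ids, graphs, feats = _prepare_items(model, dataset)
    golds = np.array([r.score for r, _, _ in dataset], dtype=np.float64)

    trainable = model.graph_and_head_tensors()
    groups = [{"params": trainable, "lr": config.lr_graph},
              {"params": model.text_tensors(), "lr": config.lr_text}]
    for group in groups:
        for p in group["params"]:
            p.requires_grad = True
    optimizer = Adam(groups)
    rng = np.random.default_rng(config.shuffle_seed)
    n = len(dataset)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            scores = _batch_forward(model, ids[idx],
                                    [graphs[i] for i in idx],
                                    [feats[i] for i in idx])
            t_batch = None if teachers is None else teachers[idx]
            loss = loss_fn(scores, golds[idx], t_batch, loss_cfg)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    for group in groups:
        for p in group["params"]:
            p.requires_grad = False
            p.grad = None
    return trace


def train(model: FusionModel, dataset: list[TrainItem],
          config: TrainConfig | None = None
          ) -> tuple[FusionModel, list[float]]:
    """Minimize MSE in place; returns the model and the per-epoch mean
    training loss."""
    config = config or TrainConfig()
    trace = _train_loop(model, dataset, config, _mse_loss, None, None)
    return model, trace


def distill(model: FusionModel, dataset: list[TrainItem],
            train_config: TrainConfig, distill_config: DistillConfig
            ) -> tuple[FusionModel, list[float]]:
    """Train against gold labels plus the teacher's soft labels under the
    bounded regression loss."""
    missing = [r.record_id for r, _, _ in dataset
               if r.record_id not in distill_config.teacher_predictions]
    if missing:
        raise InputError("no teacher prediction for records: "
                         + ", ".join(sorted(missing)))
    teachers = np.array(
        [distill_config.teacher_predictions[r.record_id]
         for r, _, _ in dataset], dtype=np.float64)
    trace = _train_loop(model, dataset, train_config, _bounded_loss,
                        teachers, distill_config)
    return model, trace


# -- prediction ------------------------------------------------------------


def _raw_scores(model: FusionModel, dataset: list[TrainItem],
                batch_size: int = 64) -> np.ndarray:
    ids, graphs, feats = _prepare_items(model, dataset)
    out = []
    for start in range(0, len(dataset), batch_size):
        scores = _batch_forward(model, ids[start:start + batch_size],
                                graphs[start:start + batch_size],
                                feats[start:start + batch_size])
        out.append(scores.data)
    return np.concatenate(out) if out else np.zeros(0)


def predict(model: FusionModel, dataset: list[TrainItem]
            ) -> list[Prediction]:
    """Per-record predictions, clamped to the [0, 5] rubric."""
    raw = _raw_scores(model, dataset)
    return [Prediction(record_id=r.record_id,
                       score=float(np.clip(s, 0.0, 5.0)))
            for (r, _, _), s in zip(dataset, raw)]


def ensemble_predict(models: list, dataset: list[TrainItem]
                     ) -> list[Prediction]:
    """Unweighted mean of member scores in the models' native (unclamped)
    output space, clamped to [0, 5] afterwards.  Members may be
    :class:`FusionModel` instances or any object with a
    ``raw_scores(dataset) -> array`` method."""
    if not models:
        raise InputError("ensemble requires at least one model")
    all_scores = []
    for member in models:
        if isinstance(member, FusionModel):
            all_scores.append(_raw_scores(member, dataset))
        else:
            all_scores.append(np.asarray(member.raw_scores(dataset),
                                         dtype=np.float64))
    mean_scores = np.mean(all_scores, axis=0)
    return [Prediction(record_id=r.record_id,
                       score=float(np.clip(s, 0.0, 5.0)))
            for (r, _, _), s in zip(dataset, mean_scores)]


# -- checkpoint serialization (versioned JSON archive) ---------------------


def save_model(model: FusionModel, path):
    def arr(t: Tensor):
        return t.data.tolist()

    manifest = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "text_config": {
            "encoder_kind": model.text_config.encoder_kind,
            "output_dim": model.text_config.output_dim,
            "embedding_dim": model.text_config.embedding_dim,
            "n_blocks": model.text_config.n_blocks,
            "max_len": model.text_config.max_len,
            "external_checkpoint": model.text_config.external_checkpoint,
        },
        "feature_mode": model.feature_mode,
        "feature_dim": model.feature_dim,
        "feature_seed": model.feature_seed,
        "graph_enabled": model.graph_enabled,
        "gcn_activation": model.gcn_params.activation,
        "vocab": sorted(model.vocab.token_to_id,
                        key=model.vocab.token_to_id.get),
        "params": {
            "token_emb": arr(model.text_params.token_emb),
            "pos_emb": arr(model.text_params.pos_emb),
            "blocks": [{k: arr(v) for k, v in b.items()}
                       for b in model.text_params.blocks],
            "gcn_layers": [arr(w) for w in model.gcn_params.layer_weights],
            "gcn_projection": (
                None if model.gcn_params.input_projection is None
                else arr(model.gcn_params.input_projection)),
            "head_w1": arr(model.head_w1),
            "head_b1": arr(model.head_b1),
            "head_w2": arr(model.head_w2),
            "head_b2": arr(model.head_b2),
        },
        "embedding_table": (
            None if model.embedding_table is None
            else {"dim": model.embedding_table.dim,
                  "vectors": {k: v.tolist() for k, v in
                              sorted(model.embedding_table.vectors.items())}}),
    }
    Path(path).write_text(json.dumps(manifest), encoding="utf-8")


def load_model(path) -> FusionModel:
    manifest = json.loads(Path(path).read_text(encoding="utf-8"))
    if manifest.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ConfigurationError(
            f"unsupported checkpoint format version "
            f"{manifest.get('format_version')}")
    text_config = TextEncoderConfig(**manifest["text_config"])
    vocab = TokenVocab(token_to_id={t: i for i, t in
                                    enumerate(manifest["vocab"])})
    p = manifest["params"]

    def t(x):
        return Tensor(np.array(x, dtype=np.float64))

    text_params = TextEncoderParams(
        token_emb=t(p["token_emb"]), pos_emb=t(p["pos_emb"]),
        blocks=[{k: t(v) for k, v in b.items()} for b in p["blocks"]])
    gcn_params = GCNParams(
        layer_weights=[t(w) for w in p["gcn_layers"]],
        activation=manifest["gcn_activation"],
        input_projection=(None if p["gcn_projection"] is None
                          else t(p["gcn_projection"])))
    table = None
    if manifest["embedding_table"] is not None:
        table = EmbeddingTable(
            dim=manifest["embedding_table"]["dim"],
            vectors={k: np.array(v) for k, v in
                     manifest["embedding_table"]["vectors"].items()})
    return FusionModel(
        text_config=text_config, text_params=text_params,
        gcn_params=gcn_params, vocab=vocab,
        head_w1=t(p["head_w1"]), head_b1=t(p["head_b1"]),
        head_w2=t(p["head_w2"]), head_b2=t(p["head_b2"]),
        feature_mode=manifest["feature_mode"],
        feature_dim=manifest["feature_dim"],
        feature_seed=manifest["feature_seed"],
        embedding_table=table,
        graph_enabled=manifest["graph_enabled"])
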