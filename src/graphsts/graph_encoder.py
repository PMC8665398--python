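"""Graph convolutional encoding of sentence concept graphs.

Each layer applies the symmetric-normalized propagation rule with self-loops,

    H' = act( D̃^{-1/2} (A + I) D̃^{-1/2} · H · W ),

where A is the binary adjacency matrix, D̃ the degree matrix of A + I, H the
node features and W the layer weights.  A whole-graph representation is read
out by mean pooling over node rows, which makes the encoding invariant to
node permutation and to graph size.

Node features are initialized either from a pretrained concept-embedding
table (the knowledge-graph-embedding route) or from a seeded random normal;
concepts missing from the table fall back to seeded random rows.

The layer and readout operations accept both plain numpy arrays and this
package's autodiff :class:`~graphsts._autodiff.Tensor`, so the same code
path serves oracle-style numeric checks and gradient-based training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .errors import ConfigurationError, RecordFormatError
from .terminology import InducedGraph

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingTable", "GCNParams",
    "read_embedding_file", "write_embedding_file",
    "init_node_features", "normalized_adjacency", "gcn_layer",
    "encode_graph", "create_gcn_params",
]

ACTIVATIONS = ("relu", "tanh", "identity")


@dataclass
class EmbeddingTable:
    """Concept-identifier -> dense vector map; all vectors share ``dim``."""
    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for cui, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ConfigurationError(
                    f"vector for {cui} has length {vec.shape}, "
                    f"expected ({self.dim},)")


@dataclass
class GCNParams:
    """Stacked layer weights plus activation and readout names.

    ``input_projection``, when present, linearly maps raw node features to
    the first layer's input width — needed when a pretrained embedding table
    was trained at a different dimension than the encoder expects.
    """
    layer_weights: list  # of (d_l, d_{l+1}) matrices (ndarray or Tensor)
    activation: str = "relu"
    readout: str = "mean"
    input_projection: object | None = None

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(f"unknown activation {self.activation}")
        if len(self.layer_weights) < 1:
            raise ConfigurationError("at least one layer required")
        for w_a, w_b in zip(self.layer_weights, self.layer_weights[1:]):
            if _shape(w_a)[1] != _shape(w_b)[0]:
                raise ConfigurationError("layer dimensions do not chain")

    @property
    def n_layers(self) -> int:
        return len(self.layer_weights)

    @property
    def output_dim(self) -> int:
        return _shape(self.layer_weights[-1])[1]


def _shape(x):
    return x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape


def _apply_activation(x, name: str):
    if name == "identity":
        return x
    if isinstance(x, Tensor):
        return x.relu() if name == "relu" else x.tanh()
    return np.maximum(x, 0.0) if name == "relu" else np.tanh(x)


# -- embedding files: word2vec-style text ---------------------------------


def read_embedding_file(path) -> EmbeddingTable:
    """Read "identifier v1 v2 ... vd" lines; a leading "count dim" header
    line (two integer fields) is accepted and skipped."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if line_no == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            if len(parts) < 2:
                raise RecordFormatError(path, line_no,
                                        "expected identifier plus vector")
            try:
                vec = np.array([float(v) for v in parts[1:]])
            except ValueError:
                raise RecordFormatError(path, line_no,
                                        "non-numeric vector entry") from None
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise RecordFormatError(path, line_no,
                                        f"vector length {len(vec)} != {dim}")
            vectors[parts[0]] = vec
    if dim is None:
        raise RecordFormatError(path, 0, "empty embedding file")
    return EmbeddingTable(dim=dim, vectors=vectors)


def write_embedding_file(table: EmbeddingTable, path, header: bool = True):
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table.vectors)} {table.dim}\n")
        for cui in sorted(table.vectors):
            vals = " ".join(format(v, ".6g") for v in table.vectors[cui])
            fh.write(f"{cui} {vals}\n")


# -- node feature initialization ------------------------------------------


def init_node_features(graph: InducedGraph, mode: str = "random",
                       table: EmbeddingTable | None = None,
                       dim: int = 64, seed: int = 0) -> np.ndarray:
    """Build the (n_nodes, dim) feature matrix, rows ordered as
    ``graph.node_ids``.

    random mode: seeded standard normal scaled by 1/sqrt(dim).  pretrained
    mode: table lookup per node, with a seeded random fallback row for
    concepts missing from the table (logged); the fallback for a given node
    depends only on the seed and the node's position, so in-table rows are
    untouched by the seed.
    """
    n = graph.n_nodes
    if mode == "random":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n, dim)) / np.sqrt(dim)
    if mode != "pretrained":
        raise ConfigurationError(f"unknown init mode {mode!r}")
    if table is None:
        raise ConfigurationError("pretrained mode requires an embedding "
                                 "table")
    if table.dim != dim:
        raise ConfigurationError(
            f"table dimension {table.dim} != requested dimension {dim}")
    features = np.zeros((n, dim))
    missing = []
    for i, cui in enumerate(graph.node_ids):
        vec = table.vectors.get(cui)
        if vec is None:
            row_rng = np.random.default_rng((seed, i))
            features[i] = row_rng.standard_normal(dim) / np.sqrt(dim)
            missing.append(cui)
        else:
            features[i] = vec
    if missing:
        logger.warning("no pretrained vector for %d node(s): %s",
                       len(missing), ",".join(missing))
    return features


# -- propagation ------------------------------------------------------------


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """S = D̃^{-1/2} (A + I) D̃^{-1/2} with D̃ the degree matrix of A + I."""
    adjacency = np.asarray(adjacency, dtype=np.float64)
    n = adjacency.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    a_tilde = adjacency + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(features, adjacency: np.ndarray, weights,
              activation: str = "relu"):
    """One propagation step: activation(S · features · weights)."""
    n = np.asarray(adjacency).shape[0]
    if _shape(features)[0] != n:
        raise ConfigurationError("feature rows do not match adjacency size")
    if _shape(features)[1] != _shape(weights)[0]:
        raise ConfigurationError("feature width does not match weight rows")
    s = normalized_adjacency(adjacency)
    if isinstance(features, Tensor) or isinstance(weights, Tensor):
        out = Tensor(s) @ features @ weights
    else:
        out = s @ np.asarray(features) @ np.asarray(weights)
    return _apply_activation(out, activation)


def encode_graph(graph: InducedGraph, features, params: GCNParams):
    """Stack the configured layers, then mean-pool node rows into one
    vector.  The empty graph encodes to the zero vector."""
    d_out = params.output_dim
    if graph.n_nodes == 0:
        zero = np.zeros(d_out)
        return Tensor(zero) if _params_need_tensor(params) else zero
    h = features
    if params.input_projection is not None:
        if isinstance(h, Tensor) or isinstance(params.input_projection,
                                               Tensor):
            h = (h if isinstance(h, Tensor) else Tensor(h)) \
                @ params.input_projection
        else:
            h = np.asarray(h) @ params.input_projection
    for w in params.layer_weights:
        h = gcn_layer(h, graph.adjacency, w, params.activation)
    if params.readout != "mean":
        raise ConfigurationError(f"unknown readout {params.readout!r}")
    return h.mean(axis=0)


def _params_need_tensor(params: GCNParams) -> bool:
    return any(isinstance(w, Tensor) for w in params.layer_weights)


def create_gcn_params(dims: list[int], activation: str = "relu",
                      seed: int = 0,
                      input_dim: int | None = None) -> GCNParams:
    """Glorot-initialized weights for a layer stack ``dims[0] -> dims[1]
    -> ...``; an input projection from ``input_dim`` is prepended when it
    differs from ``dims[0]``."""
    rng = np.random.default_rng(seed)

    def glorot(d_in, d_out):
        scale = np.sqrt(6.0 / (d_in + d_out))
        return rng.uniform(-scale, scale, size=(d_in, d_out))

    weights = [glorot(a, b) for a, b in zip(dims, dims[1:])]
    projection = None
    if input_dim is not None and input_dim != dims[0]:
        projection = glorot(input_dim, dims[0])
    return GCNParams(layer_weights=weights, activation=activation,
                     input_projection=projection)
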