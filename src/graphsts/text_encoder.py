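"""Sentence-pair text encoding.

The package ships a small trainable encoder — token + position embeddings
followed by a configurable number of single-head self-attention blocks with
residual connections, mean-pooled over non-pad positions — sized for
CPU-minute experiments.  Production-scale pretrained transformer checkpoints
plug in through the external-adapter contract instead: any callable mapping
``(text1, text2)`` to a fixed-length vector satisfies the same interface, so
the rest of the pipeline is agnostic to which encoder produced the vector.

Both sentences are encoded jointly as one sequence, "text1 [SEP] text2",
following the standard sentence-pair convention of transformer encoders.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._autodiff import Tensor
from .errors import CapabilityError, ConfigurationError

__all__ = [
    "TokenVocab", "TextEncoderConfig", "TextEncoderParams",
    "build_vocab", "read_vocab_file", "write_vocab_file",
    "tokenize", "create_text_params", "encode_ids_batch", "encode_pair",
]

_TOKEN_RE = re.compile(r"[0-9a-z]+")

PAD_TOKEN, UNK_TOKEN, SEP_TOKEN = "<pad>", "<unk>", "<sep>"


@dataclass
class TokenVocab:
    token_to_id: dict[str, int]
    pad_id: int = 0
    unk_id: int = 1
    sep_id: int = 2

    def __post_init__(self):
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ConfigurationError("vocabulary ids must be dense from 0")
        if self.pad_id == self.unk_id:
            raise ConfigurationError("pad and unknown ids must differ")

    @property
    def size(self) -> int:
        return len(self.token_to_id)


def build_vocab(texts: list[str]) -> TokenVocab:
    """Special tokens first, then the corpus tokens in sorted order."""
    tokens: set[str] = set()
    for text in texts:
        tokens.update(_TOKEN_RE.findall(text.lower()))
    mapping = {PAD_TOKEN: 0, UNK_TOKEN: 1, SEP_TOKEN: 2}
    for tok in sorted(tokens):
        if tok not in mapping:
            mapping[tok] = len(mapping)
    return TokenVocab(token_to_id=mapping)


def read_vocab_file(path) -> TokenVocab:
    """One token per line; id = 0-based line number."""
    mapping: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            mapping[line.rstrip("\n")] = i
    return TokenVocab(token_to_id=mapping,
                      pad_id=mapping.get(PAD_TOKEN, 0),
                      unk_id=mapping.get(UNK_TOKEN, 1),
                      sep_id=mapping.get(SEP_TOKEN, 2))


def write_vocab_file(vocab: TokenVocab, path):
    by_id = sorted(vocab.token_to_id.items(), key=lambda kv: kv[1])
    with open(path, "w", encoding="utf-8") as fh:
        for token, _ in by_id:
            fh.write(token + "\n")


def tokenize(text: str, vocab: TokenVocab, max_len: int) -> np.ndarray:
    """Lowercased alphanumeric-run tokens mapped to ids, truncated and
    right-padded to exactly ``max_len``."""
    ids = [vocab.token_to_id.get(tok, vocab.unk_id)
           for tok in _TOKEN_RE.findall(text.lower())]
    ids = ids[:max_len]
    ids += [vocab.pad_id] * (max_len - len(ids))
    return np.array(ids, dtype=np.int64)


def pair_ids(text1: str, text2: str, vocab: TokenVocab,
             max_len: int) -> np.ndarray:
    """Joint id sequence "text1 [SEP] text2" truncated/padded to max_len."""
    ids1 = [vocab.token_to_id.get(t, vocab.unk_id)
            for t in _TOKEN_RE.findall(text1.lower())]
    ids2 = [vocab.token_to_id.get(t, vocab.unk_id)
            for t in _TOKEN_RE.findall(text2.lower())]
    joint = ids1 + [vocab.sep_id] + ids2
    joint = joint[:max_len]
    joint += [vocab.pad_id] * (max_len - len(joint))
    return np.array(joint, dtype=np.int64)


@dataclass
class TextEncoderConfig:
    encoder_kind: str = "builtin_small"  # or "external_adapter"
    output_dim: int = 64
    embedding_dim: int = 64
    n_blocks: int = 2
    max_len: int = 64
    external_checkpoint: str = ""

    def __post_init__(self):
        if self.output_dim <= 0:
            raise ConfigurationError("output_dim must be positive")
        if self.encoder_kind not in ("builtin_small", "external_adapter"):
            raise ConfigurationError(
                f"unknown encoder kind {self.encoder_kind!r}")
        if (self.encoder_kind == "builtin_small"
                and self.output_dim != self.embedding_dim):
            raise ConfigurationError(
                "builtin encoder pools its hidden states, so output_dim "
                "must equal embedding_dim")


@dataclass
class TextEncoderParams:
    """Builtin-encoder parameters as autodiff tensors.

    ``blocks`` holds per-block dicts with query/key/value/output projection
    matrices ``wq, wk, wv, wo``.
    """
    token_emb: Tensor
    pos_emb: Tensor
    blocks: list[dict[str, Tensor]] = field(default_factory=list)

    def all_tensors(self) -> list[Tensor]:
        out = [self.token_emb, self.pos_emb]
        for block in self.blocks:
            out.extend(block.values())
        return out


def create_text_params(config: TextEncoderConfig, vocab_size: int,
                       seed: int = 0) -> TextEncoderParams:
    rng = np.random.default_rng(seed)
    d = config.embedding_dim

    def init(shape, scale):
        return Tensor(rng.standard_normal(shape) * scale)

    token_emb = init((vocab_size, d), 1.0 / np.sqrt(d))
    pos_emb = init((config.max_len, d), 0.01)
    blocks = [
        {name: init((d, d), 1.0 / np.sqrt(d))
         for name in ("wq", "wk", "wv", "wo")}
        for _ in range(config.n_blocks)
    ]
    return TextEncoderParams(token_emb=token_emb, pos_emb=pos_emb,
                             blocks=blocks)


def encode_ids_batch(ids: np.ndarray, params: TextEncoderParams,
                     config: TextEncoderConfig,
                     pad_id: int = 0) -> Tensor:
    """Encode a (batch, max_len) id matrix to a (batch, embedding_dim)
    tensor.

    With zero attention blocks the result is exactly the mean of the token
    embeddings over non-pad positions (position embeddings enter only
    through the attention path).  Rows that are all padding encode to zero.
    """
    if ids.ndim != 2:
        raise ConfigurationError("ids must be a (batch, max_len) matrix")
    mask = (ids != pad_id).astype(np.float64)          # (B, L)
    x = params.token_emb.take_rows(ids)                # (B, L, d)
    if config.n_blocks > 0:
        x = x + params.pos_emb
        attn_mask = np.where(mask[:, None, :] > 0, 0.0, -1e9)  # (B, 1, L)
        scale = 1.0 / np.sqrt(config.embedding_dim)
        for block in params.blocks:
            q = x @ block["wq"]
            k = x @ block["wk"]
            v = x @ block["wv"]
            scores = (q @ k.transpose_last()) * scale
            attn = scores.softmax_last(additive_mask=attn_mask)
            x = x + ((attn @ v) @ block["wo"]).relu()
    summed = (x * Tensor(mask[:, :, None])).sum(axis=1)  # (B, d)
    counts = mask.sum(axis=1, keepdims=True)
    counts[counts == 0] = 1.0
    return summed * Tensor(1.0 / counts)


def encode_pair(text1: str, text2: str, config: TextEncoderConfig,
                parameters, vocab: TokenVocab | None = None,
                external: Callable[[str, str], np.ndarray] | None = None
                ) -> np.ndarray:
    """Encode one sentence pair to a vector of length ``config.output_dim``.

    builtin_small requires ``vocab`` and a :class:`TextEncoderParams`;
    external_adapter delegates to the ``external`` callable.
    """
    if config.encoder_kind == "external_adapter":
        if external is None:
            raise CapabilityError(
                "no external text-encoder adapter was supplied; use "
                "encoder_kind='builtin_small' or inject a callable")
        vec = np.asarray(external(text1, text2), dtype=np.float64)
        if vec.shape != (config.output_dim,):
            raise ConfigurationError(
                f"external adapter returned shape {vec.shape}, expected "
                f"({config.output_dim},)")
        return vec
    if vocab is None:
        raise ConfigurationError("builtin encoder requires a vocabulary")
    ids = pair_ids(text1, text2, vocab, config.max_len)[None, :]
    return encode_ids_batch(ids, parameters, config,
                            pad_id=vocab.pad_id).data[0]
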