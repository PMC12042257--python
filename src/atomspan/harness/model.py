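"""T5-style encoder-decoder: parameter accounting and a smoke-scale
training/decoding harness.

The architecture audited here is the standard pre-norm encoder-decoder
with relative-position attention biases, RMS layer norms without biases,
bias-free linear projections, a gated feed-forward block (three
projections), and an input embedding tied to the output head.  At the
published configuration — 8 encoder and 8 decoder layers, 10 heads of
dimension 64, model width 640, feed-forward width 2048, a 203-token
vocabulary — this sums to 102.4 M learnable parameters.

``count_parameters`` is a closed form over tensor shapes and is verified
against instantiate-and-count; ``smoke_train`` / ``greedy_decode`` run
tiny configurations end to end to show the corruption objectives are
learnable, which is as far as a single CPU goes — full pretraining (the
documented :class:`PretrainingSchedule`) is not an executable target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..tokenizer import EOS, PAD, Vocabulary, build_vocabulary
from .autodiff import (
    Adam,
    Tensor,
    cross_entropy,
    embedding,
    rms_norm,
    silu,
    softmax,
)

__all__ = [
    "ArchitectureConfig",
    "PretrainingSchedule",
    "count_parameters",
    "param_shapes",
    "init_params",
    "forward_logits",
    "smoke_train",
    "greedy_decode",
    "examples_to_batch",
]

NEG_INF = -1e9


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters of the encoder-decoder.

    ``n_layers`` counts layers per stack (encoder and decoder each).
    ``ffn_gated`` selects the three-projection gated feed-forward block;
    ``tie_embedding`` shares the input embedding with the output head.
    """

    n_layers: int = 8
    n_heads: int = 10
    d_model: int = 640
    d_ff: int = 2048
    vocab_size: int = 203
    head_dim: int = 64
    ffn_gated: bool = True
    tie_embedding: bool = True
    rel_pos_buckets: int = 32
    rel_pos_max_distance: int = 128

    def __post_init__(self):
        if min(self.n_layers, self.n_heads, self.d_model, self.d_ff,
               self.vocab_size, self.head_dim, self.rel_pos_buckets) < 1:
            raise ValueError("all architecture dimensions must be positive")
        if self.n_heads * self.head_dim != self.d_model:
            raise ValueError("n_heads * head_dim must equal d_model")

    @property
    def inner_dim(self) -> int:
        return self.n_heads * self.head_dim


@dataclass(frozen=True)
class PretrainingSchedule:
    """The full-scale pretraining recipe, documented but not executable
    at desk scale (it assumes multi-GPU bf16 training)."""

    steps: int = 142599
    batch_size: int = 2880
    learning_rate: float = 1.414e-4
    loss: str = "cross_entropy"


def count_parameters(config: ArchitectureConfig) -> int:
    """Closed-form learnable-parameter count of the architecture.

    Sums the shared embedding (plus a separate head when untied),
    per-layer attention projections (Q, K, V, O without biases), the
    feed-forward projections (3 when gated, 2 otherwise), RMS-norm
    weights (2 per encoder layer, 3 per decoder layer, 1 final per
    stack), and one relative-position bias table per stack.
    """
    d, f, v = config.d_model, config.d_ff, config.vocab_size
    inner = config.inner_dim
    attn = 4 * d * inner
    ffn = (3 if config.ffn_gated else 2) * d * f
    enc_layer = attn + ffn + 2 * d
    dec_layer = 2 * attn + ffn + 3 * d
    rel = config.rel_pos_buckets * config.n_heads
    total = config.n_layers * (enc_layer + dec_layer)
    total += 2 * d          # final norms, encoder + decoder
    total += 2 * rel        # relative-position bias tables per stack
    total += v * d          # tied input embedding
    if not config.tie_embedding:
        total += v * d      # separate output head
    return total


def param_shapes(config: ArchitectureConfig) -> dict[str, tuple[int, ...]]:
    """Name -> shape map of every learnable tensor in the harness model."""
    d, f = config.d_model, config.d_ff
    inner = config.inner_dim
    shapes: dict[str, tuple[int, ...]] = {
        "embedding": (config.vocab_size, d),
        "enc.rel_bias": (config.rel_pos_buckets, config.n_heads),
        "dec.rel_bias": (config.rel_pos_buckets, config.n_heads),
        "enc.final_norm": (d,),
        "dec.final_norm": (d,),
    }
    if not config.tie_embedding:
        shapes["lm_head"] = (config.vocab_size, d)

    def attn(prefix: str):
        shapes[f"{prefix}.q"] = (d, inner)
        shapes[f"{prefix}.k"] = (d, inner)
        shapes[f"{prefix}.v"] = (d, inner)
        shapes[f"{prefix}.o"] = (inner, d)

    def ffn(prefix: str):
        if config.ffn_gated:
            shapes[f"{prefix}.wi0"] = (d, f)
            shapes[f"{prefix}.wi1"] = (d, f)
        else:
            shapes[f"{prefix}.wi"] = (d, f)
        shapes[f"{prefix}.wo"] = (f, d)

    for i in range(config.n_layers):
        attn(f"enc.{i}.attn")
        ffn(f"enc.{i}.ffn")
        shapes[f"enc.{i}.norm0"] = (d,)
        shapes[f"enc.{i}.norm1"] = (d,)
        attn(f"dec.{i}.self_attn")
        attn(f"dec.{i}.cross_attn")
        ffn(f"dec.{i}.ffn")
        shapes[f"dec.{i}.norm0"] = (d,)
        shapes[f"dec.{i}.norm1"] = (d,)
        shapes[f"dec.{i}.norm2"] = (d,)
    return shapes


def init_params(config: ArchitectureConfig, seed: int = 0,
                zeros: bool = False) -> dict[str, Tensor]:
    """Instantiate every tensor of :func:`param_shapes`.

    Norm weights start at 1, bias tables at 0, projections at scaled
    Gaussians.  ``zeros=True`` allocates without random init (useful for
    pure accounting)."""
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    for name, shape in param_shapes(config).items():
        if zeros or "rel_bias" in name:
            data = np.zeros(shape)
        elif "norm" in name:
            data = np.ones(shape)
        else:
            fan_in = shape[0]
            data = rng.normal(0.0, fan_in ** -0.5, size=shape)
        params[name] = Tensor(data)
    return params


# ---- relative position buckets (shared-table attention bias) ---------------

def _relative_position_bucket(relative_position: np.ndarray, bidirectional: bool,
                              num_buckets: int, max_distance: int) -> np.ndarray:
    ret = np.zeros_like(relative_position)
    n = -relative_position
    if bidirectional:
        num_buckets //= 2
        ret += (n < 0).astype(int) * num_buckets
        n = np.abs(n)
    else:
        n = np.maximum(n, 0)
    max_exact = num_buckets // 2
    is_small = n < max_exact
    large = max_exact + (
        np.log(np.maximum(n, 1) / max_exact)
        / np.log(max_distance / max_exact)
        * (num_buckets - max_exact)
    ).astype(int)
    large = np.minimum(large, num_buckets - 1)
    return ret + np.where(is_small, n, large)


def _position_bias(table: Tensor, q_len: int, k_len: int, bidirectional: bool,
                   config: ArchitectureConfig) -> Tensor:
    ctx = np.arange(q_len)[:, None]
    mem = np.arange(k_len)[None, :]
    buckets = _relative_position_bucket(
        mem - ctx, bidirectional, config.rel_pos_buckets,
        config.rel_pos_max_distance,
    )
    bias = embedding(table, buckets)          # (Tq, Tk, H)
    return bias.transpose((2, 0, 1))          # (H, Tq, Tk)


# ---- forward ---------------------------------------------------------------

def _split_heads(x: Tensor, config: ArchitectureConfig) -> Tensor:
    b, t, _ = x.shape
    return x.reshape(b, t, config.n_heads, config.head_dim).transpose((0, 2, 1, 3))


def _merge_heads(x: Tensor, config: ArchitectureConfig) -> Tensor:
    b, h, t, hd = x.shape
    return x.transpose((0, 2, 1, 3)).reshape(b, t, h * hd)


def _attention(params, prefix: str, x_q: Tensor, x_kv: Tensor,
               mask: np.ndarray | None, bias: Tensor | None,
               config: ArchitectureConfig) -> Tensor:
    q = _split_heads(x_q.matmul(params[f"{prefix}.q"]), config)
    k = _split_heads(x_kv.matmul(params[f"{prefix}.k"]), config)
    v = _split_heads(x_kv.matmul(params[f"{prefix}.v"]), config)
    scores = q.matmul(k.transpose((0, 1, 3, 2))).scale(config.head_dim ** -0.5)
    if bias is not None:
        scores = scores + bias
    if mask is not None:
        scores = scores.add_const(mask)
    attn = softmax(scores, axis=-1)
    out = _merge_heads(attn.matmul(v), config)
    return out.matmul(params[f"{prefix}.o"])


def _ffn(params, prefix: str, x: Tensor, config: ArchitectureConfig) -> Tensor:
    if config.ffn_gated:
        h = silu(x.matmul(params[f"{prefix}.wi0"])) * x.matmul(params[f"{prefix}.wi1"])
    else:
        h = silu(x.matmul(params[f"{prefix}.wi"]))
    return h.matmul(params[f"{prefix}.wo"])


def forward_logits(params: dict[str, Tensor], config: ArchitectureConfig,
                   src_ids: np.ndarray, tgt_in_ids: np.ndarray,
                   src_pad_mask: np.ndarray | None = None) -> Tensor:
    """Teacher-forced decoder logits, shape (B, T_tgt, vocab)."""
    src_ids = np.asarray(src_ids)
    tgt_in_ids = np.asarray(tgt_in_ids)
    b, ts = src_ids.shape
    tt = tgt_in_ids.shape[1]

    enc_mask = None
    if src_pad_mask is not None:
        enc_mask = np.where(src_pad_mask, 0.0, NEG_INF)[:, None, None, :]

    x = embedding(params["embedding"], src_ids)
    enc_bias = _position_bias(params["enc.rel_bias"], ts, ts, True, config)
    for i in range(config.n_layers):
        h = rms_norm(x, params[f"enc.{i}.norm0"])
        x = x + _attention(params, f"enc.{i}.attn", h, h, enc_mask, enc_bias, config)
        h = rms_norm(x, params[f"enc.{i}.norm1"])
        x = x + _ffn(params, f"enc.{i}.ffn", h, config)
    enc_out = rms_norm(x, params["enc.final_norm"])

    causal = np.triu(np.full((tt, tt), NEG_INF), k=1)[None, None, :, :]
    dec_bias = _position_bias(params["dec.rel_bias"], tt, tt, False, config)
    y = embedding(params["embedding"], tgt_in_ids)
    for i in range(config.n_layers):
        h = rms_norm(y, params[f"dec.{i}.norm0"])
        y = y + _attention(params, f"dec.{i}.self_attn", h, h, causal, dec_bias, config)
        h = rms_norm(y, params[f"dec.{i}.norm1"])
        y = y + _attention(params, f"dec.{i}.cross_attn", h, enc_out, enc_mask,
                           None, config)
        h = rms_norm(y, params[f"dec.{i}.norm2"])
        y = y + _ffn(params, f"dec.{i}.ffn", h, config)
    y = rms_norm(y, params["dec.final_norm"])

    if config.tie_embedding:
        head = params["embedding"].transpose((1, 0))
        return y.scale(config.d_model ** -0.5).matmul(head)
    return y.matmul(params["lm_head"].transpose((1, 0)))


# ---- batching, training, decoding ------------------------------------------

def examples_to_batch(examples, vocab: Vocabulary):
    """Pad corruption examples into (src, tgt_in, tgt_out, src_mask, loss_mask)."""
    pad = vocab.index(PAD)
    srcs = [vocab.encode(list(e.input_tokens)) for e in examples]
    tgts = [vocab.encode(list(e.target_tokens)) for e in examples]
    ts = max(len(s) for s in srcs)
    tt = max(len(t) for t in tgts)
    b = len(examples)
    src = np.full((b, ts), pad, dtype=np.int64)
    tgt_out = np.full((b, tt), pad, dtype=np.int64)
    src_mask = np.zeros((b, ts), dtype=bool)
    loss_mask = np.zeros((b, tt), dtype=np.float64)
    for i, (s, t) in enumerate(zip(srcs, tgts)):
        src[i, : len(s)] = s
        src_mask[i, : len(s)] = True
        tgt_out[i, : len(t)] = t
        loss_mask[i, : len(t)] = 1.0
    tgt_in = np.roll(tgt_out, 1, axis=1)
    tgt_in[:, 0] = pad  # decoder start token
    return src, tgt_in, tgt_out, src_mask, loss_mask


SMOKE_CONFIG = ArchitectureConfig(
    n_layers=2, n_heads=4, d_model=64, d_ff=128, head_dim=16,
    rel_pos_buckets=16, rel_pos_max_distance=64,
)


def smoke_train(corpus, steps: int, seed: int = 0,
                config: ArchitectureConfig = SMOKE_CONFIG,
                lr: float = 3e-3,
                vocab: Vocabulary | None = None,
                stop_below: float | None = None) -> list[float]:
    """Full-batch Adam training on a tiny corpus; returns the loss trace.

    Deterministic under ``seed`` (pure NumPy).  Meant for learnability
    smoke tests — e.g. a handful of corruption examples memorized to
    near-zero loss within a few hundred steps.  ``stop_below`` ends
    training early once the loss drops under the given value.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    vocab = vocab or build_vocabulary()
    src, tgt_in, tgt_out, src_mask, loss_mask = examples_to_batch(corpus, vocab)
    params = init_params(config, seed=seed)
    opt = Adam(params, lr=lr)
    trace: list[float] = []
    for _ in range(steps):
        opt.zero_grad()
        logits = forward_logits(params, config, src, tgt_in, src_mask)
        loss = cross_entropy(logits, tgt_out, loss_mask)
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
        if stop_below is not None and trace[-1] < stop_below:
            break
    smoke_train.last_params = params  # retained for decoding after training
    smoke_train.last_config = config
    return trace


def greedy_decode(params: dict[str, Tensor], config: ArchitectureConfig,
                  input_tokens, max_len: int = 64,
                  vocab: Vocabulary | None = None) -> list[str]:
    """Argmax decoding until ``<eos>`` or ``max_len`` tokens."""
    vocab = vocab or build_vocabulary()
    toks = list(input_tokens)
    for t in toks:
        if t not in vocab:
            raise ValueError(f"input token not in vocabulary: {t!r}")
    pad = vocab.index(PAD)
    eos = vocab.index(EOS)
    src = np.array([vocab.encode(toks)], dtype=np.int64)
    out_ids: list[int] = []
    for _ in range(max_len):
        tgt_in = np.array([[pad] + out_ids], dtype=np.int64)
        logits = forward_logits(params, config, src, tgt_in)
        nxt = int(np.argmax(logits.data[0, -1]))
        out_ids.append(nxt)
        if nxt == eos:
            break
    return vocab.decode(out_ids)
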