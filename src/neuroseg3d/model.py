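"""Hybrid CNN–Transformer architecture for 3D patch segmentation.

The network maps an intensity block of shape (H, W, D, C) to per-voxel class
probabilities of shape (H, W, D, S+1):

1. **Encoder** — a stack of stride-1 3×3×3 convolutions with ReLU and *no
   pooling or striding*: spatial resolution is preserved end to end, so the
   encoder contributes purely local features.
2. **Tokenization** — the feature maps are partitioned into nonoverlapping
   P×P×P blocks (P = ``patch_resolution``); each block is flattened and
   linearly projected to ``hidden_size`` = d_model, and a learned positional
   embedding E_pos ∈ ℝ^{N×d_model} is added. N = (H/P)(W/P)(D/P).
3. **Transformer bottleneck** — I pre-norm layers, each
   ``x + MHSA(LN(x))`` followed by ``· + MLP(LN(·))`` with a ReLU hidden
   layer of width ``mlp_size`` and dropout. MHSA is scaled dot-product
   attention, ``softmax(Q Kᵀ / √d_k) V`` per head, heads concatenated and
   projected by W^O.
4. **Decoder** — tokens reshaped back to the (H/P, W/P, D/P) grid, then
   log₂(P) stages of ×2 nearest-neighbour upsampling + 3×3×3 conv + ReLU.
   At full resolution the encoder features arrive through a **Res path**
   (residual conv units along the skip), are concatenated, fused by a conv,
   and a 1×1×1 conv head produces the class logits; softmax gives
   probabilities.

Everything runs on the numpy autograd engine in :mod:`neuroseg3d.autograd`;
parameters are float32 Tensors in a flat name→Tensor registry, which is also
the checkpoint format.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["ModelConfig", "AttentionParams", "TokenSequence", "SegmentationNetwork",
           "scaled_dot_attention", "mhsa", "conv3d", "upsample2", "layer_norm"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference training setup: 4 transformer layers with
    4 heads each, hidden size (d_model) 64, MLP size 192, dropout 0.1,
    layer-norm epsilon 1e-4, patch resolution 8³ (16³ as the coarser
    alternative). Encoder depth/widths are open in the original description;
    two 3×3×3 conv blocks of width 16 keep the P³·C′ token flatten tractable.
    """

    input_shape: tuple[int, int, int, int] = (64, 64, 64, 1)
    n_classes: int = 2
    n_transformer_layers: int = 4
    n_heads: int = 4
    hidden_size: int = 64
    mlp_size: int = 192
    dropout_rate: float = 0.1
    layer_norm_epsilon: float = 1e-4
    patch_resolution: int = 8
    encoder_channels: tuple[int, ...] = (16, 16)
    decoder_channels: tuple[int, ...] | None = None
    res_path_blocks: int = 1
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self):
        h, w, d, c = self.input_shape
        p = self.patch_resolution
        if p < 1 or (p & (p - 1)) != 0:
            raise ValueError(f"patch_resolution must be a power of two, got {p}")
        if any(dim % p for dim in (h, w, d)):
            raise ValueError(f"input dims {h, w, d} must be divisible by P={p}")
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least background + one structure")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same-padding convs)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        p = self.patch_resolution
        return tuple(s // p for s in self.input_shape[:3])

    @property
    def n_tokens(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.n_heads

    @property
    def n_upsample_stages(self) -> int:
        return int(math.log2(self.patch_resolution))

    def resolved_decoder_channels(self) -> tuple[int, ...]:
        if self.decoder_channels is not None:
            if len(self.decoder_channels) != self.n_upsample_stages:
                raise ValueError("decoder_channels must have one width per "
                                 f"upsampling stage ({self.n_upsample_stages})")
            return tuple(self.decoder_channels)
        return tuple(max(16, self.hidden_size >> (i + 1))
                     for i in range(self.n_upsample_stages))


@dataclass
class TokenSequence:
    """A batch of token embeddings plus the grid needed to undo flattening."""

    tokens: Tensor | np.ndarray  # (B, N, d_model)
    grid_shape: tuple[int, int, int]

    def __post_init__(self):
        n = self.tokens.shape[-2]
        if n != int(np.prod(self.grid_shape)):
            raise ValueError(f"{n} tokens inconsistent with grid {self.grid_shape}")


@dataclass
class AttentionParams:
    """Per-head projections W_i^Q/K/V (h, d_model, d_k|d_v) and W^O (h·d_v, d_model)."""

    w_q: Tensor
    w_k: Tensor
    w_v: Tensor
    w_o: Tensor

    def __post_init__(self):
        h, d_model, d_k = self.w_q.shape
        if self.w_k.shape != (h, d_model, d_k):
            raise ValueError("W^K shape inconsistent with W^Q")
        h2, _, d_v = self.w_v.shape
        if h2 != h:
            raise ValueError("W^V head count inconsistent")
        if self.w_o.shape != (h * d_v, d_model):
            raise ValueError(f"W^O must be ({h * d_v}, {d_model}), got {self.w_o.shape}")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,D,C) -> (B·H·W·D, k³·C) patch matrix under same zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # win: (B, H, W, D, C, k, k, k) -> (B, H, W, D, k, k, k, C)
    win = win.transpose(0, 1, 2, 3, 5, 6, 7, 4)
    return win.reshape(-1, k ** 3 * x.shape[-1])


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    k, _, _, c_in, c_out = w.shape
    cols = _im2col(x, k)
    y = cols @ w.reshape(k ** 3 * c_in, c_out)
    if b is not None:
        y += b
    return y.reshape(x.shape[:4] + (c_out,))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, same-padded 3D convolution, (B,H,W,D,Cin) -> (B,H,W,D,Cout).

    Kernel layout is (k, k, k, Cin, Cout) with odd k. The input gradient is
    itself a convolution with the spatially flipped, channel-transposed
    kernel; the weight gradient is the im2col matrix against the output
    gradient — both ride on BLAS.
    """
    k = w.shape[0]
    parents = (x, w) if b is None else (x, w, b)

    def forward():
        return _conv_forward(x.data, w.data, None if b is None else b.data)

    def backward(g):
        g2 = g.reshape(-1, w.shape[-1])
        grads = []
        if x.requires_grad:
            wf = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)  # flip + swap io
            grads.append(_conv_forward(g, np.ascontiguousarray(wf), None))
        else:
            grads.append(None)
        if w.requires_grad:
            cols = _im2col(x.data, k)
            grads.append((cols.T @ g2).reshape(w.shape))
        else:
            grads.append(None)
        if b is not None:
            grads.append(g2.sum(axis=0) if b.requires_grad else None)
        return grads

    return ag.make_op(forward, backward, *parents)


def upsample2(x: Tensor | np.ndarray) -> Tensor | np.ndarray:
    """Nearest-neighbour ×2 upsampling on the three spatial axes."""
    if not isinstance(x, Tensor):
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def forward():
        return x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        b, h2, w2, d2, c = g.shape
        g = g.reshape(b, h2 // 2, 2, w2 // 2, 2, d2 // 2, 2, c)
        return [g.sum(axis=(2, 4, 6))]

    return ag.make_op(forward, backward, x)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Layer normalization over the trailing feature axis."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta


def _swap_last(x):
    if isinstance(x, Tensor):
        axes = list(range(x.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return x.transpose(axes)
    return np.swapaxes(x, -1, -2)


def scaled_dot_attention(q, k, v):
    """``softmax(Q Kᵀ / √d_k) V`` over the last two axes (leading axes batch).

    Attention weights are row-stochastic, so each output row is a convex
    combination of the rows of V. Accepts Tensors (differentiable) or plain
    arrays.
    """
    d_k = q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    if k.shape[-1] != d_k:
        raise ValueError("Q and K feature dimensions differ")
    scores = (q @ _swap_last(k)) * (1.0 / math.sqrt(d_k))
    weights = ag.softmax(scores, axis=-1)
    return weights @ v


def mhsa(seq, params: AttentionParams):
    """Multi-head self-attention on a token sequence (..., N, d_model).

    Each head projects the sequence with its own W^Q, W^K, W^V, runs scaled
    dot-product attention, and the concatenated head outputs are projected
    by W^O.
    """
    x = seq.tokens if isinstance(seq, TokenSequence) else seq
    plain_input = not isinstance(x, Tensor)
    if plain_input:
        x = Tensor(np.asarray(x))
    h, d_model, d_k = params.w_q.shape
    d_v = params.w_v.shape[-1]

    # (h, d_model, d_k) -> (d_model, h·d_k) so one matmul projects all heads
    def all_heads(w, d_out):
        return w.transpose(1, 0, 2).reshape(d_model, h * d_out)

    q = x @ all_heads(params.w_q, d_k)
    k = x @ all_heads(params.w_k, d_k)
    v = x @ all_heads(params.w_v, d_v)

    def split(t, d_out):  # (..., N, h·d) -> (..., h, N, d)
        n = t.shape[-2]
        lead = t.shape[:-2]
        t = t.reshape(lead + (n, h, d_out))
        axes = list(range(len(lead))) + [len(lead) + 1, len(lead), len(lead) + 2]
        return t.transpose(axes)

    heads = scaled_dot_attention(split(q, d_k), split(k, d_k), split(v, d_v))
    lead = x.shape[:-2]
    n = x.shape[-2]
    axes = list(range(len(lead))) + [len(lead) + 1, len(lead), len(lead) + 2]
    concat = heads.transpose(axes).reshape(lead + (n, h * d_v))
    out = concat @ params.w_o
    if plain_input and not out.requires_grad:
        out = out.data
    if isinstance(seq, TokenSequence):
        return TokenSequence(tokens=out, grid_shape=seq.grid_shape)
    return out


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class SegmentationNetwork:
    """Parameterised network instance; owns the weight registry and the RNG."""

    def __init__(self, cfg: ModelConfig, init: bool = True):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(cfg.seed)
        if init:
            self._build()

    # -- parameter setup -----------------------------------------------
    def _param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array.astype(np.float32), requires_grad=True, name=name)
        self.params[name] = t
        return t

    def _conv_init(self, name: str, k: int, c_in: int, c_out: int):
        fan_in = k ** 3 * c_in
        std = math.sqrt(2.0 / fan_in)  # He, matches ReLU nonlinearity
        self._param(f"{name}.w", self._rng.normal(0, std, (k, k, k, c_in, c_out)))
        self._param(f"{name}.b", np.zeros(c_out))

    def _linear_init(self, name: str, d_in: int, d_out: int, bias: bool = True):
        std = math.sqrt(1.0 / d_in)
        self._param(f"{name}.w", self._rng.normal(0, std, (d_in, d_out)))
        if bias:
            self._param(f"{name}.b", np.zeros(d_out))

    def _build(self):
        cfg = self.cfg
        k = cfg.kernel_size
        c = cfg.input_shape[3]
        for i, width in enumerate(cfg.encoder_channels):
            self._conv_init(f"enc.{i}", k, c, width)
            c = width
        c_enc = c

        p3c = cfg.patch_resolution ** 3 * c_enc
        self._linear_init("embed", p3c, cfg.hidden_size)
        self._param("e_pos", self._rng.normal(0, 0.02, (cfg.n_tokens, cfg.hidden_size)))

        d, d_h = cfg.hidden_size, cfg.head_dim
        for i in range(cfg.n_transformer_layers):
            pre = f"tf.{i}"
            self._param(f"{pre}.ln1.g", np.ones(d))
            self._param(f"{pre}.ln1.b", np.zeros(d))
            std = math.sqrt(1.0 / d)
            for nm in ("w_q", "w_k", "w_v"):
                self._param(f"{pre}.attn.{nm}",
                            self._rng.normal(0, std, (cfg.n_heads, d, d_h)))
            # residual output projections start at zero so every transformer
            # layer begins as the identity; greatly improves conditioning
            self._param(f"{pre}.attn.w_o", np.zeros((d, d)))
            self._param(f"{pre}.ln2.g", np.ones(d))
            self._param(f"{pre}.ln2.b", np.zeros(d))
            self._linear_init(f"{pre}.mlp.0", d, cfg.mlp_size)
            self._param(f"{pre}.mlp.1.w", np.zeros((cfg.mlp_size, d)))
            self._param(f"{pre}.mlp.1.b", np.zeros(d))

        c = cfg.hidden_size
        for i, width in enumerate(cfg.resolved_decoder_channels()):
            self._conv_init(f"dec.{i}", k, c, width)
            c = width
        c_dec = c

        for i in range(cfg.res_path_blocks):
            self._conv_init(f"res.{i}.conv3", k, c_enc, c_enc)
            self._conv_init(f"res.{i}.conv1", 1, c_enc, c_enc)

        self._conv_init("fuse", k, c_dec + c_enc, c_dec)
        # classification head: 1×1×1 conv to S+1 channels, zero-initialised
        # so the initial prediction is exactly uniform over classes
        self._param("head.w", np.zeros((1, 1, 1, c_dec, cfg.n_classes)))
        self._param("head.b", np.zeros(cfg.n_classes))

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- stages ----------------------------------------------------------
    def _check_finite(self, t: Tensor, stage: str):
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError(f"non-finite activations after stage '{stage}'")

    def conv_encoder(self, x: Tensor) -> Tensor:
        """Pooling-free encoder; spatial shape is preserved at every layer."""
        spatial = x.shape[1:4]
        for i in range(len(self.cfg.encoder_channels)):
            x = ag.relu(conv3d(x, self.params[f"enc.{i}.w"], self.params[f"enc.{i}.b"]))
            assert x.shape[1:4] == spatial, "encoder must preserve resolution"
        return x

    def patch_embed(self, features: Tensor) -> TokenSequence:
        """P³ block partition -> flatten -> linear projection -> + E_pos."""
        cfg = self.cfg
        p = cfg.patch_resolution
        b, h, w, d, c = features.shape
        if any(dim % p for dim in (h, w, d)):
            raise ValueError(f"feature dims {(h, w, d)} not divisible by P={p}")
        gh, gw, gd = h // p, w // p, d // p
        t = features.reshape(b, gh, p, gw, p, gd, p, c)
        t = t.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        t = t.reshape(b, gh * gw * gd, p ** 3 * c)
        tokens = t @ self.params["embed.w"] + self.params["embed.b"]
        tokens = tokens + self.params["e_pos"]
        return TokenSequence(tokens=tokens, grid_shape=(gh, gw, gd))

    def transformer_layer(self, seq: TokenSequence, index: int,
                          training: bool = False) -> TokenSequence:
        """Pre-norm residual block: x + MHSA(LN(x)), then + MLP(LN(·))."""
        cfg = self.cfg
        pre = f"tf.{index}"
        eps = cfg.layer_norm_epsilon
        x = seq.tokens
        attn = AttentionParams(w_q=self.params[f"{pre}.attn.w_q"],
                               w_k=self.params[f"{pre}.attn.w_k"],
                               w_v=self.params[f"{pre}.attn.w_v"],
                               w_o=self.params[f"{pre}.attn.w_o"])
        normed = layer_norm(x, self.params[f"{pre}.ln1.g"], self.params[f"{pre}.ln1.b"], eps)
        x = x + mhsa(normed, attn)
        normed = layer_norm(x, self.params[f"{pre}.ln2.g"], self.params[f"{pre}.ln2.b"], eps)
        hidden = ag.relu(normed @ self.params[f"{pre}.mlp.0.w"] + self.params[f"{pre}.mlp.0.b"])
        hidden = self._dropout(hidden, training)
        x = x + (hidden @ self.params[f"{pre}.mlp.1.w"] + self.params[f"{pre}.mlp.1.b"])
        return TokenSequence(tokens=x, grid_shape=seq.grid_shape)

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        rate = self.cfg.dropout_rate
        if not training or rate == 0.0:
            return x
        keep = (self._rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
        return x * Tensor(keep)

    def res_path(self, features: Tensor, n_blocks: int | None = None) -> Tensor:
        """Residual conv units along the skip: relu(conv3(x) + conv1(x))."""
        if n_blocks is None:
            n_blocks = self.cfg.res_path_blocks
        for i in range(n_blocks):
            a = conv3d(features, self.params[f"res.{i}.conv3.w"],
                       self.params[f"res.{i}.conv3.b"])
            b = conv3d(features, self.params[f"res.{i}.conv1.w"],
                       self.params[f"res.{i}.conv1.b"])
            features = ag.relu(a + b)
        return features

    def decoder(self, seq: TokenSequence, skip: Tensor) -> Tensor:
        """Token grid -> ×2 upsampling stages -> Res-path fusion -> logits."""
        cfg = self.cfg
        gh, gw, gd = seq.grid_shape
        b = seq.tokens.shape[0]
        x = seq.tokens.reshape(b, gh, gw, gd, cfg.hidden_size)
        for i in range(cfg.n_upsample_stages):
            x = upsample2(x)
            x = ag.relu(conv3d(x, self.params[f"dec.{i}.w"], self.params[f"dec.{i}.b"]))
        skip = self.res_path(skip)
        x = ag.concatenate([x, skip], axis=-1)
        x = ag.relu(conv3d(x, self.params["fuse.w"], self.params["fuse.b"]))
        return conv3d(x, self.params["head.w"], self.params["head.b"])

    def forward(self, x: np.ndarray | Tensor, training: bool = False) -> Tensor:
        """Full forward pass -> per-voxel class probabilities (B,H,W,D,S+1).

        Accepts a single (H,W,D) or (H,W,D,C) block or a batch; probabilities
        along the class axis sum to 1. Non-finite activations raise a
        FloatingPointError naming the stage.
        """
        if not isinstance(x, Tensor):
            arr = np.asarray(x, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[..., None]
            if arr.ndim == 4:
                arr = arr[None]
            x = Tensor(arr)
        feats = self.conv_encoder(x)
        self._check_finite(feats, "conv_encoder")
        seq = self.patch_embed(feats)
        for i in range(self.cfg.n_transformer_layers):
            seq = self.transformer_layer(seq, i, training=training)
        self._check_finite(seq.tokens, "transformer")
        logits = self.decoder(seq, feats)
        self._check_finite(logits, "decoder")
        return ag.softmax(logits, axis=-1)

    def predict_labels(self, block: np.ndarray) -> np.ndarray:
        """Argmax segmentation of one (H,W,D) intensity block."""
        probs = self.forward(block, training=False).data[0]
        return probs.argmax(axis=-1).astype(np.int16)

    # -- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Single-file archive: JSON config + named parameter arrays."""
        path = Path(path)
        cfg = asdict(self.cfg)
        arrays = {name.replace(".", "__"): p.data for name, p in self.params.items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        path = Path(path)
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
            cfg_json = bytes(data["__config__"]).decode()
            d = json.loads(cfg_json)
            for key in ("input_shape", "encoder_channels"):
                d[key] = tuple(d[key])
            if d.get("decoder_channels") is not None:
                d["decoder_channels"] = tuple(d["decoder_channels"])
            net = cls(ModelConfig(**d), init=False)
            for name in data.files:
                if name == "__config__":
                    continue
                net.params[name.replace("__", ".")] = Tensor(
                    data[name], requires_grad=True, name=name.replace("__", "."))
        return net
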