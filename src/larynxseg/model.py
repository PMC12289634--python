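"""Hierarchical transformer encoder + all-MLP decoder for laryngeal segmentation.

The network follows the efficient hierarchical vision-transformer design:

* an **overlap patch embedding** turns the image (or a feature grid) into a
  token sequence with a strided, overlapping windowed linear projection;
  the first stage uses stride 4 (4x4-pixel patches), later stages stride 2,
  so the encoder emits a feature pyramid at 1/4, 1/8, 1/16 and 1/32 of the
  input resolution;
* **efficient self-attention** keeps full-length queries but reduces the
  key/value sequence by a ratio R: the N x C sequence is reshaped to
  (N/R) x (C*R) and linearly projected back to C channels, cutting the
  quadratic attention cost by R;
* a **mix feed-forward network** (linear expansion, depth-wise 3x3
  convolution on the token grid, GELU, linear contraction, residual) leaks
  positional information through the convolution, so no explicit positional
  encoding is needed;
* a lightweight **all-MLP decoder** projects each pyramid level to a common
  width, upsamples everything to the 1/4 grid, fuses by a linear layer and
  classifies each pixel into {background, trachea, supraglottis}.

Everything runs on the NumPy autodiff core in :mod:`larynxseg.nn`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import autodiff as ad
from .nn import LayerNorm, Linear, Module, Conv2d, DepthwiseConv3x3, Tensor, no_grad


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters of the 4-stage encoder and MLP decoder."""

    num_classes: int = 3
    stage_depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    embed_dims: tuple[int, int, int, int] = (32, 64, 160, 256)
    num_heads: tuple[int, int, int, int] = (1, 2, 5, 8)
    reduction_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)
    patch_kernels: tuple[int, int, int, int] = (7, 3, 3, 3)
    patch_strides: tuple[int, int, int, int] = (4, 2, 2, 2)
    decoder_dim: int = 256
    ffn_expansion: int = 4

    def __post_init__(self):
        if self.patch_strides[0] != 4:
            raise ValueError("first-stage stride must be 4 (4x4-pixel patches)")
        if tuple(self.patch_strides[1:]) != (2, 2, 2):
            raise ValueError("stages 2-4 must use stride 2 for the 1/4..1/32 pyramid")
        for d, h in zip(self.embed_dims, self.num_heads):
            if d % h:
                raise ValueError(f"embed dim {d} not divisible by head count {h}")
        if any(r < 1 for r in self.reduction_ratios):
            raise ValueError("reduction ratios must be >= 1")

    @classmethod
    def micro(cls) -> "ModelConfig":
        """Small CPU-friendly capacity used by tests and desk-scale runs."""
        return cls(stage_depths=(1, 1, 1, 1), embed_dims=(16, 32, 64, 128),
                   num_heads=(1, 2, 4, 8), decoder_dim=64, ffn_expansion=2)


@dataclass
class TokenGrid:
    """A token sequence with its 2-d grid arrangement (N = H' * W')."""

    tokens: Tensor            # (B, N, C)
    grid_shape: tuple[int, int]

    def __post_init__(self):
        h, w = self.grid_shape
        if self.tokens.shape[1] != h * w:
            raise ValueError(f"token count {self.tokens.shape[1]} != grid {h}x{w}")


@dataclass
class FeaturePyramid:
    """Four multi-resolution feature grids, coarse to fine: 1/4 .. 1/32."""

    levels: list[Tensor]      # each (B, C_i, H_i, W_i)

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError(f"pyramid must have exactly 4 levels, got {len(self.levels)}")
        sizes = [lv.shape[2] * lv.shape[3] for lv in self.levels]
        if any(later >= earlier for later, earlier in zip(sizes[1:], sizes[:-1])):
            raise ValueError("pyramid spatial sizes must strictly decrease")


def tokens_to_grid(x: Tensor, grid_shape: tuple[int, int]) -> Tensor:
    """(B, N, C) tokens -> (B, C, H', W') feature grid."""
    B, N, C = x.shape
    h, w = grid_shape
    return ad.transpose(ad.reshape(x, (B, h, w, C)), (0, 3, 1, 2))


def grid_to_tokens(x: Tensor) -> tuple[Tensor, tuple[int, int]]:
    """(B, C, H, W) feature grid -> ((B, N, C) tokens, grid shape)."""
    B, C, H, W = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 3, 1)), (B, H * W, C)), (H, W)


class OverlapPatchEmbed(Module):
    """Strided overlapping-window projection followed by token layer norm."""

    def __init__(self, rng, in_ch: int, dim: int, kernel: int, stride: int):
        self.proj = Conv2d(rng, in_ch, dim, kernel, stride, padding=kernel // 2)
        self.norm = LayerNorm(dim)
        self.kernel = kernel

    def __call__(self, x: Tensor) -> TokenGrid:
        if min(x.shape[2], x.shape[3]) < self.kernel - 2 * (self.kernel // 2):
            raise ValueError("input smaller than patch kernel")
        tokens, grid = grid_to_tokens(self.proj(x))
        return TokenGrid(tokens=self.norm(tokens), grid_shape=grid)


class SequenceReduction(Module):
    """Reduce an N x C token sequence to (N/R) x C.

    Reshape to (N/R) x (C*R), then a learned linear map back to C channels.
    Sequences whose length is not divisible by R are zero-padded first.
    """

    def __init__(self, rng, dim: int, ratio: int):
        if ratio < 1:
            raise ValueError(f"reduction ratio must be >= 1, got {ratio}")
        self.ratio = ratio
        self.linear = Linear(rng, dim * ratio, dim) if ratio > 1 else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.ratio == 1:
            return x
        return reduce_sequence(x, self.ratio, self.linear)


def reduce_sequence(x: Tensor, ratio: int, linear: Linear) -> Tensor:
    """Functional form of the sequence reduction (see class docstring)."""
    if ratio < 1:
        raise ValueError(f"reduction ratio must be >= 1, got {ratio}")
    B, N, C = x.shape
    if N % ratio:
        pad = ratio - N % ratio
        zeros = Tensor(np.zeros((B, pad, C), dtype=np.float32))
        x = ad.concat([x, zeros], axis=1)
        N += pad
    x = ad.reshape(x, (B, N // ratio, C * ratio))
    return linear(x)


class EfficientSelfAttention(Module):
    """Multi-head attention with sequence-reduced keys and values.

    Queries keep the full token length N; keys/values are shortened by the
    reduction ratio. A layer norm follows the reduction (only when R > 1)
    to keep the shortened sequence well-scaled.
    """

    def __init__(self, rng, dim: int, heads: int, ratio: int):
        if dim % heads:
            raise ValueError(f"channel count {dim} not divisible by {heads} heads")
        self.heads = heads
        self.dim = dim
        self.q_proj = Linear(rng, dim, dim)
        self.k_proj = Linear(rng, dim, dim)
        self.v_proj = Linear(rng, dim, dim)
        self.out_proj = Linear(rng, dim, dim)
        self.reduce = SequenceReduction(rng, dim, ratio)
        self.reduce_norm = LayerNorm(dim) if ratio > 1 else None

    def _split_heads(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        d = C // self.heads
        return ad.transpose(ad.reshape(x, (B, N, self.heads, d)), (0, 2, 1, 3))

    def __call__(self, x: Tensor, return_weights: bool = False):
        B, N, C = x.shape
        kv = self.reduce(x)
        if self.reduce_norm is not None:
            kv = self.reduce_norm(kv)
        q = self._split_heads(self.q_proj(x))          # (B, h, N, d)
        k = self._split_heads(self.k_proj(kv))         # (B, h, M, d)
        v = self._split_heads(self.v_proj(kv))
        d = C // self.heads
        scores = ad.mul(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))),
                        Tensor(1.0 / math.sqrt(d)))
        weights = ad.softmax(scores, axis=-1)
        out = ad.matmul(weights, v)                    # (B, h, N, d)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, N, C))
        out = self.out_proj(out)
        return (out, weights) if return_weights else out


class MixFFN(Module):
    """Linear expand -> depth-wise 3x3 conv on the grid -> GELU -> contract,
    with a residual connection (``__call__``); ``inner`` omits the residual
    for use inside pre-normalized blocks."""

    def __init__(self, rng, dim: int, expansion: int):
        hidden = dim * expansion
        self.fc1 = Linear(rng, dim, hidden)
        self.conv = DepthwiseConv3x3(rng, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def inner(self, x: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        h = self.fc1(x)
        g = tokens_to_grid(h, grid_shape)
        g = self.conv(g)
        h, _ = grid_to_tokens(g)
        h = ad.gelu(h)
        return self.fc2(h)

    def __call__(self, x: TokenGrid) -> TokenGrid:
        if x.grid_shape is None:
            raise ValueError("mix-FFN requires the token grid shape")
        out = ad.add(self.inner(x.tokens, x.grid_shape), x.tokens)
        return TokenGrid(tokens=out, grid_shape=x.grid_shape)


class TransformerBlock(Module):
    """Pre-normalized attention + mix-FFN with residual connections."""

    def __init__(self, rng, dim: int, heads: int, ratio: int, expansion: int):
        self.norm1 = LayerNorm(dim)
        self.attn = EfficientSelfAttention(rng, dim, heads, ratio)
        self.norm2 = LayerNorm(dim)
        self.ffn = MixFFN(rng, dim, expansion)

    def __call__(self, x: Tensor, grid_shape: tuple[int, int]) -> Tensor:
        x = ad.add(x, self.attn(self.norm1(x)))
        x = ad.add(x, self.ffn.inner(self.norm2(x), grid_shape))
        return x


class Encoder(Module):
    """Four-stage hierarchical encoder emitting the 1/4..1/32 pyramid."""

    def __init__(self, rng, config: ModelConfig):
        self.config = config
        self.stages = []
        in_ch = 3
        for i in range(4):
            dim = config.embed_dims[i]
            stage = {
                "embed": OverlapPatchEmbed(rng, in_ch, dim,
                                           config.patch_kernels[i],
                                           config.patch_strides[i]),
                "blocks": [TransformerBlock(rng, dim, config.num_heads[i],
                                            config.reduction_ratios[i],
                                            config.ffn_expansion)
                           for _ in range(config.stage_depths[i])],
                "norm": LayerNorm(dim),
            }
            self.stages.append(stage)
            in_ch = dim

    def parameters(self):
        params = []
        for st in self.stages:
            params += st["embed"].parameters()
            for b in st["blocks"]:
                params += b.parameters()
            params += st["norm"].parameters()
        return params

    def named_parameters(self):
        out = {}
        for i, st in enumerate(self.stages):
            for k, p in st["embed"].named_parameters().items():
                out[f"stages.{i}.embed.{k}"] = p
            for j, b in enumerate(st["blocks"]):
                for k, p in b.named_parameters().items():
                    out[f"stages.{i}.blocks.{j}.{k}"] = p
            for k, p in st["norm"].named_parameters().items():
                out[f"stages.{i}.norm.{k}"] = p
        return out

    def __call__(self, x: Tensor) -> FeaturePyramid:
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError(f"input must be at least 32x32, got {x.shape[2:]}")
        levels = []
        for st in self.stages:
            tg = st["embed"](x)
            tokens, grid = tg.tokens, tg.grid_shape
            for block in st["blocks"]:
                tokens = block(tokens, grid)
            tokens = st["norm"](tokens)
            x = tokens_to_grid(tokens, grid)
            levels.append(x)
        return FeaturePyramid(levels=levels)


class Decoder(Module):
    """All-MLP decoder: per-level projection, upsample to 1/4, fuse, classify."""

    def __init__(self, rng, config: ModelConfig):
        d = config.decoder_dim
        self.proj = [Linear(rng, c, d) for c in config.embed_dims]
        self.fuse = Linear(rng, 4 * d, d)
        self.fuse_norm = LayerNorm(d)
        self.classify = Linear(rng, d, config.num_classes)

    def __call__(self, pyramid: FeaturePyramid, out_hw: tuple[int, int]) -> Tensor:
        target = pyramid.levels[0].shape[2:]
        ups = []
        for lv, proj in zip(pyramid.levels, self.proj):
            tokens, grid = grid_to_tokens(lv)
            tokens = proj(tokens)
            g = tokens_to_grid(tokens, grid)
            if g.shape[2:] != target:
                g = ad.bilinear_resize(g, target)
            ups.append(g)
        fused = ad.concat(ups, axis=1)
        tokens, grid = grid_to_tokens(fused)
        tokens = ad.gelu(self.fuse_norm(self.fuse(tokens)))
        logits = self.classify(tokens)
        logits = tokens_to_grid(logits, grid)
        return ad.bilinear_resize(logits, out_hw)


class SegmentationModel(Module):
    """End-to-end network mapping an RGB image batch to per-pixel class logits.

    Inputs whose sides are not divisible by 32 are zero-padded to the next
    multiple before the encoder and the logits are cropped back afterwards,
    so arbitrary sizes >= 32x32 (including 400x500) are supported.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(rng, self.config)
        self.decoder = Decoder(rng, self.config)

    def __call__(self, images) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) input, got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        if H < 32 or W < 32:
            raise ValueError(f"input must be at least 32x32, got {(H, W)}")
        Hp = math.ceil(H / 32) * 32
        Wp = math.ceil(W / 32) * 32
        if (Hp, Wp) != (H, W):
            x = ad.pad2d(x, Hp - H, Wp - W)
        pyramid = self.encoder(x)
        return self.decoder(pyramid, (H, W))

    def named_parameters(self):
        out = {}
        for k, p in self.encoder.named_parameters().items():
            out[f"encoder.{k}"] = p
        for k, p in self.decoder.named_parameters().items():
            out[f"decoder.{k}"] = p
        return out

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()


def images_to_batch(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack H x W x 3 images in [0,1] into a (B, 3, H, W) float32 batch."""
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images]) \
        if isinstance(images, list) else np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def predict(images, model: SegmentationModel, batch_size: int = 4) -> np.ndarray:
    """Per-pixel argmax class labels; ties break toward the lowest index."""
    batch = images_to_batch(images) if not (isinstance(images, np.ndarray) and images.ndim == 4
                                            and images.shape[1] == 3) else images
    masks = []
    with no_grad():
        for i in range(0, batch.shape[0], batch_size):
            logits = model(batch[i:i + batch_size]).data
            masks.append(np.argmax(logits, axis=1).astype(np.uint8))
    return np.concatenate(masks, axis=0)


def predict_mask(image: np.ndarray, model: SegmentationModel) -> np.ndarray:
    """Single-image convenience wrapper around :func:`predict`."""
    return predict([image], model)[0]


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Serialize weights plus a ModelConfig echo into a single .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = json.dumps({"config": dataclasses.asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> SegmentationModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        for k in ("stage_depths", "embed_dims", "num_heads", "reduction_ratios",
                  "patch_kernels", "patch_strides"):
            cfg_dict[k] = tuple(cfg_dict[k])
        model = SegmentationModel(ModelConfig(**cfg_dict), seed=meta["seed"])
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
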