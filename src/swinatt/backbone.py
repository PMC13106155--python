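"""Hierarchical windowed self-attention classifier with the ATT layer.

The backbone follows the standard four-stage shifted-window transformer
design: a patchify stem embeds non-overlapping ``patch_size x patch_size``
pixel patches into ``embed_dim`` channels; each stage applies pre-norm
residual blocks whose self-attention is restricted to ``window_size``-sided
token windows (alternating blocks cyclically shift the grid by half a
window so information crosses window borders); between stages, 2x2 token
neighborhoods are merged, halving the grid and doubling the channels; a
final layer norm, global token average and linear head produce logits.

The bidirectional spatial attention layer (:mod:`swinatt.att`) is inserted
at the entry of the stages listed in ``att_stages`` (1-indexed), operating
on the unflattened ``(B, C, h, w)`` grid.  The default placement is stage
1 only — directly after patch embedding and before token flattening —
which is where the row/column gating acts as a global spatial calibrator
ahead of the purely local window attention.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO

import numpy as np

from .att import ATTConfig, BidirectionalSpatialAttention
from .nn import (
    LayerNorm,
    Linear,
    Mlp,
    Module,
    ModuleList,
    Parameter,
    Tensor,
    as_tensor,
    concat,
    matmul,
    roll,
    softmax,
    take,
    trunc_normal,
)

__all__ = [
    "SwinConfig",
    "SwinTransformer",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
    "flatten_tokens",
    "unflatten_tokens",
    "window_partition",
    "window_reverse",
    "count_parameters",
    "att_param_count",
    "save_checkpoint",
    "load_checkpoint",
]

# (embed_dim, depths, heads) of the published variants
VARIANT_PRESETS = {
    "tiny": (96, (2, 2, 6, 2), (3, 6, 12, 24)),
    "small": (96, (2, 2, 18, 2), (3, 6, 12, 24)),
    "base": (128, (2, 2, 18, 2), (4, 8, 16, 32)),
    "large": (192, (2, 2, 18, 2), (6, 12, 24, 48)),
}


@dataclass(frozen=True)
class SwinConfig:
    """Complete architecture description."""

    image_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: float = 4.0
    num_classes: int = 3
    att_stages: frozenset[int] = frozenset({1})
    att_reduction: int = 32
    variant: str = "tiny"

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError("image_size must be divisible by patch_size")
        if len(self.depths) != len(self.heads):
            raise ValueError("depths and heads must have the same length")
        grid = self.image_size // self.patch_size
        for i in range(len(self.depths)):
            if grid % self.window_size != 0 and grid > self.window_size:
                raise ValueError(
                    f"stage {i + 1} token grid {grid} not divisible by "
                    f"window_size {self.window_size}")
            if i < len(self.depths) - 1:
                if grid % 2 != 0:
                    raise ValueError(f"stage {i + 1} grid {grid} not even; cannot merge")
                grid //= 2
        object.__setattr__(self, "att_stages", frozenset(self.att_stages))
        bad = self.att_stages - set(range(1, len(self.depths) + 1))
        if bad:
            raise ValueError(f"att_stages {sorted(bad)} outside 1..{len(self.depths)}")

    @classmethod
    def from_variant(cls, variant: str, *, image_size: int = 224,
                     num_classes: int = 3, att_stages=frozenset({1}), **kw) -> "SwinConfig":
        embed_dim, depths, heads = VARIANT_PRESETS[variant]
        return cls(image_size=image_size, embed_dim=embed_dim, depths=depths,
                   heads=heads, num_classes=num_classes,
                   att_stages=frozenset(att_stages), variant=variant, **kw)

    @classmethod
    def desk(cls, *, att_stages=frozenset({1}), num_classes: int = 3) -> "SwinConfig":
        """Reduced preset for CPU-scale experiments on 56x56 phantoms."""
        return cls(image_size=56, patch_size=4, embed_dim=24, depths=(1, 1),
                   heads=(2, 4), window_size=7, num_classes=num_classes,
                   att_stages=frozenset(att_stages), variant="desk")

    def stage_dim(self, stage: int) -> int:
        """Channel width at the entry of 1-indexed ``stage``."""
        return self.embed_dim * 2 ** (stage - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["att_stages"] = sorted(self.att_stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SwinConfig":
        d = dict(d)
        d["att_stages"] = frozenset(d.get("att_stages", ()))
        d["depths"] = tuple(d["depths"])
        d["heads"] = tuple(d["heads"])
        return cls(**d)


# ------------------------------------------------------------- token plumbing
def flatten_tokens(features: Tensor) -> Tensor:
    """``(B, C, h, w) -> (B, h*w, C)`` row-major; inverse of
    :func:`unflatten_tokens`."""
    features = as_tensor(features)
    b, c, h, w = features.shape
    return features.reshape(b, c, h * w).transpose(0, 2, 1)


def unflatten_tokens(tokens: Tensor, grid: tuple[int, int]) -> Tensor:
    """``(B, h*w, C) -> (B, C, h, w)``; exact inverse of :func:`flatten_tokens`."""
    tokens = as_tensor(tokens)
    b, length, c = tokens.shape
    h, w = grid
    if length != h * w:
        raise ValueError(f"token count {length} != grid {h}x{w}")
    return tokens.transpose(0, 2, 1).reshape(b, c, h, w)


def window_partition(tokens: Tensor, grid: tuple[int, int], window_size: int) -> Tensor:
    """``(B, h*w, C) -> (B*nW, window_size**2, C)`` non-overlapping blocks."""
    tokens = as_tensor(tokens)
    h, w = grid
    m = window_size
    if h % m or w % m:
        raise ValueError(f"grid {h}x{w} not divisible by window size {m}")
    b, length, c = tokens.shape
    x = tokens.reshape(b, h // m, m, w // m, m, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (h // m) * (w // m), m * m, c)


def window_reverse(windows: Tensor, grid: tuple[int, int], window_size: int) -> Tensor:
    """Inverse of :func:`window_partition` (bit-exact round trip)."""
    windows = as_tensor(windows)
    h, w = grid
    m = window_size
    nw = (h // m) * (w // m)
    b = windows.shape[0] // nw
    c = windows.shape[2]
    x = windows.reshape(b, h // m, w // m, m, m, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, h * w, c)


def _relative_position_index(window_size: int) -> np.ndarray:
    m = window_size
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]          # (2, M^2, M^2)
    rel = rel.transpose(1, 2, 0) + (m - 1)
    return rel[:, :, 0] * (2 * m - 1) + rel[:, :, 1]   # (M^2, M^2)


def _shift_attention_mask(grid: tuple[int, int], window_size: int,
                          shift: int) -> np.ndarray:
    """Additive mask (nW, M^2, M^2): 0 within a region, -100 across regions."""
    h, w = grid
    m = window_size
    img = np.zeros((h, w))
    cnt = 0
    slices = (slice(0, -m), slice(-m, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            img[hs, ws] = cnt
            cnt += 1
    mask_tokens = img.reshape(h // m, m, w // m, m).transpose(0, 2, 1, 3)
    mask_tokens = mask_tokens.reshape(-1, m * m)
    diff = mask_tokens[:, :, None] - mask_tokens[:, None, :]
    return np.where(diff != 0, -100.0, 0.0)


# ------------------------------------------------------------------- layers
class WindowAttention(Module):
    """Multi-head self-attention inside a window with relative position bias."""

    def __init__(self, dim: int, window_size: int, num_heads: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.dim = dim
        self.window_size = window_size
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.relative_position_bias_table = Parameter(
            trunc_normal(rng, ((2 * window_size - 1) ** 2, num_heads)))
        self._rel_index = _relative_position_index(window_size)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        nb, n, c = x.shape
        qkv = self.qkv(x).reshape(nb, n, 3, self.num_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)             # (3, nB, H, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = matmul(q * self.scale, k.transpose(0, 1, 3, 2))  # (nB, H, N, N)
        bias = take(self.relative_position_bias_table,
                    self._rel_index.reshape(-1), axis=0)
        bias = bias.reshape(n, n, self.num_heads).transpose(2, 0, 1)
        attn = attn + bias.reshape(1, self.num_heads, n, n)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(nb // nw, nw, self.num_heads, n, n)
            attn = attn + Tensor(mask[None, :, None, :, :])
            attn = attn.reshape(nb, self.num_heads, n, n)
        attn = softmax(attn, axis=-1)
        out = matmul(attn, v)                          # (nB, H, N, dh)
        out = out.transpose(0, 2, 1, 3).reshape(nb, n, c)
        return self.proj(out)


class SwinBlock(Module):
    """Pre-norm residual block: windowed attention then MLP.

    ``shift > 0`` cyclically rolls the token grid by ``shift`` before
    partitioning (and rolls back after), masking attention across the
    wrapped boundary.  Shift is disabled when the grid fits one window.
    """

    def __init__(self, dim: int, grid: tuple[int, int], num_heads: int,
                 window_size: int, shift: int, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.grid = grid
        if min(grid) <= window_size:
            window_size = min(window_size, min(grid))
            shift = 0
        self.window_size = window_size
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, window_size, num_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)
        self._mask = (_shift_attention_mask(grid, window_size, shift)
                      if shift > 0 else None)

    def forward(self, tokens: Tensor) -> Tensor:
        h, w = self.grid
        b, length, c = tokens.shape
        shortcut = tokens
        x = self.norm1(tokens)
        if self.shift > 0:
            grid_x = x.reshape(b, h, w, c)
            grid_x = roll(grid_x, (-self.shift, -self.shift), (1, 2))
            x = grid_x.reshape(b, length, c)
        windows = window_partition(x, self.grid, self.window_size)
        windows = self.attn(windows, mask=self._mask)
        x = window_reverse(windows, self.grid, self.window_size)
        if self.shift > 0:
            grid_x = x.reshape(b, h, w, c)
            grid_x = roll(grid_x, (self.shift, self.shift), (1, 2))
            x = grid_x.reshape(b, length, c)
        x = shortcut + x
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """Concatenate 2x2 token neighborhoods (4C) and project to 2C."""

    def __init__(self, dim: int, grid: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        if grid[0] % 2 or grid[1] % 2:
            raise ValueError(f"grid {grid} extents must be even to merge")
        self.grid = grid
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, tokens: Tensor) -> Tensor:
        h, w = self.grid
        b, length, c = tokens.shape
        x = tokens.reshape(b, h, w, c)
        x0 = x[:, 0::2, 0::2, :]
        x1 = x[:, 1::2, 0::2, :]
        x2 = x[:, 0::2, 1::2, :]
        x3 = x[:, 1::2, 1::2, :]
        merged = concat([x0, x1, x2, x3], axis=-1)     # (B, h/2, w/2, 4C)
        merged = merged.reshape(b, (h // 2) * (w // 2), 4 * c)
        return self.reduction(self.norm(merged))


class PatchEmbed(Module):
    """Patchify + linear projection, kept in (B, C, h, w) grid form."""

    def __init__(self, config: SwinConfig, rng: np.random.Generator):
        super().__init__()
        p = config.patch_size
        self.patch_size = p
        self.proj = Linear(3 * p * p, config.embed_dim, rng=rng)
        self.grid = (config.image_size // p, config.image_size // p)

    def forward(self, images: Tensor) -> Tensor:
        images = as_tensor(images)
        b, c, hh, ww = images.shape
        p = self.patch_size
        if c != 3:
            raise ValueError(f"expected 3-channel input, got {c}")
        if hh % p or ww % p:
            raise ValueError(f"image size {hh}x{ww} not divisible by patch {p}")
        x = images.reshape(b, c, hh // p, p, ww // p, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)              # (B, h, w, 3, p, p)
        x = x.reshape(b, (hh // p) * (ww // p), c * p * p)
        x = self.proj(x)                               # (B, L, C)
        return unflatten_tokens(x, (hh // p, ww // p))


class SwinTransformer(Module):
    """The full classifier; see module docstring for the data flow."""

    def __init__(self, config: SwinConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.patch_embed = PatchEmbed(config, rng)
        self.norm_embed = LayerNorm(config.embed_dim)
        grid = self.patch_embed.grid

        self.att_layers = ModuleList()
        self.stages = ModuleList()
        self.mergers = ModuleList()
        self._stage_grids: list[tuple[int, int]] = []
        num_stages = len(config.depths)
        for i in range(num_stages):
            dim = config.stage_dim(i + 1)
            self._stage_grids.append(grid)
            if (i + 1) in config.att_stages:
                att_seed = int(rng.integers(0, 2 ** 31 - 1))
                self.att_layers.append(BidirectionalSpatialAttention(
                    ATTConfig(inp=dim, reduction=config.att_reduction), seed=att_seed))
            else:
                self.att_layers.append(Module())  # placeholder, no parameters
            blocks = ModuleList()
            for j in range(config.depths[i]):
                shift = 0 if j % 2 == 0 else config.window_size // 2
                blocks.append(SwinBlock(dim, grid, config.heads[i],
                                        config.window_size, shift,
                                        config.mlp_ratio, rng))
            self.stages.append(blocks)
            if i < num_stages - 1:
                self.mergers.append(PatchMerging(dim, grid, rng))
                grid = (grid[0] // 2, grid[1] // 2)
        self.norm = LayerNorm(config.stage_dim(num_stages))
        self.head = Linear(config.stage_dim(num_stages), config.num_classes, rng=rng)

    # ---------------------------------------------------------------- parts
    def apply_att(self, features: Tensor, stage: int) -> Tensor:
        """Apply the stage's ATT layer to a (B, C, h, w) grid; no-op if the
        stage carries none."""
        if (stage) in self.config.att_stages:
            layer = self.att_layers[stage - 1]
            layer.train(self.training)
            return layer(features)
        return as_tensor(features)

    def classify(self, tokens: Tensor) -> Tensor:
        """Global token average then the linear head."""
        pooled = self.norm(tokens).mean(axis=1)
        return self.head(pooled)

    def forward(self, images) -> Tensor:
        features = self.patch_embed(as_tensor(images))  # (B, C, h, w)
        tokens = None
        for i in range(len(self.config.depths)):
            grid = self._stage_grids[i]
            if (i + 1) in self.config.att_stages:
                if tokens is not None:
                    features = unflatten_tokens(tokens, grid)
                features = self.apply_att(features, i + 1)
                tokens = flatten_tokens(features)
            elif tokens is None:
                tokens = flatten_tokens(features)
            if i == 0:
                tokens = self.norm_embed(tokens)
            for block in self.stages[i]:
                tokens = block(tokens)
            if i < len(self.config.depths) - 1:
                tokens = self.mergers[i](tokens)
        return self.classify(tokens)

    def predict(self, images, batch_size: int = 32) -> np.ndarray:
        """Eval-mode argmax labels for an (N, 3, S, S) array."""
        self.eval()
        images = np.asarray(images, dtype=np.float64)
        out = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(Tensor(images[start:start + batch_size]))
            out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)


# -------------------------------------------------------------- accounting
def att_param_count(channels: int, reduction: int = 32) -> int:
    """Learnable scalars of one ATT layer at the given channel width."""
    cfg = ATTConfig(inp=channels, reduction=reduction)
    conv1 = cfg.inp * cfg.mip
    bn = 2 * cfg.mip
    branches = 2 * (cfg.mip * cfg.oup + cfg.oup)
    return conv1 + bn + branches


def count_parameters(config: SwinConfig) -> int:
    """Exact learnable-scalar count of the architecture, by closed-form
    accounting over its layers (cross-checked against instantiation in the
    test suite)."""
    c = config.embed_dim
    p = config.patch_size
    m = config.window_size
    grid = config.image_size // p
    total = 3 * p * p * c + c          # patch projection
    total += 2 * c                     # post-embed layer norm
    num_stages = len(config.depths)
    for i in range(num_stages):
        dim = config.stage_dim(i + 1)
        win = min(m, grid)
        hidden = int(dim * config.mlp_ratio)
        per_block = (
            2 * dim                            # norm1
            + dim * 3 * dim + 3 * dim          # qkv
            + dim * dim + dim                  # attention projection
            + (2 * win - 1) ** 2 * config.heads[i]  # relative position bias
            + 2 * dim                          # norm2
            + dim * hidden + hidden            # mlp fc1
            + hidden * dim + dim               # mlp fc2
        )
        total += config.depths[i] * per_block
        if (i + 1) in config.att_stages:
            total += att_param_count(dim, config.att_reduction)
        if i < num_stages - 1:
            total += 2 * (4 * dim) + 4 * dim * 2 * dim  # merging norm + reduction
            grid //= 2
    final_dim = config.stage_dim(num_stages)
    total += 2 * final_dim                             # final norm
    total += final_dim * config.num_classes + config.num_classes
    return total


# ------------------------------------------------------------ serialization
def save_checkpoint(path, model: SwinTransformer) -> None:
    """Single-archive checkpoint: config as JSON + parameter state."""
    state = model.state_dict()
    buf = BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(model.config.to_dict()))
        zf.writestr("state.npz", buf.getvalue())


def load_checkpoint(path) -> SwinTransformer:
    with zipfile.ZipFile(path) as zf:
        config = SwinConfig.from_dict(json.loads(zf.read("config.json")))
        with np.load(BytesIO(zf.read("state.npz"))) as npz:
            state = {k: npz[k] for k in npz.files}
    model = SwinTransformer(config, seed=0)
    model.load_state_dict(state)
    return model
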