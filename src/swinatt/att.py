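"""Bidirectional spatial attention (ATT).

The module recalibrates a feature map ``x`` of shape ``(n, c, h, w)`` by
direction-aware pooling: the map is averaged over the width axis (giving a
per-row descriptor ``x_h`` of shape ``(n, c, h, 1)``) and over the height
axis (a per-column descriptor ``x_w``, permuted to ``(n, c, w, 1)``).  The
two descriptors are concatenated along the pooled axis, compressed by a
1x1 convolution to ``mip`` channels, batch-normalized, passed through the
hard-swish nonlinearity, split back into a height and a width branch, and
expanded by independent 1x1 convolutions followed by a sigmoid into
per-row weights ``x_h''`` in (0,1) and per-column weights ``x_w''``.  The
output is the broadcast product

    y(i, j) = x(i, j) * x_h''(i) * x_w''(j)

applied per batch element and channel, so rows and columns that carry
salient structure (in brain MRI: e.g. the rows crossing the ventricles or
the cortical band) are emphasized while others are damped.  Because every
weight is strictly below 1, the map is never amplified, only re-weighted.

The layer is backbone-agnostic: any architecture producing an
``(n, c, h, w)`` map can insert it in place (``oup == inp``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Module,
    Parameter,
    Tensor,
    as_tensor,
    concat,
    h_swish_t,
    matmul,
    sigmoid,
)

__all__ = [
    "ATTConfig",
    "BidirectionalSpatialAttention",
    "pool_height",
    "pool_width",
    "h_sigmoid",
    "h_swish",
    "compute_attention",
    "att_forward",
    "init_params",
]


def _validate_feature_map(x) -> None:
    if x.ndim != 4:
        raise ValueError(f"feature map must be 4-D (n, c, h, w), got ndim={x.ndim}")
    if min(x.shape) < 1:
        raise ValueError(f"all feature-map extents must be >= 1, got {x.shape}")


def pool_height(x):
    """Average over the width axis: ``(n, c, h, w) -> (n, c, h, 1)``.

    Entry ``(i, j, r, 0)`` is the arithmetic mean of row ``r``.
    """
    x = as_tensor(x)
    _validate_feature_map(x)
    return x.mean(axis=3, keepdims=True)


def pool_width(x):
    """Average over the height axis, permuted to ``(n, c, w, 1)``.

    Entry ``(i, j, k, 0)`` is the arithmetic mean of column ``k``; the
    pooled axis is moved to the third slot so the result can be stacked
    with :func:`pool_height` along that axis.
    """
    x = as_tensor(x)
    _validate_feature_map(x)
    return x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)


def h_sigmoid(x):
    """Hard sigmoid, ``ReLU6(x + 3) / 6`` — a piecewise-linear sigmoid.

    Saturates at 0 for ``x <= -3`` and 1 for ``x >= 3``; 0.5 at 0.
    Accepts scalars, numpy arrays or autodiff tensors.
    """
    if isinstance(x, Tensor):
        from .nn import h_sigmoid_t

        return h_sigmoid_t(x)
    return np.clip((np.asarray(x, dtype=np.float64) + 3.0) / 6.0, 0.0, 1.0)


def h_swish(x):
    """Hard swish, ``x * h_sigmoid(x)`` — cheap smooth-ish gating.

    Identity for ``x >= 3``, zero for ``x <= -3``.
    """
    if isinstance(x, Tensor):
        return h_swish_t(x)
    arr = np.asarray(x, dtype=np.float64)
    return arr * h_sigmoid(arr)


@dataclass(frozen=True)
class ATTConfig:
    """Hyperparameters of the attention layer.

    ``mip = max(8, inp // reduction)`` is the bottleneck width of the
    shared 1x1 compression convolution; ``oup`` equals ``inp`` so the
    layer can be used in place inside a backbone.
    """

    inp: int
    reduction: int = 32
    oup: int = field(default=0)
    mip: int = field(default=0)

    def __post_init__(self):
        if self.inp < 1 or self.reduction < 1:
            raise ValueError("inp and reduction must be positive")
        object.__setattr__(self, "oup", self.oup or self.inp)
        object.__setattr__(self, "mip", max(8, self.inp // self.reduction))


def _conv1x1(x: Tensor, weight: Parameter, bias: Parameter | None) -> Tensor:
    """1x1 convolution on an (n, c, h, w) tensor via a channel matmul."""
    moved = x.transpose(0, 2, 3, 1)
    out = matmul(moved, weight.transpose(1, 0))
    if bias is not None:
        out = out + bias
    return out.transpose(0, 3, 1, 2)


class BidirectionalSpatialAttention(Module):
    """The ATT layer: pooled row/column descriptors -> per-axis gates.

    Parameters
    ----------
    config:
        Channel bookkeeping (``inp``, ``oup``, ``reduction``, ``mip``).
    seed:
        Seeds the parameter initialization; the same seed yields
        bit-identical parameters.
    """

    def __init__(self, config: ATTConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        inp, mip, oup = config.inp, config.mip, config.oup
        # compression conv has no bias (normalization follows it)
        self.conv1_weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / inp), (mip, inp)))
        self.bn1 = BatchNorm2d(mip)
        self.conv_h_weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / mip), (oup, mip)))
        self.conv_h_bias = Parameter(np.zeros(oup))
        self.conv_w_weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / mip), (oup, mip)))
        self.conv_w_bias = Parameter(np.zeros(oup))

    # ----------------------------------------------------------------- core
    def compute_attention(self, x) -> tuple[Tensor, Tensor]:
        """Return (height weights (n, oup, h, 1), width weights (n, oup, 1, w))."""
        x = as_tensor(x)
        _validate_feature_map(x)
        if x.shape[1] != self.config.inp:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, "
                f"layer expects {self.config.inp}")
        n, c, h, w = x.shape
        pooled = concat([pool_height(x), pool_width(x)], axis=2)  # (n, c, h+w, 1)
        y = _conv1x1(pooled, self.conv1_weight, None)
        y = self.bn1(y)
        y = h_swish_t(y)
        y_h = y[:, :, :h, :]                       # (n, mip, h, 1)
        y_w = y[:, :, h:, :]                       # (n, mip, w, 1)
        a_h = sigmoid(_conv1x1(y_h, self.conv_h_weight, self.conv_h_bias))
        a_w = sigmoid(_conv1x1(y_w, self.conv_w_weight, self.conv_w_bias))
        return a_h, a_w.transpose(0, 1, 3, 2)      # (n, oup, h, 1), (n, oup, 1, w)

    def forward(self, x) -> Tensor:
        """Re-weight ``x`` by the broadcast product of both gates."""
        x = as_tensor(x)
        a_h, a_w = self.compute_attention(x)
        return x * a_h * a_w


# ----------------------------------------------------- functional interface
def init_params(config: ATTConfig, seed: int = 0) -> BidirectionalSpatialAttention:
    """Construct an ATT layer with reproducible parameters."""
    return BidirectionalSpatialAttention(config, seed=seed)


def compute_attention(x, layer: BidirectionalSpatialAttention,
                      train: bool = False) -> tuple[Tensor, Tensor]:
    layer.train(train)
    return layer.compute_attention(x)


def att_forward(x, layer: BidirectionalSpatialAttention, train: bool = False) -> Tensor:
    """Apply the layer to a feature map; output shape equals input shape."""
    layer.train(train)
    return layer(x)
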