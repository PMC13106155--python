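"""Medically-constrained stochastic augmentation and class balancing.

The policy draws a short random sequence of geometric (rotation bounded
at +-30 degrees, translation, shear) and intensity (brightness, contrast,
solarize) operations per image.  Erasing/cutout-style operations are
forbidden by construction: on small-lesion medical images they can delete
the very biomarker the label depends on.  Geometric operations use
bilinear interpolation with reflective padding so no empty corners are
introduced.

Minority-class balancing generates augmented variants — never bare
copies — of each minority image, with integer per-class expansion factors
chosen to bring the class ratio close to 1:1:1.  Expansion is a
training-set operation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import LabeledImage

__all__ = [
    "AugmentationPolicy",
    "BalancePlan",
    "FORBIDDEN_OPS",
    "random_augment",
    "expand_minority",
    "build_balance_plan",
    "audit_policy",
]

FORBIDDEN_OPS = frozenset({"erase", "cutout", "random_erasing"})
_GEOMETRIC_OPS = ("rotation", "translation", "shear")
_INTENSITY_OPS = ("brightness", "contrast", "solarize")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Ranges of the stochastic augmentation operations.

    ``ops_per_image`` operations are drawn uniformly (with replacement)
    from the union of enabled geometric and intensity ops and applied in
    sequence with parameters uniform in their ranges.
    """

    rotation_deg: float = 30.0            # magnitude bound, degrees
    translation_frac: float = 0.10        # fraction of the image side
    shear_deg: float = 10.0
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    solarize_threshold_range: tuple[int, int] = (128, 255)
    ops_per_image: int = 2
    extra_ops: tuple[str, ...] = ()       # names of additional (custom) ops

    def __post_init__(self):
        if abs(self.rotation_deg) > 30.0:
            raise ValueError("rotation bound must not exceed 30 degrees in magnitude")
        forbidden = {op.lower() for op in self.extra_ops} & FORBIDDEN_OPS
        if forbidden:
            raise ValueError(f"forbidden augmentation ops: {sorted(forbidden)}")
        if self.ops_per_image < 1:
            raise ValueError("ops_per_image must be >= 1")

    @property
    def op_names(self) -> tuple[str, ...]:
        return _GEOMETRIC_OPS + _INTENSITY_OPS + self.extra_ops

    def is_identity(self) -> bool:
        return (self.rotation_deg == 0 and self.translation_frac == 0
                and self.shear_deg == 0
                and self.brightness_range == (1.0, 1.0)
                and self.contrast_range == (1.0, 1.0)
                and self.solarize_threshold_range[0] > 255)


@dataclass(frozen=True)
class BalancePlan:
    """Integer expansion factor per class (>= 1 each)."""

    factors: dict[str, int]
    achieved_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if any(f < 1 for f in self.factors.values()):
            raise ValueError("expansion factors must be >= 1")


def _geometric(pixels: np.ndarray, matrix_params: dict) -> np.ndarray:
    """Affine warp (HW or HWC uint8) with bilinear interpolation and
    reflective padding, rotation/shear about the image center."""
    angle = math.radians(matrix_params.get("angle", 0.0))
    shear = math.radians(matrix_params.get("shear", 0.0))
    dy = matrix_params.get("dy", 0.0)
    dx = matrix_params.get("dx", 0.0)
    cos_a, sin_a = math.cos(angle), math.sin(angle)
    # output->input mapping: rotate, then shear along x
    mat = np.array([[cos_a, -sin_a],
                    [sin_a, cos_a]]) @ np.array([[1.0, math.tan(shear)],
                                                 [0.0, 1.0]])
    h, w = pixels.shape[:2]
    center = np.array([(h - 1) / 2, (w - 1) / 2])
    offset = center - mat @ center + np.array([dy, dx])

    def warp_plane(plane):
        return ndimage.affine_transform(plane.astype(np.float64), mat,
                                        offset=offset, order=1, mode="reflect")

    if pixels.ndim == 2:
        out = warp_plane(pixels)
    else:
        out = np.stack([warp_plane(pixels[:, :, c])
                        for c in range(pixels.shape[2])], axis=2)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def _apply_op(pixels: np.ndarray, op: str, policy: AugmentationPolicy,
              rng: np.random.Generator) -> np.ndarray:
    if op == "rotation":
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
        return _geometric(pixels, {"angle": angle})
    if op == "translation":
        side = pixels.shape[0]
        limit = policy.translation_frac * side
        return _geometric(pixels, {"dy": rng.uniform(-limit, limit),
                                   "dx": rng.uniform(-limit, limit)})
    if op == "shear":
        return _geometric(pixels, {"shear": rng.uniform(-policy.shear_deg,
                                                        policy.shear_deg)})
    arr = pixels.astype(np.float64)
    if op == "brightness":
        factor = rng.uniform(*policy.brightness_range)
        arr = arr * factor
    elif op == "contrast":
        factor = rng.uniform(*policy.contrast_range)
        arr = arr.mean() + factor * (arr - arr.mean())
    elif op == "solarize":
        lo, hi = policy.solarize_threshold_range
        threshold = rng.uniform(lo, hi)
        arr = np.where(arr >= threshold, 255.0 - arr, arr)
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def random_augment(pixels: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply ``policy.ops_per_image`` randomly drawn operations in sequence.

    Deterministic given the generator state; spatial size is preserved.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint8:
        raise ValueError("expected uint8 pixels")
    if policy.is_identity():
        return pixels.copy()
    ops = rng.choice(len(policy.op_names), size=policy.ops_per_image)
    out = pixels
    for op_index in ops:
        out = _apply_op(out, policy.op_names[int(op_index)], policy, rng)
    return out


def expand_minority(items: list[LabeledImage], factor: int,
                    policy: AugmentationPolicy, seed: int = 0) -> list[LabeledImage]:
    """``factor`` augmented variants per source image (sources not included).

    Every variant passes through :func:`random_augment`; labels and
    subject ids are inherited so patient-level guarantees survive
    expansion.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not items:
        raise ValueError("cannot expand an empty class")
    rng = np.random.default_rng(seed)
    out: list[LabeledImage] = []
    for item in items:
        for _ in range(factor):
            out.append(LabeledImage(pixels=random_augment(item.pixels, policy, rng),
                                    label=item.label, subject_id=item.subject_id,
                                    augmented=True))
    return out


def build_balance_plan(counts: dict[str, int], target: int | None = None) -> BalancePlan:
    """Integer per-class factors approximating a 1:1:1 post-expansion ratio.

    The target is the maximum class count (or ``target``).  A class
    already within 10% of the target is left alone (factor 1); an
    underrepresented class receives the ceiling of ``target / count``
    (the convention that turns 52 minority images into 52*50 variants
    against a ~2600-image majority).  With very coarse counts the
    achieved ratio can exceed 10%; the plan records what was achieved.
    """
    if any(c <= 0 for c in counts.values()):
        raise ValueError("class counts must be positive")
    goal = target or max(counts.values())
    factors, achieved = {}, {}
    for label, count in counts.items():
        factor = 1 if count >= 0.9 * goal else max(1, math.ceil(goal / count))
        factors[label] = factor
        achieved[label] = factor * count
    return BalancePlan(factors=factors, achieved_counts=achieved)


def audit_policy(policy: AugmentationPolicy) -> dict:
    """Walk the op inventory and report the constraint audit."""
    return {
        "ops": list(policy.op_names),
        "forbidden_present": sorted({o.lower() for o in policy.op_names}
                                    & FORBIDDEN_OPS),
        "rotation_bound_ok": abs(policy.rotation_deg) <= 30.0,
    }
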