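"""Dataset ingestion, patient-level splitting and the synthetic phantom generator.

Real data enters as class-labelled image folders (PNG/JPEG) with an
optional CSV sidecar mapping each file to a subject identifier; the
synthetic generator materializes the same structures in memory (or on
disk in the identical layout), so every downstream stage runs unchanged
on either source.

The staging task is three-class: NonDemented / MildDemented /
ModerateDemented, with the very-mild category folded into mild at
ingestion.  Splitting is performed over subjects, never images, so no
individual contributes scans to more than one partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "CLASSES",
    "RAW_CLASSES",
    "LabeledImage",
    "DatasetSplit",
    "SyntheticSpec",
    "merge_labels",
    "label_index",
    "patient_level_split",
    "load_image_folder",
    "resize_image",
    "normalize_standardize",
    "inverse_normalize",
    "generate_synthetic_dataset",
    "materialize_dataset",
    "central_region_mean",
]

CLASSES = ("NonDemented", "MildDemented", "ModerateDemented")
RAW_CLASSES = ("NonDemented", "VeryMildDemented", "MildDemented", "ModerateDemented")

# ImageNet channel statistics applied after scaling pixels to [0, 1]
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406])
CHANNEL_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class LabeledImage:
    """A single 2-D scan slice with its class label and subject identity."""

    pixels: np.ndarray          # uint8, (H, W) or (H, W, 3)
    label: str
    subject_id: str
    augmented: bool = False

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not in {CLASSES}")
        arr = np.asarray(self.pixels)
        if arr.dtype != np.uint8:
            raise ValueError("pixels must be uint8 in [0, 255]")
        self.pixels = arr

    def rgb(self) -> np.ndarray:
        """(H, W, 3) uint8; grayscale replicated across channels."""
        if self.pixels.ndim == 2:
            return np.repeat(self.pixels[:, :, None], 3, axis=2)
        return self.pixels


@dataclass
class DatasetSplit:
    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]
    split_seed: int

    def subject_sets(self) -> tuple[set, set, set]:
        return ({i.subject_id for i in self.train},
                {i.subject_id for i in self.val},
                {i.subject_id for i in self.test})


def merge_labels(raw_label: str) -> str:
    """Fold VeryMildDemented into MildDemented; pass the rest through."""
    if raw_label not in RAW_CLASSES:
        raise ValueError(f"unknown label {raw_label!r}; expected one of {RAW_CLASSES}")
    return "MildDemented" if raw_label == "VeryMildDemented" else raw_label


def label_index(label: str) -> int:
    return CLASSES.index(label)


def patient_level_split(items: list[LabeledImage], ratios=(8, 1, 1),
                        seed: int = 0, stratify: bool = False) -> DatasetSplit:
    """Subject-disjoint 8:1:1 split: subjects are shuffled by ``seed`` and
    assigned to partitions by cumulative ratio; every image follows its
    subject.

    With ``stratify=True`` the subject split is performed within each
    class and the partitions merged, so every class is represented in
    every partition when it has enough subjects (useful when a rare
    class would otherwise vanish from a small test set); subjects must
    then be single-class, which the check below enforces implicitly by
    splitting a subject's images with its first-seen label group.
    """
    for item in items:
        if not item.subject_id:
            raise ValueError("every item needs a subject_id for patient-level splitting")
    if stratify:
        by_label: dict[str, list[LabeledImage]] = {}
        for item in items:
            by_label.setdefault(item.label, []).append(item)
        parts: list[list[LabeledImage]] = [[], [], []]
        for label in sorted(by_label):
            sub = patient_level_split(by_label[label], ratios, seed)
            for bucket, grp in zip(parts, (sub.train, sub.val, sub.test)):
                bucket.extend(grp)
        return DatasetSplit(train=parts[0], val=parts[1], test=parts[2],
                            split_seed=seed)
    by_subject: dict[str, list[LabeledImage]] = {}
    for item in items:
        by_subject.setdefault(item.subject_id, []).append(item)
    subjects = sorted(by_subject)
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    fractions = np.cumsum(ratios) / np.sum(ratios)
    cuts = np.floor(fractions * len(subjects)).astype(int)
    groups = (subjects[:cuts[0]], subjects[cuts[0]:cuts[1]], subjects[cuts[1]:])
    parts = [[img for s in grp for img in by_subject[s]] for grp in groups]
    return DatasetSplit(train=parts[0], val=parts[1], test=parts[2], split_seed=seed)


def load_image_folder(root, sidecar: str | Path | None = None) -> list[LabeledImage]:
    """Read ``root/<raw_label>/*.png|jpg`` into labelled items.

    A sidecar CSV with columns (filename, subject_id[, raw_label])
    overrides per-file metadata; without one the subject id falls back to
    the filename stem.  Unreadable files are skipped with a warning; an
    empty class directory is an error.
    """
    root = Path(root)
    mapping: dict[str, dict] = {}
    if sidecar is not None:
        table = pd.read_csv(sidecar)
        mapping = {str(r["filename"]): dict(r) for _, r in table.iterrows()}
    items: list[LabeledImage] = []
    class_dirs = [d for d in sorted(root.iterdir()) if d.is_dir()]
    for class_dir in class_dirs:
        raw_label = class_dir.name
        count = 0
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            try:
                with Image.open(path) as img:
                    pixels = np.asarray(img.convert("RGB"))
            except Exception as exc:  # unreadable file: log and move on
                warnings.warn(f"skipping unreadable image {path}: {exc}")
                continue
            meta = mapping.get(path.name, {})
            subject = str(meta.get("subject_id", path.stem))
            label = merge_labels(str(meta.get("raw_label", raw_label)))
            items.append(LabeledImage(pixels=pixels, label=label, subject_id=subject))
            count += 1
        if count == 0:
            raise ValueError(f"class directory {class_dir} contains no readable images")
    return items


def resize_image(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an (H, W[, 3]) uint8 image to (size, size[, 3])."""
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels
    img = Image.fromarray(pixels)
    return np.asarray(img.resize((size, size), Image.BILINEAR))


def normalize_standardize(pixels: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] then standardize per channel; (H, W, 3) -> (3, H, W).

    ``y_c = (x_c / 255 - mean_c) / std_c`` with the ImageNet statistics.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) input, got shape {pixels.shape}")
    scaled = pixels.astype(np.float64) / 255.0
    out = (scaled - CHANNEL_MEAN) / CHANNEL_STD
    return out.transpose(2, 0, 1)


def inverse_normalize(array: np.ndarray) -> np.ndarray:
    """Invert :func:`normalize_standardize` back to the [0, 1] scale."""
    if array.ndim != 3 or array.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) input, got shape {array.shape}")
    chw = array.transpose(1, 2, 0)
    return chw * CHANNEL_STD + CHANNEL_MEAN


# ------------------------------------------------------------------ phantoms
@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the three-class brain-phantom generator.

    Each image is an elliptical bright "brain" on a dark background with
    an outer bright "cortical" band and a central dark "ventricle"
    ellipse.  Disease severity is emulated geometrically: the ventricle
    radius (as a fraction of image size) grows and the cortical band
    thins from NonDemented through ModerateDemented, mirroring the
    ventricular enlargement and cortical thinning that drive the real
    staging task.  Gaussian intensity noise and small pose jitter
    (rotation and translation) emulate acquisition variability.
    """

    n_per_class: int = 60
    image_size: int = 224
    ventricle_radius_by_class: tuple[float, float, float] = (0.08, 0.16, 0.26)
    cortical_thickness_by_class: tuple[float, float, float] = (0.12, 0.08, 0.04)
    noise_sd: float = 8.0
    rotation_jitter_deg: float = 5.0
    translation_jitter_frac: float = 0.02
    images_per_subject: int = 3
    seed: int = 0

    def __post_init__(self):
        r = self.ventricle_radius_by_class
        t = self.cortical_thickness_by_class
        if not all(x > 0 for x in r + t):
            raise ValueError("radii and thicknesses must be positive")
        if not (r[0] < r[1] < r[2]):
            raise ValueError("ventricle radii must strictly increase with severity")
        if not (t[0] > t[1] > t[2]):
            raise ValueError("cortical thickness must strictly decrease with severity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def with_size(self, image_size: int) -> "SyntheticSpec":
        return replace(self, image_size=image_size)


# rendered gray levels
_BACKGROUND, _TISSUE, _CORTEX, _VENTRICLE = 15.0, 150.0, 225.0, 35.0


def _render_phantom(spec: SyntheticSpec, severity: int,
                    rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    angle = np.deg2rad(rng.uniform(-spec.rotation_jitter_deg,
                                   spec.rotation_jitter_deg))
    max_shift = spec.translation_jitter_frac * s
    cx = (s - 1) / 2 + rng.uniform(-max_shift, max_shift)
    cy = (s - 1) / 2 + rng.uniform(-max_shift, max_shift)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    # rotate coordinates about the jittered center
    xr = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    yr = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)

    ax_out, ay_out = 0.42 * s, 0.36 * s
    thickness = spec.cortical_thickness_by_class[severity] * s
    brain = (xr / ax_out) ** 2 + (yr / ay_out) ** 2 <= 1.0
    inner = ((xr / (ax_out - thickness)) ** 2
             + (yr / (ay_out - thickness)) ** 2) <= 1.0
    r = spec.ventricle_radius_by_class[severity] * s
    ventricle = (xr / r) ** 2 + (yr / (0.8 * r)) ** 2 <= 1.0

    img = np.full((s, s), _BACKGROUND)
    img[brain] = _CORTEX
    img[inner] = _TISSUE
    img[ventricle & inner] = _VENTRICLE
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_synthetic_dataset(spec: SyntheticSpec) -> list[LabeledImage]:
    """Deterministically draw ``n_per_class`` phantoms per class.

    Consecutive images share a synthetic subject (``images_per_subject``
    scans each, emulating repeat sessions), and the label is a property
    of the subject, so patient-level splitting is exercised realistically.
    """
    rng = np.random.default_rng(spec.seed)
    items: list[LabeledImage] = []
    for severity, label in enumerate(CLASSES):
        for i in range(spec.n_per_class):
            subject = f"syn-{label}-{i // spec.images_per_subject:04d}"
            pixels = _render_phantom(spec, severity, rng)
            items.append(LabeledImage(pixels=pixels, label=label,
                                      subject_id=subject))
    return items


def materialize_dataset(items: list[LabeledImage], root) -> Path:
    """Write items as a class-folder tree + sidecar CSV (the reader's layout)."""
    root = Path(root)
    records = []
    counters: dict[str, int] = {}
    for item in items:
        class_dir = root / item.label
        class_dir.mkdir(parents=True, exist_ok=True)
        k = counters.get(item.label, 0)
        counters[item.label] = k + 1
        name = f"{item.label.lower()}_{k:05d}.png"
        Image.fromarray(item.pixels).save(class_dir / name)
        records.append({"filename": name, "subject_id": item.subject_id,
                        "raw_label": item.label})
    pd.DataFrame(records).to_csv(root / "subjects.csv", index=False)
    return root


def central_region_mean(pixels: np.ndarray, fraction: float = 0.25) -> float:
    """Mean intensity of the central ``fraction``-sided square — a scalar
    severity proxy (larger dark ventricle -> lower value)."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    h, w = arr.shape
    dh, dw = int(h * fraction / 2), int(w * fraction / 2)
    return float(arr[h // 2 - dh:h // 2 + dh, w // 2 - dw:w // 2 + dw].mean())
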