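"""Label-driven ROI cropping, resizing, normalisation and CV fold splitting.

The pipeline mirrors the common two-stage clinical workflow: the annotated
lesion mask localises a region of interest, the crop (plus a safety margin)
is resized to the network input size, intensities are normalised, and
patients are partitioned into k cross-validation folds with a validation
carve-out taken from each fold's training portion.

Coordinates are 0-based with half-open ``[min, max)`` boxes so they compose
directly with array slicing.  Masks are always resized nearest-neighbour to
stay binary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import DatasetManifest, ImagePair, ManifestRecord, save_image, save_mask

__all__ = [
    "ROIBox",
    "FoldSplit",
    "EmptyMaskError",
    "bounding_box",
    "crop_roi",
    "pad_to_square",
    "resize_pair",
    "normalize",
    "preprocess_pair",
    "preprocess_dataset",
    "make_folds",
    "folds_to_json",
]


class EmptyMaskError(ValueError):
    """Raised when an operation requires a lesion but the label is empty."""


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned box, 0-based, half-open: rows [row_min, row_max), cols alike."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate ROI box {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    test_patients: tuple[str, ...]


def bounding_box(mask: np.ndarray) -> ROIBox:
    """Tightest half-open box containing every foreground pixel."""
    mask = np.asarray(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("no lesion in label: mask has no foreground pixels")
    return ROIBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def crop_roi(pair: ImagePair, box: ROIBox, margin_frac: float = 0.25) -> ImagePair:
    """Crop image and mask to ``box`` expanded by ``margin_frac`` of the box
    side on each edge, clamped to the image bounds."""
    h, w = pair.shape
    if box.row_max > h or box.col_max > w:
        raise ValueError(f"box {box} exceeds image bounds {(h, w)}")
    mr = int(round(margin_frac * box.height))
    mc = int(round(margin_frac * box.width))
    r0 = max(box.row_min - mr, 0)
    r1 = min(box.row_max + mr, h)
    c0 = max(box.col_min - mc, 0)
    c1 = min(box.col_max + mc, w)
    return ImagePair(pair.image[r0:r1, c0:c1].copy(), pair.mask[r0:r1, c0:c1].copy(), dict(pair.meta))


def pad_to_square(pair: ImagePair, fill: float = 0.0) -> ImagePair:
    """Symmetrically pad the shorter axis so the pair becomes square
    (aspect-preserving alternative to the default direct stretch)."""
    h, w = pair.shape
    side = max(h, w)
    pr, pc = side - h, side - w
    pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
    return ImagePair(
        np.pad(pair.image, pad, constant_values=fill),
        np.pad(pair.mask, pad, constant_values=0),
        dict(pair.meta),
    )


def resize_pair(pair: ImagePair, target: int, keep_aspect: bool = False) -> ImagePair:
    """Resize to ``target``x``target``: bilinear for the image,
    nearest-neighbour for the mask (preserves binarity).

    ``keep_aspect=True`` pads to square first instead of stretching."""
    if target < 16:
        raise ValueError("target size must be >= 16")
    if keep_aspect:
        pair = pad_to_square(pair)
    image = _sk_resize(
        pair.image.astype(np.float64), (target, target),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True,
    ).astype(np.float32)
    mask = _sk_resize(
        pair.mask, (target, target),
        order=0, mode="edge", anti_aliasing=False, preserve_range=True,
    ).astype(np.uint8)
    return ImagePair(image, mask, dict(pair.meta))


def normalize(image: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Intensity normalisation; constant images map to all zeros."""
    x = np.asarray(image, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("image contains non-finite values")
    if method == "minmax":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x, dtype=np.float32)
        return ((x - lo) / (hi - lo)).astype(np.float32)
    if method == "zscore":
        if x.max() == x.min():  # constant image: sd is (numerically) zero
            return np.zeros_like(x, dtype=np.float32)
        return ((x - x.mean()) / x.std()).astype(np.float32)
    raise ValueError(f"unknown normalisation method {method!r}")


def preprocess_pair(
    pair: ImagePair,
    target_size: int = 512,
    margin_frac: float = 0.25,
    method: str = "minmax",
) -> ImagePair:
    """ROI crop (label-driven) -> resize -> normalise, as one step."""
    box = bounding_box(pair.mask)
    cropped = crop_roi(pair, box, margin_frac)
    resized = resize_pair(cropped, target_size)
    return ImagePair(normalize(resized.image, method), resized.mask, dict(resized.meta))


def preprocess_dataset(
    manifest: DatasetManifest,
    out_dir: Path | str,
    target_size: int = 512,
    margin_frac: float = 0.25,
    method: str = "minmax",
) -> DatasetManifest:
    """Apply :func:`preprocess_pair` to every record, writing a new dataset.

    Normalised intensities are re-scaled per-image to [0, 1] for 16-bit PNG
    storage (z-scored images are min-max mapped for disk only)."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for rec in manifest.records:
        pair = preprocess_pair(manifest.load_pair(rec), target_size, margin_frac, method)
        image = pair.image
        lo, hi = image.min(), image.max()
        disk = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
        image_rel = f"images/{rec.patient_id}_{rec.slice_id}.png"
        mask_rel = f"masks/{rec.patient_id}_{rec.slice_id}.png"
        save_image(out_dir / image_rel, disk)
        save_mask(out_dir / mask_rel, pair.mask)
        records.append(ManifestRecord(rec.patient_id, rec.slice_id, image_rel, mask_rel, rec.class_label))
    out = DatasetManifest(records, out_dir)
    out.to_csv(out_dir / "manifest.csv")
    return out


def make_folds(
    patients: DatasetManifest | list[str],
    k: int = 3,
    val_frac: float = 0.2,
    seed: int = 0,
) -> list[FoldSplit]:
    """Patient-grouped k-fold partition with a validation carve-out.

    Patients are shuffled once (seeded) and split into k near-equal test
    sets; within each fold the remaining patients are shuffled again (an
    independently spawned stream) and ``ceil(val_frac * n_remaining)`` of
    them become the validation set.
    """
    if isinstance(patients, DatasetManifest):
        patients = patients.patient_ids()
    patients = list(patients)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    if not 0.0 <= val_frac < 1.0:
        raise ValueError("val_frac must lie in [0, 1)")

    ss = np.random.SeedSequence(seed)
    test_rng = np.random.default_rng(ss.spawn(1)[0])
    order = list(patients)
    test_rng.shuffle(order)
    test_sets = [list(chunk) for chunk in np.array_split(np.asarray(order, dtype=object), k)]

    folds = []
    val_streams = ss.spawn(k + 1)[1:]
    for fold_index in range(k):
        test = [str(p) for p in test_sets[fold_index]]
        remaining = [p for p in order if p not in set(test)]
        val_rng = np.random.default_rng(val_streams[fold_index])
        rem = list(remaining)
        val_rng.shuffle(rem)
        n_val = math.ceil(val_frac * len(rem))
        folds.append(
            FoldSplit(
                fold_index=fold_index,
                train_patients=tuple(rem[n_val:]),
                val_patients=tuple(rem[:n_val]),
                test_patients=tuple(test),
            )
        )
    return folds


def folds_to_json(folds: list[FoldSplit], path: Path | str | None = None) -> str:
    payload = {
        str(f.fold_index): {
            "train": list(f.train_patients),
            "val": list(f.val_patients),
            "test": list(f.test_patients),
        }
        for f in folds
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
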