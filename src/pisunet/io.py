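"""Image/mask disk formats and dataset manifests.

On disk: images are single-channel 16-bit PNG (intensities in [0, 1] scaled
to [0, 65535]); masks are single-channel 8-bit PNG with values strictly
{0, 255}.  In memory: images are float arrays in [0, 1], masks uint8 {0, 1}.
Manifests are CSV files with columns
``patient_id,slice_id,image_path,mask_path,class_label`` and paths relative
to the manifest's root directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImagePair",
    "ManifestRecord",
    "DatasetManifest",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["patient_id", "slice_id", "image_path", "mask_path", "class_label"]


@dataclass
class ImagePair:
    """One grayscale slice with its binary ground-truth mask."""

    image: np.ndarray  # float, [0, 1], shape (H, W)
    mask: np.ndarray  # uint8, {0, 1}, shape (H, W)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class ManifestRecord:
    patient_id: str
    slice_id: str
    image_path: str  # relative to root_dir
    mask_path: str
    class_label: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    root_dir: Path

    def __len__(self):
        return len(self.records)

    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def by_patient(self) -> dict[str, list[ManifestRecord]]:
        out: dict[str, list[ManifestRecord]] = {}
        for r in self.records:
            out.setdefault(r.patient_id, []).append(r)
        return out

    def subset_patients(self, patients) -> "DatasetManifest":
        pats = set(patients)
        return DatasetManifest([r for r in self.records if r.patient_id in pats], self.root_dir)

    def subset_class(self, class_label: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.class_label == class_label], self.root_dir)

    def class_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.class_label, None)
        return list(seen)

    def load_pair(self, record: ManifestRecord) -> ImagePair:
        image = load_image(self.root_dir / record.image_path)
        mask = load_mask(self.root_dir / record.mask_path)
        return ImagePair(image, mask, meta={
            "patient_id": record.patient_id,
            "slice_id": record.slice_id,
            "class_label": record.class_label,
        })

    def to_csv(self, path: Path | str) -> Path:
        path = Path(path)
        df = pd.DataFrame([vars(r) for r in self.records], columns=MANIFEST_COLUMNS)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: Path | str, root_dir: Path | str | None = None) -> "DatasetManifest":
        path = Path(path)
        root = Path(root_dir) if root_dir is not None else path.parent
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest {path} missing columns: {missing}")
        records = [ManifestRecord(**{c: row[c] for c in MANIFEST_COLUMNS}) for _, row in df.iterrows()]
        return cls(records, root)

    def validate(self) -> None:
        """Check every referenced file exists and loads as a coherent pair."""
        if not self.records:
            raise ValueError("empty manifest")
        for r in self.records:
            pair = self.load_pair(r)
            if pair.mask.max(initial=0) > 1:
                raise ValueError(f"mask {r.mask_path} is not binary")


def save_image(path: Path | str, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535.0).astype(np.uint16))


def load_image(path: Path | str) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {arr.shape}")
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return (arr.astype(np.float64) / scale).astype(np.float32)


def save_mask(path: Path | str, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as 8-bit PNG with values {0, 255}."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    iio.imwrite(Path(path), (m.astype(np.uint8) * 255))


def load_mask(path: Path | str) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel mask, got shape {arr.shape}")
    return (arr > 127).astype(np.uint8)
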