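"""Synthetic cystic-lesion phantoms with exact binary ground truth.

The generator emulates the salient structure of T2-weighted abdominal
slices of pancreatic cystic neoplasms without any real data: fluid-filled
cysts appear as bright regions on a smooth, low-frequency background
texture, with low lesion/background contrast, blurred borders and additive
noise.  Two lesion morphologies are produced:

* ``MCN-like`` — a single large smooth-walled cyst (one ellipse);
* ``SCN-like`` — a multi-cystic cluster (3–8 overlapping sub-cysts).

The ground-truth mask is the *pre-blur* lesion support, so labels stay
crisp even when the rendered image has indistinct borders — mirroring the
clinical challenge (unclear cyst walls) while keeping supervision exact.

All randomness flows from ``PhantomSpec.seed`` (one generator per phantom),
so identical specs reproduce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import DatasetManifest, ImagePair, ManifestRecord, save_image, save_mask

__all__ = [
    "SCN_LIKE",
    "MCN_LIKE",
    "PhantomSpec",
    "PhantomGenerationError",
    "generate_phantom",
    "generate_dataset",
]

SCN_LIKE = "SCN-like"
MCN_LIKE = "MCN-like"

_MAX_PLACEMENT_RETRIES = 10


class PhantomGenerationError(RuntimeError):
    """Raised when no valid lesion placement is found within the retry limit."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``n_subcysts=None`` resolves by class: MCN-like always uses a single
    cyst; SCN-like draws 3–8 sub-cysts.  ``contrast`` is the mean intensity
    the lesion adds over the background; ``background_level`` and
    ``background_texture`` control the smooth Gaussian-random-field
    background (set both to 0 for an exactly black background).
    """

    class_label: str = MCN_LIKE
    image_size: int = 128
    n_subcysts: int | None = None
    lesion_radius_frac: float = 0.18
    contrast: float = 0.5
    border_blur_sigma: float = 1.0
    noise_sigma: float = 0.05
    background_level: float = 0.25
    background_texture: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in (SCN_LIKE, MCN_LIKE):
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_subcysts is not None and self.n_subcysts < 1:
            raise ValueError("n_subcysts must be >= 1")
        if not 0.05 < self.lesion_radius_frac < 0.4:
            raise ValueError("lesion_radius_frac must lie in (0.05, 0.4)")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if self.border_blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur/noise sigmas must be >= 0")


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    return (u * u + v * v) <= 1.0


def _lesion_indicator(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    radius = spec.lesion_radius_frac * s
    if spec.class_label == MCN_LIKE:
        n = 1
    elif spec.n_subcysts is not None:
        n = spec.n_subcysts
    else:
        n = int(rng.integers(3, 9))
    center = rng.uniform(0.3 * s, 0.7 * s, size=2)
    mask = np.zeros((s, s), dtype=bool)
    for _ in range(n):
        if n == 1:
            cy, cx = center
            a = rng.uniform(0.7, 1.0) * radius
            b = rng.uniform(0.7, 1.0) * radius
        else:
            cy, cx = center + rng.uniform(-0.6, 0.6, size=2) * radius
            a = rng.uniform(0.25, 0.5) * radius
            b = rng.uniform(0.25, 0.5) * radius
        theta = rng.uniform(0, np.pi)
        mask |= _ellipse_mask(s, cy, cx, max(a, 1.0), max(b, 1.0), theta)
    return mask


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    bg = np.full((s, s), spec.background_level, dtype=np.float64)
    if spec.background_texture > 0:
        field = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 8.0, mode="reflect")
        sd = field.std()
        if sd > 0:
            bg += spec.background_texture * field / sd
    return bg


def generate_phantom(spec: PhantomSpec) -> ImagePair:
    """Render one phantom slice and its exact binary mask.

    The image is ``background + contrast * lesion``, Gaussian-blurred by
    ``border_blur_sigma``, plus i.i.d. Gaussian noise of sd ``noise_sigma``,
    clipped to [0, 1].  The mask is the crisp pre-blur lesion support.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lesion = None
    for _ in range(_MAX_PLACEMENT_RETRIES):
        candidate = _lesion_indicator(spec, rng)
        if candidate.any():
            lesion = candidate
            break
    if lesion is None:
        raise PhantomGenerationError(
            f"no in-bounds lesion after {_MAX_PLACEMENT_RETRIES} placements (spec={spec})"
        )
    image = _background(spec, rng) + spec.contrast * lesion
    if spec.border_blur_sigma > 0:
        image = gaussian_filter(image, sigma=spec.border_blur_sigma, mode="reflect")
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return ImagePair(image, lesion.astype(np.uint8), meta={"spec": spec})


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_dataset(
    n_patients: int,
    slices_per_patient: tuple[int, int],
    class_mix: float,
    out_dir: Path | str,
    seed: int,
    image_size: int = 128,
) -> DatasetManifest:
    """Write a phantom dataset (PNG pairs + CSV manifest) to ``out_dir``.

    ``class_mix`` is the fraction of patients assigned the SCN-like class
    (round-half-up).  Each synthetic patient has one base lesion geometry;
    its slices perturb radius/contrast/blur slightly, simulating adjacent
    slices through the same tumor, so patient-level splitting is meaningful.
    """
    if n_patients < 3:
        raise ValueError("n_patients must be >= 3 so 3-fold cross-validation is possible")
    if not 0.0 <= class_mix <= 1.0:
        raise ValueError("class_mix must lie in [0, 1]")
    lo, hi = slices_per_patient
    if not 1 <= lo <= hi:
        raise ValueError("slices_per_patient must be a (lo, hi) range with 1 <= lo <= hi")

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    n_scn = _round_half_up(class_mix * n_patients)
    labels = [SCN_LIKE] * n_scn + [MCN_LIKE] * (n_patients - n_scn)
    rng.shuffle(labels)

    records: list[ManifestRecord] = []
    for p in range(n_patients):
        patient_id = f"p{p:03d}"
        label = labels[p]
        base = PhantomSpec(
            class_label=label,
            image_size=image_size,
            n_subcysts=int(rng.integers(3, 9)) if label == SCN_LIKE else 1,
            lesion_radius_frac=float(rng.uniform(0.10, 0.25)),
            contrast=float(rng.uniform(0.3, 0.7)),
            border_blur_sigma=float(rng.uniform(0.5, 1.5)),
            noise_sigma=0.05,
            seed=int(rng.integers(2**31)),
        )
        n_slices = int(rng.integers(lo, hi + 1))
        for s in range(n_slices):
            spec = replace(
                base,
                lesion_radius_frac=float(
                    np.clip(base.lesion_radius_frac * rng.uniform(0.9, 1.1), 0.06, 0.39)
                ),
                contrast=float(np.clip(base.contrast * rng.uniform(0.9, 1.1), 0.05, 1.0)),
                seed=int(rng.integers(2**31)),
            )
            pair = generate_phantom(spec)
            slice_id = f"s{s:02d}"
            image_rel = f"images/{patient_id}_{slice_id}.png"
            mask_rel = f"masks/{patient_id}_{slice_id}.png"
            save_image(out_dir / image_rel, pair.image)
            save_mask(out_dir / mask_rel, pair.mask)
            records.append(ManifestRecord(patient_id, slice_id, image_rel, mask_rel, label))

    manifest = DatasetManifest(records, out_dir)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
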