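"""Training protocol, k-fold cross-validation and ablation tables.

Protocol defaults follow the study design this package reproduces: Adam
with learning rate 1e-4 and beta1 = 0.9, 30 epochs, and the checkpoint with
the minimum validation loss kept as the final model.  The loss is a
BCE + soft-Dice compound by default (pure ``bce`` or ``dice`` selectable);
the two lesion classes are trained separately, one model per class, and
performance is reported as mean ± SD of the per-fold means over the k
cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .io import DatasetManifest
from .model import ModelConfig, SegModel, build_model
from .nn import Adam, Tensor
from .nn.autograd import clip as _clip
from .nn.autograd import log as _log
from .preprocessing import FoldSplit, make_folds

__all__ = [
    "TrainConfig",
    "TrainResult",
    "CVReport",
    "METRIC_NAMES",
    "load_arrays",
    "segmentation_loss",
    "train",
    "evaluate_model",
    "cross_validate",
    "run_ablation",
]

METRIC_NAMES = ("dsc", "voe", "rvd", "pre", "recall")

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    loss: str = "bce_dice"  # {bce, dice, bce_dice}
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("bce", "dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainResult:
    """Best checkpoint (by validation loss) plus the full loss history."""

    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_loss: float
    history: list[dict[str, float]]  # per epoch: {"epoch", "train_loss", "val_loss"}

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def load_arrays(
    manifest: DatasetManifest, patients=None
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Load (preprocessed) slices as batched arrays.

    Returns images (M, 1, H, W) float32, masks (M, 1, H, W) float32, and the
    (patient_id, slice_id) key per row.
    """
    records = manifest.records
    if patients is not None:
        pats = set(patients)
        records = [r for r in records if r.patient_id in pats]
    if not records:
        raise ValueError("no records selected")
    images, masks, keys = [], [], []
    for rec in records:
        pair = manifest.load_pair(rec)
        images.append(pair.image[None])
        masks.append(pair.mask.astype(np.float32)[None])
        keys.append((rec.patient_id, rec.slice_id))
    return np.stack(images), np.stack(masks), keys


def segmentation_loss(prob: Tensor, target: np.ndarray, kind: str = "bce_dice") -> Tensor:
    """Scalar loss between predicted probabilities and a {0,1} target."""
    g = Tensor(np.asarray(target, dtype=prob.dtype))
    terms = []
    if kind in ("bce", "bce_dice"):
        p = _clip(prob, _BCE_EPS, 1.0 - _BCE_EPS)
        terms.append(-(g * _log(p) + (1.0 - g) * _log(1.0 - p)).mean())
    if kind in ("dice", "bce_dice"):
        inter = (prob * g).sum()
        terms.append(1.0 - (2.0 * inter + 1.0) / (prob.sum() + g.sum() + 1.0))
    if not terms:
        raise ValueError(f"unknown loss {kind!r}")
    loss = terms[0]
    for t in terms[1:]:
        loss = loss + t
    return loss


def _epoch_loss(model: SegModel, images, masks, cfg: TrainConfig) -> float:
    """Mean loss over the set without gradient bookkeeping (eval mode)."""
    model.eval()
    total, count = 0.0, 0
    for i in range(0, len(images), cfg.batch_size):
        xb, yb = images[i : i + cfg.batch_size], masks[i : i + cfg.batch_size]
        loss = segmentation_loss(model(xb), yb, cfg.loss)
        total += loss.item() * len(xb)
        count += len(xb)
    return total / count


def train(
    model: SegModel,
    split: FoldSplit,
    data: DatasetManifest,
    cfg: TrainConfig,
) -> TrainResult:
    """Train on ``split.train_patients``, checkpoint on minimum validation loss.

    Raises on empty splits and aborts with a diagnostic on non-finite loss.
    All randomness (batch order) comes from ``cfg.seed``.
    """
    cfg.validate()
    if not split.train_patients or not split.val_patients:
        raise ValueError("train and validation patient sets must be non-empty")
    train_x, train_y, _ = load_arrays(data, split.train_patients)
    val_x, val_y, _ = load_arrays(data, split.val_patients)
    return fit(model, train_x, train_y, val_x, val_y, cfg)


def fit(
    model: SegModel,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    cfg: TrainConfig,
) -> TrainResult:
    """Array-level training loop behind :func:`train`."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=(cfg.beta1, cfg.beta2))
    history: list[dict[str, float]] = []
    best_state: dict[str, np.ndarray] | None = None
    best_val = np.inf
    best_epoch = -1
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_x))
        total = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            loss = segmentation_loss(model(train_x[idx]), train_y[idx], cfg.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss {value} at epoch {epoch}; aborting"
                )
            loss.backward()
            opt.step()
            total += value * len(idx)
        train_loss = total / len(order)
        val_loss = _epoch_loss(model, val_x, val_y, cfg)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_dict()
    assert best_state is not None
    model.load_state_dict(best_state)
    return TrainResult(best_state, best_epoch, best_val, history)


def evaluate_model(
    model: SegModel,
    images: np.ndarray,
    masks: np.ndarray,
    keys: list[tuple[str, str]],
    fold: int = -1,
    threshold: float = 0.5,
    voe_form: str = "fp",
    batch_size: int = 8,
) -> list[M.MetricsRecord]:
    """Per-image metric records for thresholded model predictions."""
    model.eval()
    records = []
    for i in range(0, len(images), batch_size):
        prob = model(images[i : i + batch_size]).data
        seg = (prob > threshold).astype(np.uint8)
        for j in range(len(seg)):
            pid, sid = keys[i + j]
            records.append(
                M.compute_all(
                    seg[j, 0], masks[i + j, 0] > 0.5, voe_form,
                    patient_id=pid, slice_id=sid, fold=fold,
                )
            )
    return records


@dataclass
class CVReport:
    """Cross-validation summary: per-class, per-metric mean ± SD over folds."""

    variant: str
    k: int
    per_class: dict[str, dict[str, dict]] = field(default_factory=dict)
    records: list[M.MetricsRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"variant": self.variant, "k": self.k, "classes": self.per_class}

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _summarise_folds(
    fold_means: list[dict[str, float]],
    image_pcts: list[dict[str, float]],
    sd_over: str = "folds",
) -> dict[str, dict]:
    """Mean ± SD per metric; the SD is over per-fold means by default,
    over per-image values with ``sd_over='images'``."""
    if sd_over not in ("folds", "images"):
        raise ValueError(f"sd_over must be 'folds' or 'images', got {sd_over!r}")
    out: dict[str, dict] = {}
    for name in METRIC_NAMES:
        per_fold = np.array([fm[name] for fm in fold_means], dtype=float)
        pool = per_fold if sd_over == "folds" else np.array(
            [p[name] for p in image_pcts], dtype=float
        )
        out[name] = {
            "mean": float(pool.mean()),
            "sd": float(pool.std(ddof=1)) if len(pool) > 1 else 0.0,
            "per_fold": [float(v) for v in per_fold],
        }
    return out


def _percent_record(rec: M.MetricsRecord) -> dict[str, float]:
    # dsc/voe/pre/recall on the 0-100 percent scale; rvd is already percent
    return {
        "dsc": rec.dsc * 100.0,
        "voe": rec.voe * 100.0,
        "rvd": rec.rvd,
        "pre": rec.pre * 100.0,
        "recall": rec.recall * 100.0,
    }


def cross_validate(
    variant: str,
    data: DatasetManifest,
    cfg: TrainConfig,
    k: int = 3,
    val_frac: float = 0.2,
    model_overrides: dict | None = None,
    threshold: float = 0.5,
    voe_form: str = "fp",
    oracle: bool = False,
    sd_over: str = "folds",
) -> CVReport:
    """k-fold cross-validation, one model per lesion class per fold.

    ``oracle=True`` bypasses training and feeds the ground truth back as the
    prediction — an end-to-end identity check of the evaluation plumbing.
    Reported numbers are on the percent scale for DSC/VOE/PRE/Recall.
    """
    cfg.validate()
    config = ModelConfig.for_variant(variant, **(model_overrides or {}))
    report = CVReport(variant=variant, k=k)
    for class_label in data.class_labels():
        class_data = data.subset_class(class_label)
        folds = make_folds(class_data.patient_ids(), k=k, val_frac=val_frac, seed=cfg.seed)
        fold_means: list[dict[str, float]] = []
        class_pcts: list[dict[str, float]] = []
        for split in folds:
            test_x, test_y, test_keys = load_arrays(class_data, split.test_patients)
            if oracle:
                recs = [
                    M.compute_all(
                        test_y[j, 0] > 0.5, test_y[j, 0] > 0.5, voe_form,
                        patient_id=test_keys[j][0], slice_id=test_keys[j][1],
                        fold=split.fold_index,
                    )
                    for j in range(len(test_x))
                ]
            else:
                model = build_model(config, seed=cfg.seed * 1009 + split.fold_index)
                train(model, split, class_data, cfg)
                recs = evaluate_model(
                    model, test_x, test_y, test_keys,
                    fold=split.fold_index, threshold=threshold, voe_form=voe_form,
                    batch_size=cfg.batch_size,
                )
            report.records.extend(recs)
            pct = [_percent_record(r) for r in recs]
            class_pcts.extend(pct)
            fold_means.append(
                {name: float(np.mean([p[name] for p in pct])) for name in METRIC_NAMES}
            )
        report.per_class[class_label] = _summarise_folds(fold_means, class_pcts, sd_over)
    return report


def run_ablation(
    variants: list[str],
    data: DatasetManifest,
    cfg: TrainConfig,
    k: int = 3,
    val_frac: float = 0.2,
    model_overrides: dict | None = None,
    voe_form: str = "fp",
) -> tuple[pd.DataFrame, dict[str, CVReport]]:
    """Run cross-validation for each architecture variant and tabulate.

    Returns a table with one row per (variant, class) — columns Network,
    Class, DSC, VOE, RVD, PRE, Recall as "mean ± sd" percent strings — plus
    the underlying :class:`CVReport` per variant.
    """
    unknown = [v for v in variants if v not in ("unet", "se_unet", "ppm_unet", "is_unet", "pis_unet")]
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    reports: dict[str, CVReport] = {}
    rows = []
    for variant in variants:
        rep = cross_validate(
            variant, data, cfg, k=k, val_frac=val_frac,
            model_overrides=model_overrides, voe_form=voe_form,
        )
        reports[variant] = rep
        for class_label, stats in rep.per_class.items():
            row = {"Network": variant, "Class": class_label}
            for name, col in zip(METRIC_NAMES, ("DSC", "VOE", "RVD", "PRE", "Recall")):
                row[col] = f"{stats[name]['mean']:.2f} ± {stats[name]['sd']:.2f}"
            rows.append(row)
    return pd.DataFrame(rows), reports
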