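"""Overlap and volume metrics for binary segmentations.

Five per-image metrics: Dice similarity coefficient (DSC), volumetric
overlap error (VOE), relative volume difference (RVD), precision (PRE) and
recall.  Writing ``S`` for the predicted foreground pixel set and ``G`` for
the ground truth:

    DSC  = 2|S ∩ G| / (|S| + |G|)
    VOE  = 2|S \\ G| / (|S| + |G|)       (default, "fp" form)
    VOE  = 1 − |S ∩ G| / |S ∪ G|        (standard 1 − Jaccard form)
    RVD  = (|S| / |G| − 1) · 100
    PRE  = |S ∩ G| / |S|
    Recall = |S ∩ G| / |G|

Two VOE conventions are deliberately offered: the "fp" form charges only
false positives (so any S ⊆ G scores 0), whereas the standard form is
1 − Jaccard.  DSC/PRE/Recall are unit-interval values (multiply by 100 for
percent-scale reporting); RVD is already a signed percentage.

Empty-mask conventions: both masks empty ⇒ DSC = 1, VOE = 0,
PRE = Recall = 1 (perfect agreement on "no lesion"); empty prediction
against nonempty truth ⇒ PRE = 0; empty truth ⇒ Recall = 1 and RVD raises
(relative volume is undefined without a reference volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsRecord",
    "dice",
    "voe",
    "rvd",
    "precision_recall",
    "compute_all",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Per-image metric values (unit scale except rvd, which is percent)."""

    dsc: float
    voe: float
    rvd: float
    pre: float
    recall: float
    patient_id: str = ""
    slice_id: str = ""
    fold: int = -1


def _counts(seg: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: seg {seg.shape} vs gt {gt.shape}")
    s = seg.astype(bool)
    g = gt.astype(bool)
    return int(s.sum()), int(g.sum()), int((s & g).sum())


def dice(seg: np.ndarray, gt: np.ndarray) -> float:
    ns, ng, ni = _counts(seg, gt)
    if ns + ng == 0:
        return 1.0
    return 2.0 * ni / (ns + ng)


def voe(seg: np.ndarray, gt: np.ndarray, form: str = "fp") -> float:
    """Volumetric overlap error; ``form='fp'`` charges false positives only,
    ``form='jaccard'`` is the standard 1 − |∩|/|∪|."""
    ns, ng, ni = _counts(seg, gt)
    if form == "fp":
        if ns + ng == 0:
            return 0.0
        return 2.0 * (ns - ni) / (ns + ng)
    if form == "jaccard":
        union = ns + ng - ni
        if union == 0:
            return 0.0
        return 1.0 - ni / union
    raise ValueError(f"unknown VOE form {form!r}")


def rvd(seg: np.ndarray, gt: np.ndarray) -> float:
    """Relative volume difference in percent; positive means over-segmentation."""
    ns, ng, _ = _counts(seg, gt)
    if ng == 0:
        raise ValueError("undefined relative volume: ground-truth mask is empty")
    return (ns / ng - 1.0) * 100.0


def precision_recall(seg: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    ns, ng, ni = _counts(seg, gt)
    if ns == 0:
        pre = 1.0 if ng == 0 else 0.0
    else:
        pre = ni / ns
    recall = 1.0 if ng == 0 else ni / ng
    return pre, recall


def compute_all(
    seg: np.ndarray,
    gt: np.ndarray,
    voe_form: str = "fp",
    patient_id: str = "",
    slice_id: str = "",
    fold: int = -1,
) -> MetricsRecord:
    pre, rec = precision_recall(seg, gt)
    _, ng, _ = _counts(seg, gt)
    return MetricsRecord(
        dsc=dice(seg, gt),
        voe=voe(seg, gt, voe_form),
        rvd=rvd(seg, gt) if ng > 0 else float("nan"),
        pre=pre,
        recall=rec,
        patient_id=patient_id,
        slice_id=slice_id,
        fold=fold,
    )
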