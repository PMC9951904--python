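"""Segmentation metrics: pixel confusion counts and the derived scores.

With prediction P and ground truth G as binary pixel sets:

    AC  = (TP + TN) / (TP + TN + FP + FN)
    RE  = TP / (TP + FN)
    PR  = TP / (TP + FP)
    DSC = 2|P n G| / (|P| + |G|)
    JSC = |P n G| / |P u G|
    DL  = 1 - DSC

Degenerate denominators yield 0 (or, for overlap scores with both masks
empty, the convention DSC = JSC = 1) and are flagged, so liver-free slices
do not poison averages.  DSC and JSC satisfy DSC = 2*JSC / (1 + JSC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .imaging_io import BinaryMask

METRIC_NAMES = ("accuracy", "recall", "precision", "dice", "jaccard", "dice_loss")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(mask) -> np.ndarray:
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask is not binary: found values {uniq[:10]}")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN tallies of a predicted vs ground-truth mask."""
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        tn=int(np.sum(~p & ~g)), fn=int(np.sum(~p & g)),
    )


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    return c.tp / denom if denom else 0.0


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    return c.tp / denom if denom else 0.0


def dice(pred, truth) -> float:
    """DSC = 2|P n G| / (|P| + |G|); both masks empty -> 1 by convention."""
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.sum(p & g)) / denom


def jaccard(pred, truth) -> float:
    """JSC = |P n G| / |P u G|; both masks empty -> 1 by convention."""
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    union = int(np.sum(p | g))
    if union == 0:
        return 1.0
    return int(np.sum(p & g)) / union


def dice_loss(pred, truth) -> float:
    return 1.0 - dice(pred, truth)


def bce(pred_probs: np.ndarray, truth, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy of probabilities against a binary mask."""
    g = _as_binary(truth).astype(np.float64)
    p = np.clip(np.asarray(pred_probs, dtype=np.float64), eps, 1.0 - eps)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    return float(-np.mean(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))


@dataclass
class MetricReport:
    """All scores for one prediction/truth pair, with degenerate-case flags."""

    accuracy: float
    recall: float
    precision: float
    dice: float
    jaccard: float
    dice_loss: float
    bce: Optional[float] = None
    degenerate: Set[str] = field(default_factory=set)
    unit_id: str = ""

    @classmethod
    def from_masks(cls, pred, truth, pred_probs: Optional[np.ndarray] = None,
                   unit_id: str = "") -> "MetricReport":
        c = confusion(pred, truth)
        flags: Set[str] = set()
        if c.tp + c.fn == 0:
            flags.add("recall")
        if c.tp + c.fp == 0:
            flags.add("precision")
        d = dice(pred, truth)
        j = jaccard(pred, truth)
        p, g = _as_binary(pred), _as_binary(truth)
        if not p.any() and not g.any():
            flags.update({"dice", "jaccard", "dice_loss"})
        return cls(
            accuracy=accuracy(c), recall=recall(c), precision=precision(c),
            dice=d, jaccard=j, dice_loss=1.0 - d,
            bce=None if pred_probs is None else bce(pred_probs, truth),
            degenerate=flags, unit_id=unit_id,
        )

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def aggregate(reports: Sequence[MetricReport]) -> Dict[str, Tuple[float, float]]:
    """Per-metric arithmetic mean and population standard deviation."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    out = {}
    for name in METRIC_NAMES:
        values = np.array([getattr(r, name) for r in reports], dtype=np.float64)
        out[name] = (float(values.mean()), float(values.std(ddof=0)))
    return out


def format_percent(mean: float, sd: float) -> str:
    """Tables-style 'mean +/- sd' as percent with two decimals, e.g. 97.86 +/- 4.65."""
    return f"{100 * mean:.2f} ± {100 * sd:.2f}"


def aggregate_by_patient(reports: Sequence[MetricReport]) -> Dict[str, Tuple[float, float]]:
    """Per-slice metrics averaged within each patient, then across patients.

    ``unit_id`` is expected to be '<patient>/<slice>'.  This is the default
    reporting level; plain :func:`aggregate` gives the across-slices variant.
    """
    groups: Dict[str, List[MetricReport]] = {}
    for r in reports:
        patient = r.unit_id.split("/")[0]
        groups.setdefault(patient, []).append(r)
    patient_means = []
    for patient, rs in groups.items():
        agg = aggregate(rs)
        patient_means.append(MetricReport(
            **{name: agg[name][0] for name in METRIC_NAMES}, unit_id=patient))
    return aggregate(patient_means)
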