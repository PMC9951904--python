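"""Model/Results objects tying the pipeline together.

:class:`AIMUnet` is the model object: an architecture plus (optionally) the
data it will be fitted to.  ``fit()`` runs the training protocol and returns
an :class:`AIMUnetResults` carrying the fitted weights, the per-epoch
history, prediction and evaluation methods, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import NetworkConfig, TrainConfig
from .evaluate import MetricReport, aggregate, format_percent
from .imaging_io import BinaryMask, CTSlice
from .network import Network, count_parameters
from .postprocess import PredictedMask, ProbabilityMap, binarize
from .training import TrainHistory, train


class AIMUnet:
    """Segmentation model: U-Net with inception modules on the skips."""

    def __init__(self, config: Optional[NetworkConfig] = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.config.validate()
        self.seed = seed
        self.network = Network.from_config(self.config, seed=seed)

    @property
    def description(self):
        return self.network.description

    def parameter_totals(self) -> Tuple[int, int, int]:
        """(total, trainable, non_trainable) parameters of the built graph."""
        return count_parameters(self.description)

    def fit(self, images: Sequence, masks: Sequence,
            train_config: Optional[TrainConfig] = None,
            max_steps: Optional[int] = None) -> "AIMUnetResults":
        history = train(self.network, images, masks, train_config, max_steps=max_steps)
        return AIMUnetResults(model=self, history=history)

    def predict_slice(self, ct: CTSlice) -> ProbabilityMap:
        """One normalized slice -> pre-threshold probability map in (0, 1)."""
        if ct.intensity_state != "normalized":
            raise ValueError("predict_slice expects a normalized slice")
        probs = self.network.predict(ct.pixels[None, ..., None].astype(np.float32))
        return ProbabilityMap(pixels=probs[0, ..., 0].astype(np.float64),
                              patient_id=ct.patient_id, slice_index=ct.slice_index)

    def predict(self, slices: Sequence[CTSlice],
                batch_size: int = 3) -> List[ProbabilityMap]:
        """Batched inference; input order preserved."""
        if not slices:
            return []
        x = np.stack([s.pixels for s in slices])[..., None].astype(np.float32)
        probs = self.network.predict(x, batch_size=batch_size)
        return [ProbabilityMap(pixels=probs[i, ..., 0].astype(np.float64),
                               patient_id=s.patient_id, slice_index=s.slice_index)
                for i, s in enumerate(slices)]


@dataclass
class AIMUnetResults:
    """Fitted model with history, prediction, evaluation and a summary table."""

    model: AIMUnet
    history: TrainHistory

    def predict(self, slices: Sequence[CTSlice], threshold: float = 0.5,
                batch_size: int = 3) -> List[PredictedMask]:
        maps = self.model.predict(slices, batch_size=batch_size)
        return [binarize(m, threshold=threshold) for m in maps]

    def evaluate(self, slices: Sequence[CTSlice], truths: Sequence[BinaryMask],
                 threshold: float = 0.5) -> pd.DataFrame:
        """Per-slice metric table (one row per slice, columns per metric)."""
        maps = self.model.predict(slices)
        rows = []
        for m, truth in zip(maps, truths):
            pred = binarize(m, threshold=threshold)
            rep = MetricReport.from_masks(pred.mask, truth, pred_probs=m.pixels,
                                          unit_id=f"{m.patient_id}/{m.slice_index}")
            rows.append({"unit_id": rep.unit_id, **rep.as_dict(), "bce": rep.bce})
        return pd.DataFrame(rows)

    def reports(self, slices, truths, threshold: float = 0.5) -> List[MetricReport]:
        maps = self.model.predict(slices)
        out = []
        for m, truth in zip(maps, truths):
            pred = binarize(m, threshold=threshold)
            out.append(MetricReport.from_masks(pred.mask, truth, pred_probs=m.pixels,
                                               unit_id=f"{m.patient_id}/{m.slice_index}"))
        return out

    def summary(self) -> str:
        total, trainable, non_trainable = self.model.parameter_totals()
        lines = [
            "AIM-Unet segmentation results",
            "=" * 46,
            f"layers:               {self.model.description.n_layers}",
            f"parameters (total):   {total:,}",
            f"  trainable:          {trainable:,}",
            f"  non-trainable:      {non_trainable:,}",
            f"epochs run:           {len(self.history)}",
        ]
        if len(self.history):
            lines += [
                f"final train loss:     {self.history.loss[-1]:.4f}",
                f"final val loss:       {self.history.val_loss[-1]:.4f}",
                f"final val Dice:       {self.history.dice[-1]:.4f}",
                f"final val IoU:        {self.history.iou[-1]:.4f}",
            ]
        return "\n".join(lines)

    def history_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.history.as_dict())
        df.insert(0, "epoch", np.arange(1, len(df) + 1))
        return df


def summarize_reports(reports: Sequence[MetricReport]) -> str:
    """Mean +/- sd table over reports, formatted as percentages."""
    agg = aggregate(reports)
    rows = [f"{name:>10}: {format_percent(*agg[name])}" for name in agg]
    return "\n".join(rows)
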