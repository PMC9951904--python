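"""End-to-end orchestration: simulate -> preprocess -> train -> predict -> evaluate.

Each stage writes a manifest (inputs, outputs, seed) into the run directory,
so every artifact on disk is attributable.  Re-running with the same config
and seed reproduces the evaluation within floating-point tolerance.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import phantoms, preprocess
from .config import RunConfig
from .imaging_io import BinaryMask, CTSlice
from .model import AIMUnet, AIMUnetResults
from .postprocess import export_volume


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_manifest(run_dir: Path, stage: str, payload: dict) -> None:
    payload = {"stage": stage, "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"), **payload}
    with open(run_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def run_pipeline(config: RunConfig, run_dir) -> pd.DataFrame:
    """Run the full pipeline; returns the per-slice metric table."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        lo, hi = config.slices_per_patient
        patients: Dict[str, List] = {}
        for p in range(config.n_patients):
            pid = f"phantom{p:03d}"
            n_slices = int(phantoms.keyed_rng(config.phantom.seed, "count", pid)
                           .integers(lo, hi + 1))
            _, slices = phantoms.generate_volume(config.phantom, pid, n_slices)
            patients[pid] = slices
        _write_manifest(run_dir, stage, {
            "seed": config.phantom.seed, "n_patients": config.n_patients,
            "slices": {pid: len(s) for pid, s in patients.items()},
        })
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise PipelineError(stage, exc) from exc

    # --- preprocess (window -> equalize -> resize -> normalize, split) ----
    stage = "preprocess"
    try:
        split = preprocess.split_patients(sorted(patients), config.split)
        prepared: Dict[str, List[Tuple[CTSlice, BinaryMask]]] = {}
        for pid, slices in patients.items():
            pairs = []
            for s in slices:
                ct = preprocess.preprocess_slice(s.image, config.window, config.network_size)
                mask = preprocess.resize_to_network(s.liver_mask, config.network_size)
                pairs.append((ct, mask))
            prepared[pid] = pairs
        train_pairs = [pr for pid in sorted(split["train"]) for pr in prepared[pid]]
        if config.augment_training:
            train_pairs = preprocess.augment_dataset(train_pairs, config.augmentation)
        test_pairs = [pr for pid in sorted(split["test"]) for pr in prepared[pid]]
        _write_manifest(run_dir, stage, {
            "split": {k: sorted(v) for k, v in split.items()},
            "n_train_pairs": len(train_pairs), "n_test_pairs": len(test_pairs),
            "augmented": config.augment_training, "window": config.window,
            "size": config.network_size,
        })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- train ------------------------------------------------------------
    stage = "train"
    try:
        model = AIMUnet(config.network, seed=config.seed)
        images = [p[0] for p in train_pairs]
        masks = [p[1] for p in train_pairs]
        results = model.fit(images, masks, config.train)
        results.history_frame().to_csv(run_dir / "history.csv", index=False)
        np.savez(run_dir / "weights.npz", **model.network.get_weights())
        _write_manifest(run_dir, stage, {
            "seed": config.train.seed, "epochs": len(results.history),
            "n_pairs": len(images), "weights": "weights.npz",
        })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- predict + evaluate ------------------------------------------------
    stage = "predict"
    try:
        pred_dir = run_dir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        all_rows = []
        for pid in sorted(split["test"]):
            slices = [p[0] for p in prepared[pid]]
            truths = [p[1] for p in prepared[pid]]
            frame = results.evaluate(slices, truths, threshold=config.threshold)
            preds = results.predict(slices, threshold=config.threshold)
            export_volume(pred_dir / f"{pid}.nii.gz", preds)
            all_rows.append(frame)
        metrics = pd.concat(all_rows, ignore_index=True)
        metrics.to_csv(run_dir / "metrics.csv", index=False)
        _write_manifest(run_dir, stage, {
            "threshold": config.threshold,
            "patients": sorted(split["test"]), "report": "metrics.csv",
        })
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return metrics
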