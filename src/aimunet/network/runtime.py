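"""Executable network materialized from a :class:`NetworkDescription`.

The description is the single source of architectural truth: every layer
record becomes one NumPy layer, and forward/backward run over the record
order (which is topologically sorted by construction).  Gradients from
fan-out nodes (the inception-module branches read their input several times)
are accumulated before a node's backward pass runs.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from ..config import NetworkConfig
from . import layers as L
from .describe import NetworkDescription, build_aim_unet


class InferenceError(ValueError):
    """Input does not match the network's expected geometry or state."""


class Network:
    """A trainable network instantiated from a description."""

    def __init__(self, description: NetworkDescription, rng: np.random.Generator):
        self.description = description
        self.modules: Dict[str, L.Layer] = {}
        for rec in description.layers:
            self.modules[rec.name] = self._materialize(rec, rng)

    @classmethod
    def from_config(cls, config: NetworkConfig, seed: int = 0) -> "Network":
        return cls(build_aim_unet(config), np.random.default_rng(seed))

    @staticmethod
    def _materialize(rec, rng) -> L.Layer:
        cin = rec.input_shape[2]
        cout = rec.output_shape[2]
        if rec.kind in ("conv", "output"):
            kh, kw = rec.kernel
            return L.Conv2D(rec.name, kh, kw, cin, cout, rec.activation, rng)
        if rec.kind == "batch_norm":
            return L.BatchNorm(rec.name, cout)
        if rec.kind == "max_pool":
            return L.MaxPool2() if rec.stride == 2 else L.MaxPoolSame(rec.kernel[0])
        if rec.kind == "upsample":
            if rec.n_trainable:  # transposed convolution
                return L.ConvTranspose2x2(rec.name, cin, cout, rec.activation, rng)
            return L.Upsample2()
        if rec.kind == "concat":
            return L.Concat()
        if rec.kind == "input":
            return L.Identity()
        raise ValueError(f"unknown layer kind {rec.kind!r}")

    # -- parameter access ---------------------------------------------------

    def params(self) -> List[L.Param]:
        out: List[L.Param] = []
        for rec in self.description.layers:
            out.extend(self.modules[rec.name].params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def get_weights(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for name, mod in self.modules.items():
            if isinstance(mod, L.BatchNorm):
                state[f"{name}.running_mean"] = mod.running_mean.copy()
                state[f"{name}.running_var"] = mod.running_var.copy()
        return state

    def set_weights(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for name, mod in self.modules.items():
            if isinstance(mod, L.BatchNorm):
                mod.running_mean[...] = state[f"{name}.running_mean"]
                mod.running_var[...] = state[f"{name}.running_var"]

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        expected = self.description.layers[0].output_shape
        if x.ndim != 4 or x.shape[1:] != expected:
            raise InferenceError(
                f"input shape {x.shape} does not match network input (N, {expected})"
            )
        outputs: Dict[str, np.ndarray] = {}
        y = x.astype(np.float32)
        for rec in self.description.layers:
            ins = [outputs[s] for s in rec.inputs] if rec.inputs else [y]
            outputs[rec.name] = self.modules[rec.name].forward(*ins, training=training)
        self._outputs = outputs
        return outputs[self.description.layers[-1].name]

    def backward(self, dy: np.ndarray) -> None:
        grads: Dict[str, np.ndarray] = {self.description.layers[-1].name: dy.astype(np.float32)}
        for rec in reversed(self.description.layers):
            if rec.name not in grads or rec.kind == "input":
                continue
            din = self.modules[rec.name].backward(grads.pop(rec.name))
            for src, g in zip(rec.inputs, din):
                if src in grads:
                    grads[src] = grads[src] + g
                else:
                    grads[src] = g

    def predict(self, x: np.ndarray, batch_size: Optional[int] = None) -> np.ndarray:
        """Inference-mode forward pass, preserving input order."""
        if batch_size is None:
            return self.forward(x, training=False)
        chunks = [self.forward(x[i:i + batch_size], training=False)
                  for i in range(0, len(x), batch_size)]
        return np.concatenate(chunks, axis=0)
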