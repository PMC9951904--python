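"""Symbolic computation-graph builder with per-layer parameter accounting.

The network is a four-stage U-Net whose skip connections each pass through an
inception module (two four-branch repetitions closed by two 3x3 convolutions).
This module builds the graph as an ordered list of :class:`LayerRecord`
objects — no arrays are allocated — so the layer table, parameter totals and
shapes can be inspected and audited cheaply.  The runtime (``runtime.py``)
materializes the same records into executable NumPy layers, so the description
is the single source of architectural truth.

Counting conventions
--------------------
* Parameters: a convolution with kernel ``kh x kw`` mapping ``Cin -> Cout``
  channels carries ``kh*kw*Cin*Cout + Cout`` trainable parameters; a batch
  normalization over ``C`` channels carries ``2C`` trainable (scale, shift)
  and ``2C`` non-trainable (running mean, variance).
* Layers: every graph node of kind input, conv, batch_norm, max_pool,
  upsample, concat or output counts as one layer.  ReLU / sigmoid activations
  are fused into their convolution records and are not counted separately;
  this is the convention under which the full-size network has 188 layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from ..config import ConfigurationError, IMPSpec, NetworkConfig

Shape = Tuple[int, int, int]  # (height, width, channels)


@dataclass
class LayerRecord:
    name: str
    kind: str  # input | conv | batch_norm | max_pool | upsample | concat | output
    inputs: Tuple[str, ...]
    input_shape: Shape
    output_shape: Shape
    n_trainable: int = 0
    n_non_trainable: int = 0
    kernel: Optional[Tuple[int, int]] = None
    stride: int = 1
    activation: Optional[str] = None  # fused activation, not a separate layer


@dataclass
class NetworkDescription:
    layers: List[LayerRecord] = field(default_factory=list)

    @property
    def edges(self) -> List[Tuple[str, str]]:
        return [(src, rec.name) for rec in self.layers for src in rec.inputs]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> LayerRecord:
        for rec in self.layers:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def totals(self) -> Tuple[int, int, int, int]:
        trainable = sum(r.n_trainable for r in self.layers)
        non_trainable = sum(r.n_non_trainable for r in self.layers)
        return (self.n_layers, trainable + non_trainable, trainable, non_trainable)

    def to_tsv(self) -> str:
        rows = ["name\tkind\tinput_shape\toutput_shape\ttrainable\tnon_trainable"]
        for r in self.layers:
            rows.append(
                f"{r.name}\t{r.kind}\t{r.input_shape}\t{r.output_shape}"
                f"\t{r.n_trainable}\t{r.n_non_trainable}"
            )
        return "\n".join(rows)


def count_parameters(net: NetworkDescription) -> Tuple[int, int, int]:
    """(total, trainable, non_trainable) over all layer records."""
    _, total, trainable, non_trainable = net.totals
    return total, trainable, non_trainable


class _Builder:
    def __init__(self, bn_scope: Tuple[str, ...]):
        self.records: List[LayerRecord] = []
        self.bn_scope = set(bn_scope)

    def add(self, rec: LayerRecord) -> str:
        self.records.append(rec)
        return rec.name

    def conv(self, name: str, src: str, src_shape: Shape, kernel: Tuple[int, int],
             out_ch: int, scope: str, activation: str = "relu", kind: str = "conv") -> Tuple[str, Shape]:
        h, w, cin = src_shape
        out_shape = (h, w, out_ch)
        kh, kw = kernel
        self.add(LayerRecord(name, kind, (src,), src_shape, out_shape,
                             n_trainable=kh * kw * cin * out_ch + out_ch,
                             kernel=kernel, activation=activation))
        if scope in self.bn_scope:
            self.add(LayerRecord(f"{name}_bn", "batch_norm", (name,), out_shape, out_shape,
                                 n_trainable=2 * out_ch, n_non_trainable=2 * out_ch))
            return f"{name}_bn", out_shape
        return name, out_shape

    def pool(self, name: str, src: str, src_shape: Shape, kernel: int, stride: int) -> Tuple[str, Shape]:
        h, w, c = src_shape
        out_shape = (h // stride, w // stride, c)
        self.add(LayerRecord(name, "max_pool", (src,), src_shape, out_shape,
                             kernel=(kernel, kernel), stride=stride))
        return name, out_shape

    def concat(self, name: str, srcs: List[Tuple[str, Shape]]) -> Tuple[str, Shape]:
        h, w, _ = srcs[0][1]
        c = sum(s[1][2] for s in srcs)
        out_shape = (h, w, c)
        self.add(LayerRecord(name, "concat", tuple(s[0] for s in srcs), srcs[0][1], out_shape))
        return name, out_shape


def build_imp(builder: _Builder, level: int, src: str, src_shape: Shape,
              spec: IMPSpec) -> Tuple[str, Shape]:
    """Append one inception module to the graph; returns its output node.

    Structure: twice [1x1 | 1x1->5x5 | 1x1->3x3->3x3 | pool->1x1, concat],
    then two 3x3 convolutions.  Every convolution has batch norm + ReLU.
    Spatial dimensions are preserved throughout (stride 1, same padding).
    """
    spec.validate()
    if src_shape[2] < 1:
        raise ConfigurationError("IMP input must have >= 1 channel")
    node, shape = src, src_shape
    for rep_idx, widths in ((1, spec.rep1), (2, spec.rep2)):
        p = f"imp{level + 1}_r{rep_idx}"
        b1, s1 = builder.conv(f"{p}_b1", node, shape, (1, 1), widths.b1, "imp")
        b2, s2 = builder.conv(f"{p}_b2a", node, shape, (1, 1), widths.b2_in, "imp")
        b2, s2 = builder.conv(f"{p}_b2b", b2, s2, (5, 5), widths.b2_out, "imp")
        b3, s3 = builder.conv(f"{p}_b3a", node, shape, (1, 1), widths.b3_in, "imp")
        b3, s3 = builder.conv(f"{p}_b3b", b3, s3, (3, 3), widths.b3_mid, "imp")
        b3, s3 = builder.conv(f"{p}_b3c", b3, s3, (3, 3), widths.b3_out, "imp")
        b4, s4 = builder.pool(f"{p}_pool", node, shape, spec.pool_kernel, 1)
        b4, s4 = builder.conv(f"{p}_b4", b4, s4, (1, 1), widths.b4, "imp")
        node, shape = builder.concat(f"{p}_concat", [(b1, s1), (b2, s2), (b3, s3), (b4, s4)])
    t1, t2 = spec.tail_filters
    node, shape = builder.conv(f"imp{level + 1}_tail1", node, shape, (3, 3), t1, "imp")
    node, shape = builder.conv(f"imp{level + 1}_tail2", node, shape, (3, 3), t2, "imp")
    return node, shape


def build_aim_unet(config: NetworkConfig) -> NetworkDescription:
    """Build the full network description from a validated configuration.

    Encoder stage k: two 3x3 convolutions (filters ``base * growth**k``) then
    a 2x2 max-pool.  Base: two 3x3 convolutions.  Each skip level routes the
    encoder's convolution output through an inception module whose output is
    concatenated with the decoder's upsampled features.  Decoder stage: 2x2
    upsampling then two 3x3 convolutions.  Head: 1x1 convolution with sigmoid.
    """
    config.validate()
    b = _Builder(config.bn_scope)
    shape: Shape = (config.input_height, config.input_width, config.input_channels)
    node = b.add(LayerRecord("input", "input", (), shape, shape))

    skip_nodes: List[Tuple[str, Shape]] = []
    for level in range(config.depth):
        f = config.encoder_filters(level)
        node, shape = b.conv(f"enc{level + 1}a", node, shape, (3, 3), f, "encoder")
        node, shape = b.conv(f"enc{level + 1}b", node, shape, (3, 3), f, "encoder")
        skip_nodes.append((node, shape))
        node, shape = b.pool(f"enc{level + 1}_pool", node, shape, 2, 2)

    base_f = config.base_filters * config.growth**config.depth
    node, shape = b.conv("base1", node, shape, (3, 3), base_f, "base")
    node, shape = b.conv("base2", node, shape, (3, 3), base_f, "base")

    imp_nodes: List[Tuple[str, Shape]] = []
    for level in range(config.depth):
        src, src_shape = skip_nodes[level]
        imp_nodes.append(build_imp(b, level, src, src_shape, config.imp_specs[level]))

    for level in range(config.depth - 1, -1, -1):
        f = config.encoder_filters(level)
        h, w, c = shape
        up_shape = (h * 2, w * 2, f)
        if config.upsample_mode == "transposed_conv":
            b.add(LayerRecord(f"up{level + 1}", "upsample", (node,), shape, up_shape,
                              n_trainable=2 * 2 * c * f + f, kernel=(2, 2), stride=2,
                              activation="relu"))
            node, shape = f"up{level + 1}", up_shape
            if "upsample" in b.bn_scope:
                b.add(LayerRecord(f"up{level + 1}_bn", "batch_norm", (node,), shape, shape,
                                  n_trainable=2 * f, n_non_trainable=2 * f))
                node = f"up{level + 1}_bn"
        else:
            b.add(LayerRecord(f"up{level + 1}", "upsample", (node,), shape,
                              (h * 2, w * 2, c), kernel=(2, 2), stride=2))
            node, shape = b.conv(f"up{level + 1}_conv", f"up{level + 1}",
                                 (h * 2, w * 2, c), (2, 2), f, "upsample")
            up_shape = shape
        node, shape = b.concat(f"skip{level + 1}_concat", [imp_nodes[level], (node, up_shape)])
        node, shape = b.conv(f"dec{level + 1}a", node, shape, (3, 3), f, "decoder")
        node, shape = b.conv(f"dec{level + 1}b", node, shape, (3, 3), f, "decoder")

    b.conv("head", node, shape, (1, 1), config.output_channels, "head",
           activation="sigmoid", kind="output")
    return NetworkDescription(layers=b.records)
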