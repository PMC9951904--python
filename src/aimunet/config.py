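"""Configuration objects for every pipeline stage.

All stage configs are plain dataclasses with a ``validate()`` method that
raises :class:`ConfigurationError` naming the offending field, plus YAML
round-tripping so a single run config file can drive the CLI.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml


class ConfigurationError(ValueError):
    """A stage configuration violates one of its invariants."""


def _check_range(name: str, rng: Tuple[float, float]) -> None:
    if len(rng) != 2 or rng[0] > rng[1]:
        raise ConfigurationError(f"{name}: range must be (low, high) with low <= high, got {rng!r}")


@dataclass
class PhantomConfig:
    """Distributional knobs for the synthetic abdominal-CT generator.

    Intensities are in Hounsfield units (HU).  Defaults place the liver
    (60 +/- 10 HU) and hypodense tumors (offset -30 HU) inside the standard
    soft-tissue window [-100, 200], against darker background clutter.
    """

    height: int = 512
    width: int = 512
    liver_axes_range: Tuple[int, int] = (60, 160)
    liver_hu_mean: float = 60.0
    liver_hu_sd: float = 10.0
    background_hu_mean: float = -50.0
    background_hu_sd: float = 25.0
    tumor_probability: float = 0.3
    tumor_count_range: Tuple[int, int] = (1, 3)
    tumor_radius_range: Tuple[int, int] = (6, 28)
    tumor_hu_offset: float = -30.0
    clutter_count: int = 12
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(f"height/width must be >= 16, got {self.height}x{self.width}")
        _check_range("liver_axes_range", self.liver_axes_range)
        _check_range("tumor_count_range", self.tumor_count_range)
        _check_range("tumor_radius_range", self.tumor_radius_range)
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ConfigurationError(f"tumor_probability must be in [0, 1], got {self.tumor_probability}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.clutter_count < 0:
            raise ConfigurationError(f"clutter_count must be >= 0, got {self.clutter_count}")
        if self.liver_axes_range[1] * 2 >= min(self.height, self.width):
            raise ConfigurationError(
                "liver_axes_range: largest semi-axis must fit inside the slice "
                f"(2*{self.liver_axes_range[1]} >= {min(self.height, self.width)})"
            )


# The six views produced for every training pair, in application order.
AUGMENTATION_NAMES = (
    "center_crop",
    "rotate_cw",
    "rotate_ccw",
    "grid_distortion",
    "vertical_flip",
    "random_brightness_contrast",
)


@dataclass
class AugmentationPolicy:
    """Parameters for the six-view augmentation of a slice/mask pair.

    Geometric transforms are applied identically to image and mask (nearest
    neighbour for the mask); photometric transforms touch the image only.
    """

    crop_fraction: float = 0.875
    rotate_degrees: float = 15.0
    grid_cells: int = 5
    grid_magnitude: float = 0.3
    brightness_delta: float = 0.2
    contrast_delta: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ConfigurationError(f"crop_fraction must be in (0, 1], got {self.crop_fraction}")
        if self.grid_cells < 2:
            raise ConfigurationError(f"grid_cells must be >= 2, got {self.grid_cells}")
        if not 0.0 <= self.grid_magnitude < 1.0:
            raise ConfigurationError(f"grid_magnitude must be in [0, 1), got {self.grid_magnitude}")

    @property
    def transforms(self) -> Tuple[str, ...]:
        return AUGMENTATION_NAMES


@dataclass
class SplitSpec:
    """Patient-level split: 10% of patients test, then 30% of the rest validation."""

    test_fraction: float = 0.10
    val_fraction: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in ("test_fraction", "val_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")


@dataclass
class BranchWidths:
    """Output channels of the seven convolutions in one four-branch repetition.

    ``b1``: the lone 1x1 branch; ``b2_in``/``b2_out``: the 1x1 -> 5x5 branch;
    ``b3_in``/``b3_mid``/``b3_out``: the 1x1 -> 3x3 -> 3x3 branch;
    ``b4``: the 1x1 after the stride-1 max-pool.
    """

    b1: int
    b2_in: int
    b2_out: int
    b3_in: int
    b3_mid: int
    b3_out: int
    b4: int

    @classmethod
    def uniform(cls, width: int) -> "BranchWidths":
        return cls(width, width, width, width, width, width, width)

    def all_widths(self) -> Tuple[int, ...]:
        return (self.b1, self.b2_in, self.b2_out, self.b3_in, self.b3_mid, self.b3_out, self.b4)

    @property
    def concat_channels(self) -> int:
        return self.b1 + self.b2_out + self.b3_out + self.b4


@dataclass
class IMPSpec:
    """Widths of one inception module: two four-branch repetitions plus two 3x3 tails."""

    rep1: BranchWidths
    rep2: BranchWidths
    tail_filters: Tuple[int, int]
    pool_kernel: int = 3

    @classmethod
    def uniform(cls, branch_width: int, tail_width: int) -> "IMPSpec":
        return cls(
            rep1=BranchWidths.uniform(branch_width),
            rep2=BranchWidths.uniform(branch_width),
            tail_filters=(tail_width, tail_width),
        )

    def validate(self) -> None:
        for w in (*self.rep1.all_widths(), *self.rep2.all_widths(), *self.tail_filters):
            if w < 1:
                raise ConfigurationError(f"IMP filter counts must be >= 1, got {w}")
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ConfigurationError(f"pool_kernel must be odd and >= 1, got {self.pool_kernel}")

    @property
    def output_channels(self) -> int:
        return self.tail_filters[1]


# Shipped full-size IMP widths.  These, together with batch normalization on
# every IMP / decoder / up-convolution and transposed 2x2 upsampling, reproduce
# the published totals exactly: 41,695,169 parameters (41,672,129 trainable,
# 23,040 non-trainable) and 188 layers.  The branch and tail widths per skip
# level are the only free quantities the published totals leave; see
# docs/methods.md for how they were fixed.
DEFAULT_IMP_BRANCH_WIDTHS = (72, 136, 152, 176)
DEFAULT_IMP_TAIL_WIDTHS = (80, 136, 160, 192)


def default_imp_specs(depth: int = 4, base_filters: int = 64) -> Tuple[IMPSpec, ...]:
    """IMP widths per skip level.

    At the shipped full-size configuration (depth 4, base 64) these are the
    exact widths that reproduce the published parameter totals.  For reduced
    or enlarged configurations the widths scale proportionally with
    ``base_filters`` (minimum 1 channel); for depths other than 4 the
    branch/tail widths fall back to half/full the encoder width at that level.
    """

    scale = base_filters / 64.0
    specs = []
    for level in range(depth):
        if level < 4:
            b = max(1, round(DEFAULT_IMP_BRANCH_WIDTHS[level] * scale))
            t = max(1, round(DEFAULT_IMP_TAIL_WIDTHS[level] * scale))
        else:
            enc = base_filters * 2**level
            b, t = max(1, enc // 2), max(1, enc)
        specs.append(IMPSpec.uniform(b, t))
    return tuple(specs)


@dataclass
class NetworkConfig:
    """Architecture of the segmentation network.

    ``bn_scope`` lists where batch normalization follows a convolution:
    any subset of {"imp", "encoder", "base", "decoder", "upsample"}.  The
    shipped default ("imp", "decoder", "upsample") is part of the exact
    parameter-total reproduction.
    """

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 1
    depth: int = 4
    base_filters: int = 64
    growth: int = 2
    imp_specs: Optional[Tuple[IMPSpec, ...]] = None
    upsample_mode: str = "transposed_conv"  # or "upsample_then_conv"
    bn_scope: Tuple[str, ...] = ("imp", "decoder", "upsample")
    output_channels: int = 1

    def __post_init__(self) -> None:
        if self.imp_specs is None:
            self.imp_specs = default_imp_specs(self.depth, self.base_filters)
        else:
            self.imp_specs = tuple(self.imp_specs)

    def validate(self) -> None:
        div = 2**self.depth
        if self.input_height % div or self.input_width % div:
            raise ConfigurationError(
                f"input dims {self.input_height}x{self.input_width} must be divisible by 2^depth = {div}"
            )
        if self.base_filters < 1:
            raise ConfigurationError(f"base_filters must be >= 1, got {self.base_filters}")
        if self.growth < 1:
            raise ConfigurationError(f"growth must be >= 1, got {self.growth}")
        if len(self.imp_specs) != self.depth:
            raise ConfigurationError(
                f"need one IMPSpec per skip level: {len(self.imp_specs)} specs for depth {self.depth}"
            )
        if self.upsample_mode not in ("transposed_conv", "upsample_then_conv"):
            raise ConfigurationError(f"unknown upsample_mode {self.upsample_mode!r}")
        known = {"imp", "encoder", "base", "decoder", "upsample"}
        unknown = set(self.bn_scope) - known
        if unknown:
            raise ConfigurationError(f"unknown bn_scope entries {sorted(unknown)}")
        for spec in self.imp_specs:
            spec.validate()

    def encoder_filters(self, level: int) -> int:
        return self.base_filters * self.growth**level


@dataclass
class TrainConfig:
    """Training protocol: Adam, lr 1e-3, batch 3, 100 epochs, BCE loss."""

    batch_size: int = 3
    epochs: int = 100
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "bce"
    val_fraction: float = 0.20
    early_stopping: bool = False
    patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "bce":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with a global seed."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    split: SplitSpec = field(default_factory=SplitSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_patients: int = 10
    slices_per_patient: Tuple[int, int] = (70, 150)
    window: Tuple[float, float] = (-100.0, 200.0)
    network_size: int = 256
    augment_training: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed propagates to every stochastic stage unless overridden
        for stage in (self.phantom, self.augmentation, self.split, self.train):
            if stage.seed == 0:
                stage.seed = self.seed

    def validate(self) -> None:
        for stage in (self.phantom, self.augmentation, self.split, self.network, self.train):
            stage.validate()
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        _check_range("slices_per_patient", self.slices_per_patient)
        if self.window[0] >= self.window[1]:
            raise ConfigurationError(f"window low must be < high, got {self.window}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1), got {self.threshold}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls, data):
    kwargs = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in hints:
            raise ConfigurationError(f"unknown field {key!r} for {cls.__name__}")
        kwargs[key] = value
    # nested stage configs
    nested = {
        "phantom": PhantomConfig, "augmentation": AugmentationPolicy, "split": SplitSpec,
        "network": NetworkConfig, "train": TrainConfig, "rep1": BranchWidths, "rep2": BranchWidths,
    }
    for key, sub in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = _from_plain(sub, kwargs[key])
    if "imp_specs" in kwargs and kwargs["imp_specs"] is not None:
        kwargs["imp_specs"] = tuple(
            _from_plain(IMPSpec, s) if isinstance(s, dict) else s for s in kwargs["imp_specs"]
        )
    for key, value in list(kwargs.items()):
        if isinstance(value, list) and key not in ("imp_specs",):
            kwargs[key] = tuple(value)
    if "tail_filters" in kwargs:
        kwargs["tail_filters"] = tuple(kwargs["tail_filters"])
    return cls(**kwargs)


def save_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_plain(RunConfig, data or {})
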