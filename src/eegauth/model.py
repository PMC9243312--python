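"""Declarative multi-scale CNN specifications and the network builder.

A network in this family is a stack of 3-5 *multi-scale vision modules*
followed by a small fully connected head.  Each module optionally reduces
channel count with a 1x1 convolution, convolves the input in parallel
branches whose kernels differ in scale, batch-normalizes each branch,
applies a leaky ReLU, concatenates branch outputs on the channel axis and
max-pools.  Kernels are quoted in the field's axis order:

* 3D: spatial x temporal x frequency (input ``1 x 16 x 94 x 60``),
* 2D: temporal x frequency          (input ``1 x 94 x 60``),
* 1D: temporal                      (input ``1 x 1504``).

Branch paddings follow the alignment rule ``pad = (k - k_min) / 2`` per
axis, so every branch of a module emits identical spatial dimensions and
concatenation is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import _nn

INPUT_SHAPES = {"3d": (1, 16, 94, 60), "2d": (1, 94, 60), "1d": (1, 16 * 94)}

#: The ten shipped reference architectures: three serial single-scale
#: nets plus seven multi-scale variants across the 1D/2D/3D input forms.
ARCHITECTURE_NAMES = (
    "1d-simple", "2d-simple", "3d-simple",
    "1d-multi-scale-length",
    "2d-multi-scale-wide", "2d-multi-scale-equal", "2d-multi-scale-length",
    "3d-multi-scale-wide", "3d-multi-scale-equal", "3d-multi-scale-length",
)


@dataclass(frozen=True)
class KernelSpec:
    """Convolution kernel extents in time-frequency(-space) pixels."""

    temporal: int
    frequency: int | None = None
    spatial: int | None = None

    def __post_init__(self):
        for v in (self.temporal, self.frequency, self.spatial):
            if v is not None and v < 1:
                raise ValueError("kernel extents must be >= 1")
        if self.spatial is not None and self.frequency is None:
            raise ValueError("a 3D kernel needs a frequency extent")

    @property
    def rank(self) -> int:
        return 1 + (self.frequency is not None) + (self.spatial is not None)

    @property
    def sizes(self) -> tuple[int, ...]:
        """Engine axis order: (spatial,) temporal (, frequency)."""
        if self.spatial is not None:
            return (self.spatial, self.temporal, self.frequency)
        if self.frequency is not None:
            return (self.temporal, self.frequency)
        return (self.temporal,)

    @classmethod
    def from_sizes(cls, sizes) -> "KernelSpec":
        sizes = tuple(int(s) for s in sizes)
        if len(sizes) == 1:
            return cls(temporal=sizes[0])
        if len(sizes) == 2:
            return cls(temporal=sizes[0], frequency=sizes[1])
        if len(sizes) == 3:
            return cls(spatial=sizes[0], temporal=sizes[1], frequency=sizes[2])
        raise ValueError("kernel rank must be 1-3")


def compute_padding(kernels: list[KernelSpec]) -> list[tuple[int, ...]]:
    """Per-branch zero padding equalizing output dims: ``(k - k_min) / 2``.

    Raises if kernel parities differ on an axis, since no symmetric integer
    padding can then equalize the branch outputs.
    """
    if not kernels:
        raise ValueError("no kernels given")
    ranks = {k.rank for k in kernels}
    if len(ranks) != 1:
        raise ValueError("branch kernels must share rank")
    sizes = np.array([k.sizes for k in kernels], dtype=int)
    kmin = sizes.min(axis=0)
    diff = sizes - kmin
    if np.any(diff % 2):
        bad = int(np.nonzero(diff.max(axis=0) % 2)[0][0])
        raise ValueError(
            f"kernel parity mismatch on axis {bad}: sizes {sizes[:, bad].tolist()} "
            "cannot be aligned by symmetric padding")
    return [tuple(int(v) for v in row) for row in diff // 2]


@dataclass(frozen=True)
class BranchSpec:
    kernel: KernelSpec
    out_channels: int
    padding: tuple[int, ...] | None = None   # None -> alignment rule


@dataclass(frozen=True)
class ModuleSpec:
    branches: tuple[BranchSpec, ...]
    pool: tuple[int, ...]
    reduce_1x1: int | None = None
    batch_norm: bool = True

    def __post_init__(self):
        if not self.branches:
            raise ValueError("a module needs at least one branch")
        if any(p < 1 for p in self.pool):
            raise ValueError("pool sizes must be >= 1")

    def resolved_paddings(self) -> list[tuple[int, ...]]:
        auto = compute_padding([b.kernel for b in self.branches])
        return [b.padding if b.padding is not None else a
                for b, a in zip(self.branches, auto)]


@dataclass(frozen=True)
class NetworkSpec:
    input_form: str                       # "1d" | "2d" | "3d"
    modules: tuple[ModuleSpec, ...]
    hidden: int = 32
    n_classes: int = 2
    dropout: float = 0.4
    leaky_slope: float = 0.01
    name: str = ""
    input_shape: tuple[int, ...] | None = None   # override (C, *S)

    def __post_init__(self):
        if self.input_form not in INPUT_SHAPES:
            raise ValueError(f"unknown input form {self.input_form!r}")
        if not 1 <= len(self.modules) <= 5:
            raise ValueError("module depth must be within 1-5")
        if any(len(m.branches) > 6 for m in self.modules):
            raise ValueError("branch count must be within 1-6")

    def resolved_input_shape(self) -> tuple[int, ...]:
        return tuple(self.input_shape) if self.input_shape else \
            INPUT_SHAPES[self.input_form]


def _module_layers(mod: ModuleSpec, in_channels: int, shape, index: int,
                   slope: float):
    """Realize one module; returns (layers, out_shape (C, *S))."""
    layers = []
    nd = len(shape) - 1
    if len(mod.pool) != nd:
        raise ValueError(f"module {index}: pool rank {len(mod.pool)} != "
                         f"spatial rank {nd}")
    if mod.reduce_1x1:
        red = _nn.ConvNd(in_channels, mod.reduce_1x1, (1,) * nd)
        shape = red.out_shape(shape)
        layers += [red, _nn.LeakyReLU(slope)]
        in_channels = mod.reduce_1x1
    paddings = mod.resolved_paddings()
    branches, out_shapes = [], []
    for b, pad in zip(mod.branches, paddings):
        if b.kernel.rank != nd:
            raise ValueError(f"module {index}: kernel rank {b.kernel.rank} "
                             f"!= input rank {nd}")
        conv = _nn.ConvNd(in_channels, b.out_channels, b.kernel.sizes, pad)
        try:
            bshape = conv.out_shape(shape)
        except ValueError as err:
            raise ValueError(f"module {index}: {err}") from None
        seq = [conv]
        if mod.batch_norm:
            seq.append(_nn.BatchNorm(b.out_channels))
        seq.append(_nn.LeakyReLU(slope))
        branches.append(_nn.Sequential(seq))
        out_shapes.append(bshape)
    if len({s[1:] for s in out_shapes}) != 1:
        raise ValueError(f"module {index}: branch outputs misaligned "
                         f"{[s[1:] for s in out_shapes]}")
    layers.append(_nn.Branches(branches))
    concat = (sum(s[0] for s in out_shapes),) + out_shapes[0][1:]
    pool = _nn.MaxPool(mod.pool)
    try:
        shape = pool.out_shape(concat)
    except ValueError as err:
        raise ValueError(f"module {index}: {err}") from None
    layers.append(pool)
    return layers, shape


def build_network(spec: NetworkSpec) -> _nn.Network:
    """Build an executable network; shape-infeasible specs raise a
    constructive error naming the offending module."""
    shape = spec.resolved_input_shape()
    layers: list[_nn.Layer] = []
    channels = shape[0]
    for i, mod in enumerate(spec.modules):
        mod_layers, shape = _module_layers(mod, channels, shape, i,
                                           spec.leaky_slope)
        layers += mod_layers
        channels = shape[0]
    flat = int(np.prod(shape))
    layers += [
        _nn.Flatten(),
        _nn.Dropout(spec.dropout),
        _nn.Linear(flat, spec.hidden),
        _nn.LeakyReLU(spec.leaky_slope),
        _nn.Dropout(spec.dropout),
        _nn.Linear(spec.hidden, spec.n_classes),
    ]
    return _nn.Network(layers, spec.resolved_input_shape())


def init_weights(network: _nn.Network, seed: int) -> _nn.Network:
    """Deterministic kaiming-uniform initialization (bound sqrt(6/fan_in))."""
    return network.initialize(seed)


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form count of trainable scalars in ``build_network(spec)``."""
    shape = spec.resolved_input_shape()
    total = 0
    channels = shape[0]
    for mod in spec.modules:
        nd = len(shape) - 1
        if mod.reduce_1x1:
            total += mod.reduce_1x1 * channels + mod.reduce_1x1
            channels = mod.reduce_1x1
            shape = (mod.reduce_1x1,) + shape[1:]
        paddings = mod.resolved_paddings()
        out_spaces, concat = [], 0
        for b, pad in zip(mod.branches, paddings):
            k = b.kernel.sizes
            total += b.out_channels * channels * int(np.prod(k)) + b.out_channels
            if mod.batch_norm:
                total += 2 * b.out_channels
            out_spaces.append(tuple(
                s + 2 * p - kk + 1 for s, p, kk in zip(shape[1:], pad, k)))
            concat += b.out_channels
        space = tuple(s // p for s, p in zip(out_spaces[0], mod.pool))
        shape = (concat,) + space
        channels = concat
    flat = int(np.prod(shape))
    total += spec.hidden * flat + spec.hidden
    total += spec.n_classes * spec.hidden + spec.n_classes
    return total


# ---------------------------------------------------------------------------
# shipped architecture family (YAML data files)
# ---------------------------------------------------------------------------

def _spec_from_dict(d: dict) -> NetworkSpec:
    modules = []
    for m in d["modules"]:
        branches = tuple(
            BranchSpec(KernelSpec.from_sizes(b["kernel"]), int(b["out"]),
                       tuple(b["padding"]) if "padding" in b else None)
            for b in m["branches"])
        modules.append(ModuleSpec(
            branches=branches,
            pool=tuple(m["pool"]),
            reduce_1x1=m.get("reduce"),
            batch_norm=m.get("batch_norm", True),
        ))
    return NetworkSpec(
        input_form=d["input_form"],
        modules=tuple(modules),
        hidden=d.get("hidden", 32),
        n_classes=d.get("n_classes", 2),
        dropout=d.get("dropout", 0.4),
        leaky_slope=d.get("leaky_slope", 0.01),
        name=d.get("name", ""),
    )


def load_architecture(name: str) -> NetworkSpec:
    """Load a shipped architecture YAML by family name (see ARCHITECTURE_NAMES)."""
    ref = resources.files("eegauth") / "architectures" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"unknown architecture {name!r}; "
                       f"available: {', '.join(ARCHITECTURE_NAMES)}")
    return _spec_from_dict(yaml.safe_load(ref.read_text()))


def reference_architectures() -> dict[str, NetworkSpec]:
    """All ten shipped architectures, keyed by family name."""
    return {name: load_architecture(name) for name in ARCHITECTURE_NAMES}
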