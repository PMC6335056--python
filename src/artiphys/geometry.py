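"""Feed-forward network geometry accounting: unique units, parameters,
spatial grids and maximal receptive-field extents.

Works from a declarative list of sublayers (conv / relu / pool / norm /
fc / prob).  The bundled :func:`alexnet` description is the Caffe
AlexNet: 21 unit-bearing sublayers totalling 22,096 unique units, 10,568
biases and 60,954,656 unique weights, with spatial grids shrinking from
55 x 55 at Conv1 to 6 x 6 after Pool5 and convolutional receptive fields
growing from 11 px (Conv1) to 163 px (Conv5).  Dropout sublayers are the
identity at test time and carry no distinct units, so they are omitted
from the accounting; the softmax output (Prob8) is counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "alexnet",
    "unique_unit_count",
    "parameter_counts",
    "grid_sizes",
    "rf_extent",
    "architecture_report",
]

_WEIGHTED = {"conv", "fc"}
_SPATIAL = {"conv", "pool"}          # kinds with a kernel/stride footprint


@dataclass
class LayerSpec:
    """One sublayer.  ``kernel``/``stride``/``pad`` apply to conv and pool
    kinds; ``input_channels_per_group`` is the kernel depth (respecting
    grouped convolutions); fc fan-in is derived from the previous sublayer."""

    name: str
    kind: str
    unique_kernels: int
    kernel: int = 1
    stride: int = 1
    pad: int = 0
    input_channels_per_group: int | None = None
    groups: int = 1

    def __post_init__(self):
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.unique_kernels < 1:
            raise ValueError("unique_kernels must be >= 1")


@dataclass
class ArchitectureSpec:
    layers: list
    input_size: int = 227
    input_channels: int = 3

    def layer_index(self, name: str) -> int:
        for i, l in enumerate(self.layers):
            if l.name == name:
                return i
        raise KeyError(f"no sublayer named {name!r}")


def alexnet() -> ArchitectureSpec:
    """The 21-sublayer Caffe AlexNet accounting (pads per the Caffe model)."""
    L = LayerSpec
    return ArchitectureSpec([
        L("conv1", "conv", 96, kernel=11, stride=4, pad=0, input_channels_per_group=3),
        L("relu1", "relu", 96),
        L("pool1", "pool", 96, kernel=3, stride=2),
        L("norm1", "norm", 96),
        L("conv2", "conv", 256, kernel=5, stride=1, pad=2,
          input_channels_per_group=48, groups=2),
        L("relu2", "relu", 256),
        L("pool2", "pool", 256, kernel=3, stride=2),
        L("norm2", "norm", 256),
        L("conv3", "conv", 384, kernel=3, stride=1, pad=1, input_channels_per_group=256),
        L("relu3", "relu", 384),
        L("conv4", "conv", 384, kernel=3, stride=1, pad=1,
          input_channels_per_group=192, groups=2),
        L("relu4", "relu", 384),
        L("conv5", "conv", 256, kernel=3, stride=1, pad=1,
          input_channels_per_group=192, groups=2),
        L("relu5", "relu", 256),
        L("pool5", "pool", 256, kernel=3, stride=2),
        L("fc6", "fc", 4096),
        L("relu6", "relu", 4096),
        L("fc7", "fc", 4096),
        L("relu7", "relu", 4096),
        L("fc8", "fc", 1000),
        L("prob8", "prob", 1000),
    ])


def unique_unit_count(arch: ArchitectureSpec) -> tuple:
    """Per-sublayer unique-unit counts (one spatial position per conv-stack
    sublayer, all units for FC-stack sublayers) and their total."""
    per = {l.name: l.unique_kernels for l in arch.layers}
    return per, sum(per.values())


def grid_sizes(arch: ArchitectureSpec) -> dict:
    """Spatial grid width at every sublayer (1 for FC-stack sublayers)."""
    size = arch.input_size
    out = {}
    for l in arch.layers:
        if l.kind in ("fc", "prob"):
            size = 1
        elif l.kind in _SPATIAL:
            size = (size + 2 * l.pad - l.kernel) // l.stride + 1
            if size < 1:
                raise ValueError(f"non-positive spatial size at {l.name}")
        out[l.name] = size
    return out


def parameter_counts(arch: ArchitectureSpec) -> tuple:
    """(weights, biases) over weighted sublayers; grouping respected.

    FC fan-in is the previous sublayer's unit count, times the spatial
    grid area at the transition from the convolutional stack.
    """
    weights = 0
    biases = 0
    size = arch.input_size
    prev_units = arch.input_channels
    for l in arch.layers:
        if l.kind == "conv":
            depth = l.input_channels_per_group
            if depth is None:
                depth = prev_units
            weights += l.kernel * l.kernel * depth * l.unique_kernels
            biases += l.unique_kernels
            size = (size + 2 * l.pad - l.kernel) // l.stride + 1
        elif l.kind == "pool":
            size = (size + 2 * l.pad - l.kernel) // l.stride + 1
        elif l.kind == "fc":
            fan_in = prev_units * size * size
            weights += fan_in * l.unique_kernels
            biases += l.unique_kernels
            size = 1
        prev_units = l.unique_kernels
    return weights, biases


def rf_extent(arch: ArchitectureSpec, layer: str) -> int:
    """Maximal receptive-field extent (pixels, one dimension) at a sublayer.

    RF = 1 + sum (kernel - 1) * jump with jump the product of earlier
    strides; FC-stack sublayers see the whole input.
    """
    idx = arch.layer_index(layer)
    rf = 1
    jump = 1
    for l in arch.layers[: idx + 1]:
        if l.kind in ("fc", "prob"):
            return arch.input_size
        if l.kind in _SPATIAL:
            rf += (l.kernel - 1) * jump
            jump *= l.stride
    return rf


def architecture_report(arch: ArchitectureSpec) -> pd.DataFrame:
    """Per-sublayer table: units, grid, kernel, weights, biases, RF extent."""
    grids = grid_sizes(arch)
    rows = []
    size = arch.input_size
    prev_units = arch.input_channels
    for l in arch.layers:
        if l.kind == "conv":
            depth = l.input_channels_per_group or prev_units
            w = l.kernel * l.kernel * depth * l.unique_kernels
            b = l.unique_kernels
        elif l.kind == "fc":
            w = prev_units * size * size * l.unique_kernels
            b = l.unique_kernels
        else:
            w = b = 0
        rows.append(dict(name=l.name, kind=l.kind,
                         unique_units=l.unique_kernels, grid=grids[l.name],
                         kernel=l.kernel if l.kind in _SPATIAL else None,
                         weights=w, biases=b, rf_px=rf_extent(arch, l.name)))
        size = grids[l.name]
        prev_units = l.unique_kernels
    df = pd.DataFrame(rows)
    rows.append(dict(name="total", kind="", unique_units=df["unique_units"].sum(),
                     grid=None, kernel=None, weights=df["weights"].sum(),
                     biases=df["biases"].sum(), rf_px=None))
    return pd.DataFrame(rows)


def load_architecture(path) -> ArchitectureSpec:
    """Read an architecture from a YAML file (keys: input_size,
    input_channels, layers: list of LayerSpec fields)."""
    import yaml

    with open(path) as f:
        doc = yaml.safe_load(f)
    layers = [LayerSpec(**d) for d in doc["layers"]]
    return ArchitectureSpec(layers, doc.get("input_size", 227),
                            doc.get("input_channels", 3))
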