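"""Declarative 3D CNN architectures with exact parameter accounting.

Two architectures are provided, 3D adaptations of LeNet-5 and AlexNet
operating on ``(29, 25, 41)`` striatal ROI grids with one channel per
isosurface level:

LeNet-style (7 layers after the input)
    conv(5 @ 3x3x3, same) -> maxpool(2x2x2) -> conv(5 @ 3x3x3, same)
    -> maxpool(2x2x2) -> flatten(3,080) -> dense(4,096) -> dropout(0.5)
    -> dense(2, softmax); 12,628,790 trainable parameters at one channel.

AlexNet-style (12 layers)
    conv(10 @ 7^3) -> pool -> conv(8 @ 6^3) -> pool -> conv(7 @ 5^3)
    -> conv(6 @ 4^3) -> conv(5 @ 3^3) -> pool -> flatten(480)
    -> dense(2,048) -> dropout(0.7) -> dense(2,048) -> dropout(0.7)
    -> dense(2, softmax); 5,216,782 trainable parameters at one channel.

All convolutions are stride-1, "same"-padded and fully connected across
input channels; pooling is ceil-mode 2x2x2 (odd extents round up, so
29 -> 15 -> 8 -> 4). Parameter counts are derived symbolically from the
spec (`count_trainable_params`) and must match the realized array sizes of
the built numpy model — two independent accounting routes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from isoscan import nn
from isoscan.errors import ArchitectureError, ParameterError

DEFAULT_INPUT_SHAPE = (29, 25, 41)

_KINDS = ("conv3d", "maxpool3d", "flatten", "dense", "dropout")


@dataclass
class LayerSpec:
    """One declarative layer description.

    Only the fields appropriate for ``kind`` are meaningful: convolutions
    use ``n_kernels``/``kernel_size``/``stride``/``padding``, pooling uses
    ``kernel_size``, dense layers use ``units``/``activation`` and dropout
    uses ``rate``.
    """

    kind: str
    n_kernels: int | None = None
    kernel_size: tuple[int, int, int] | None = None
    stride: tuple[int, int, int] = (1, 1, 1)
    padding: str = "same"
    units: int | None = None
    rate: float | None = None
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ParameterError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv3d":
            if not self.n_kernels or self.n_kernels < 1:
                raise ParameterError("conv3d needs n_kernels >= 1")
            if self.kernel_size is None or any(k < 1 for k in self.kernel_size):
                raise ParameterError("conv3d needs kernel_size >= 1 per axis")
            if self.padding not in ("same", "valid"):
                raise ParameterError(f"padding must be same|valid, got {self.padding!r}")
        elif self.kind == "maxpool3d":
            if self.kernel_size is None or any(k < 1 for k in self.kernel_size):
                raise ParameterError("maxpool3d needs kernel_size >= 1 per axis")
        elif self.kind == "dense":
            if not self.units or self.units < 1:
                raise ParameterError("dense needs units >= 1")
        elif self.kind == "dropout":
            if self.rate is None or not (0.0 <= self.rate < 1.0):
                raise ParameterError("dropout needs rate in [0, 1)")

    def describe(self) -> str:
        if self.kind == "conv3d":
            kx, ky, kz = self.kernel_size
            return f"{self.n_kernels}@{kx}x{ky}x{kz}"
        if self.kind == "maxpool3d":
            kx, ky, kz = self.kernel_size
            return f"{kx}x{ky}x{kz}"
        if self.kind == "dense":
            return f"{self.units}"
        if self.kind == "dropout":
            return f"p={self.rate}"
        return ""


@dataclass
class ArchitectureSpec:
    """Ordered layer stack with a fixed input grid and channel count."""

    name: str
    input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
    n_input_channels: int = 1
    layers: list[LayerSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.input_shape = tuple(int(v) for v in self.input_shape)  # type: ignore[assignment]
        if self.n_input_channels < 1:
            raise ParameterError(
                f"n_input_channels must be >= 1, got {self.n_input_channels}"
            )
        if self.layers:
            last = self.layers[-1]
            if not (last.kind == "dense" and last.units == 2
                    and last.activation == "softmax"):
                raise ArchitectureError(
                    "architecture must end in a 2-unit softmax dense layer"
                )

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        payload = json.loads(text)
        layers = [LayerSpec(**{**d, "kernel_size": tuple(d["kernel_size"]) if d.get("kernel_size") else None,
                                "stride": tuple(d.get("stride", (1, 1, 1)))})
                  for d in payload.pop("layers")]
        payload["input_shape"] = tuple(payload["input_shape"])
        return cls(layers=layers, **payload)


def lenet3d_spec(
    n_input_channels: int, input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
) -> ArchitectureSpec:
    """LeNet-style 3D architecture (two 5-kernel 3x3x3 conv blocks)."""
    if n_input_channels < 1:
        raise ParameterError(f"n_input_channels must be >= 1, got {n_input_channels}")
    layers = [
        LayerSpec("conv3d", n_kernels=5, kernel_size=(3, 3, 3), activation="relu"),
        LayerSpec("maxpool3d", kernel_size=(2, 2, 2)),
        LayerSpec("conv3d", n_kernels=5, kernel_size=(3, 3, 3), activation="relu"),
        LayerSpec("maxpool3d", kernel_size=(2, 2, 2)),
        LayerSpec("flatten"),
        LayerSpec("dense", units=4096, activation="relu"),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("dense", units=2, activation="softmax"),
    ]
    return ArchitectureSpec(
        name="lenet3d", input_shape=tuple(input_shape),
        n_input_channels=n_input_channels, layers=layers,
    )


def alexnet3d_spec(
    n_input_channels: int, input_shape: tuple[int, int, int] = DEFAULT_INPUT_SHAPE
) -> ArchitectureSpec:
    """AlexNet-style 3D architecture (five conv layers, three dense)."""
    if n_input_channels < 1:
        raise ParameterError(f"n_input_channels must be >= 1, got {n_input_channels}")
    layers = [
        LayerSpec("conv3d", n_kernels=10, kernel_size=(7, 7, 7), activation="relu"),
        LayerSpec("maxpool3d", kernel_size=(2, 2, 2)),
        LayerSpec("conv3d", n_kernels=8, kernel_size=(6, 6, 6), activation="relu"),
        LayerSpec("maxpool3d", kernel_size=(2, 2, 2)),
        LayerSpec("conv3d", n_kernels=7, kernel_size=(5, 5, 5), activation="relu"),
        LayerSpec("conv3d", n_kernels=6, kernel_size=(4, 4, 4), activation="relu"),
        LayerSpec("conv3d", n_kernels=5, kernel_size=(3, 3, 3), activation="relu"),
        LayerSpec("maxpool3d", kernel_size=(2, 2, 2)),
        LayerSpec("flatten"),
        LayerSpec("dense", units=2048, activation="relu"),
        LayerSpec("dropout", rate=0.7),
        LayerSpec("dense", units=2048, activation="relu"),
        LayerSpec("dropout", rate=0.7),
        LayerSpec("dense", units=2, activation="softmax"),
    ]
    return ArchitectureSpec(
        name="alexnet3d", input_shape=tuple(input_shape),
        n_input_channels=n_input_channels, layers=layers,
    )


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[LayerSpec, tuple[int, ...]]]:
    """Output shape after each layer.

    Spatial shapes are ``(channels, x, y, z)`` until flatten, then a single
    width. Same-padded stride-1 convolutions preserve the spatial extent;
    ceil-mode pooling maps ``n -> ceil(n / k)``.
    """
    channels = spec.n_input_channels
    spatial: tuple[int, ...] | None = spec.input_shape
    out: list[tuple[LayerSpec, tuple[int, ...]]] = []
    width: int | None = None
    for layer in spec.layers:
        if layer.kind == "conv3d":
            if spatial is None:
                raise ArchitectureError("conv3d after flatten")
            if layer.padding == "valid":
                spatial = tuple(n - k + 1 for n, k in zip(spatial, layer.kernel_size))
            channels = layer.n_kernels  # type: ignore[assignment]
            shape = (channels, *spatial)
        elif layer.kind == "maxpool3d":
            if spatial is None:
                raise ArchitectureError("maxpool3d after flatten")
            spatial = tuple(-(-n // k) for n, k in zip(spatial, layer.kernel_size))
            shape = (channels, *spatial)
        elif layer.kind == "flatten":
            if spatial is None:
                raise ArchitectureError("flatten applied twice")
            width = channels * int(np.prod(spatial))
            spatial = None
            shape = (width,)
        elif layer.kind == "dense":
            if width is None:
                raise ArchitectureError("dense before flatten")
            width = layer.units  # type: ignore[assignment]
            shape = (width,)
        else:  # dropout
            shape = (width,) if spatial is None else (channels, *spatial)
        if any(v < 1 for v in shape):
            raise ArchitectureError(f"shape collapsed to {shape} at {layer.kind}")
        out.append((layer, shape))
    return out


@dataclass
class ParamCount:
    """Per-layer trainable-parameter counts and their total."""

    per_layer: list[tuple[LayerSpec, int]]
    total: int


def count_trainable_params(spec: ArchitectureSpec) -> ParamCount:
    """Exact symbolic parameter accounting.

    conv3d: ``prod(kernel) * in_channels * n_kernels + n_kernels``;
    dense: ``in_width * units + units``; pooling, flatten and dropout
    contribute nothing.
    """
    shapes = propagate_shapes(spec)
    in_channels = spec.n_input_channels
    in_width: int | None = None
    per_layer: list[tuple[LayerSpec, int]] = []
    for layer, shape in shapes:
        if layer.kind == "conv3d":
            count = int(np.prod(layer.kernel_size)) * in_channels * layer.n_kernels + layer.n_kernels
            in_channels = layer.n_kernels
        elif layer.kind == "dense":
            assert in_width is not None
            count = in_width * layer.units + layer.units
        else:
            count = 0
        if len(shape) == 1:
            in_width = shape[0]
        per_layer.append((layer, count))
    return ParamCount(per_layer=per_layer, total=sum(c for _, c in per_layer))


def architecture_table(spec: ArchitectureSpec) -> pd.DataFrame:
    """Human-readable report: layer, kernel/window, output shape, parameters."""
    shapes = propagate_shapes(spec)
    counts = count_trainable_params(spec)
    rows = []
    for (layer, shape), (_, count) in zip(shapes, counts.per_layer):
        if len(shape) == 4:
            shape_str = f"{shape[0]}@{shape[1]}x{shape[2]}x{shape[3]}"
        else:
            shape_str = str(shape[0])
        rows.append({
            "layer": layer.kind,
            "kernel_window": layer.describe(),
            "output_shape": shape_str,
            "trainable_parameters": count,
        })
    rows.append({
        "layer": "total", "kernel_window": "", "output_shape": "",
        "trainable_parameters": counts.total,
    })
    return pd.DataFrame(rows)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> nn.NeuralNetClassifier:
    """Realize an ArchitectureSpec as a trainable numpy classifier.

    Weights are He-uniform with zero biases, drawn from ``seed``; the
    realized parameter tensor sizes equal ``count_trainable_params`` layer
    by layer. The terminal softmax is applied by ``predict_proba`` (the
    network itself outputs logits, which saliency differentiates).
    """
    propagate_shapes(spec)  # validates the stack
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_channels = spec.n_input_channels
    spatial: tuple[int, ...] | None = spec.input_shape
    width: int | None = None
    for layer in spec.layers:
        if layer.kind == "conv3d":
            if layer.padding != "same" or tuple(layer.stride) != (1, 1, 1):
                raise ArchitectureError(
                    "the numpy backend realizes same-padded stride-1 convolutions only"
                )
            layers.append(nn.Conv3D(in_channels, layer.n_kernels, layer.kernel_size, rng))
            if layer.activation == "relu":
                layers.append(nn.ReLU())
            in_channels = layer.n_kernels
        elif layer.kind == "maxpool3d":
            if tuple(layer.kernel_size) != (2, 2, 2):
                raise ArchitectureError("the numpy backend realizes 2x2x2 pooling only")
            layers.append(nn.MaxPool3D())
            spatial = tuple(-(-n // 2) for n in spatial)
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
            width = in_channels * int(np.prod(spatial))
            spatial = None
        elif layer.kind == "dense":
            assert width is not None
            layers.append(nn.Dense(width, layer.units, rng))
            if layer.activation == "relu":
                layers.append(nn.ReLU())
            width = layer.units
        elif layer.kind == "dropout":
            layers.append(nn.Dropout(layer.rate))
    return nn.NeuralNetClassifier(
        net=nn.Sequential(layers),
        n_input_channels=spec.n_input_channels,
        input_shape=spec.input_shape,
        seed=seed,
    )
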