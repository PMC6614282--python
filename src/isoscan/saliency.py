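"""Gradient saliency volumes for trained classifiers.

A saliency map is the voxel-wise magnitude of the gradient of a class score
with respect to the input: voxels whose perturbation would change the
classifier's output the most. The gradient target is the pre-softmax class
score (the logit), which is invariant to the shared normalizing constant of
the softmax and is the standard choice for vanilla gradient saliency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from isoscan.errors import DegenerateInputError, ParameterError
from isoscan.isosurface import IsoChannelStack
from isoscan.nn import NeuralNetClassifier
from isoscan.preprocess import BrainVolume, save_nifti

_CLASS_INDEX = {"NC": 0, "PD": 1}
_REDUCTIONS = ("max-abs-over-channels", "mean-abs")


@dataclass
class SaliencyVolume:
    """Non-negative per-voxel saliency on the ROI grid."""

    data: np.ndarray
    target_class: str
    reduction: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("saliency must be a 3D grid")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("saliency must be finite and non-negative")

    def save_nifti(self, path: str) -> None:
        save_nifti(BrainVolume(self.data, subject_id=f"saliency-{self.target_class}"),
                   path)


def gradient_saliency(
    model: NeuralNetClassifier,
    stack: IsoChannelStack,
    target_class: str = "PD",
    reduction: str = "max-abs-over-channels",
) -> SaliencyVolume:
    """Absolute input gradient of the target-class logit, reduced over channels."""
    if target_class not in _CLASS_INDEX:
        raise ParameterError(f"target_class must be NC or PD, got {target_class!r}")
    if reduction not in _REDUCTIONS:
        raise ParameterError(f"reduction must be one of {_REDUCTIONS}")
    grad = model.input_gradient(stack.channels, _CLASS_INDEX[target_class])[0]
    mag = np.abs(grad)
    data = mag.max(axis=0) if reduction == "max-abs-over-channels" else mag.mean(axis=0)
    return SaliencyVolume(data=data, target_class=target_class, reduction=reduction)


def region_mass_fraction(saliency: SaliencyVolume, mask: np.ndarray) -> float:
    """Fraction of total saliency mass that lies inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != saliency.data.shape:
        raise ParameterError(
            f"mask shape {mask.shape} != saliency shape {saliency.data.shape}"
        )
    total = float(saliency.data.sum())
    if total <= 0:
        raise DegenerateInputError("total saliency is zero")
    return float(saliency.data[mask].sum() / total)
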