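"""Volume loading, ROI cropping and intensity normalization.

Input volumes are assumed to be spatially registered to a common template;
no reorientation or resampling is applied here. The standard preprocessing
chain for a registered DaTSCAN-like volume is

    crop_roi -> integral_normalize -> minmax_scale

which yields a striatal region of interest (default shape ``(29, 25, 41)``)
with intensities in ``[0, 1]``, the input contract of every downstream
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

from isoscan.errors import BoundsError, DegenerateInputError

#: Default striatal region-of-interest size (voxels).
DEFAULT_ROI_SIZE = (29, 25, 41)

_VALID_LABELS = ("NC", "PD", "unknown")


@dataclass
class BrainVolume:
    """A 3D scalar intensity grid with minimal provenance metadata.

    Parameters
    ----------
    data:
        3D array of finite intensities (arbitrary units before
        normalization, ``[0, 1]`` after full preprocessing).
    subject_id:
        Opaque identifier carried through the pipeline.
    label:
        Diagnostic class: ``"NC"``, ``"PD"`` or ``"unknown"``.
    """

    data: np.ndarray
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"every axis must have extent >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be one of {_VALID_LABELS}, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class RoiBox:
    """Axis-aligned crop box: 0-based inclusive start, half-open extent."""

    start: tuple[int, int, int]
    size: tuple[int, int, int] = field(default=DEFAULT_ROI_SIZE)

    def __post_init__(self) -> None:
        self.start = tuple(int(v) for v in self.start)  # type: ignore[assignment]
        self.size = tuple(int(v) for v in self.size)  # type: ignore[assignment]
        if len(self.start) != 3 or len(self.size) != 3:
            raise ValueError("start and size must be integer triples")
        if any(v < 0 for v in self.start):
            raise ValueError(f"start must be non-negative, got {self.start}")
        if any(v < 1 for v in self.size):
            raise ValueError(f"size must be positive, got {self.size}")

    def validate_against(self, shape: tuple[int, ...]) -> None:
        for axis, (s, n, extent) in enumerate(zip(self.start, self.size, shape)):
            if s + n > extent:
                raise BoundsError(
                    f"ROI box exceeds volume on axis {axis}: "
                    f"start {s} + size {n} > extent {extent}"
                )


def centered_box(
    shape: tuple[int, int, int], size: tuple[int, int, int] = DEFAULT_ROI_SIZE
) -> RoiBox:
    """Box of the given size centered on the volume midpoint.

    Registration places the striatum near the template center, so the
    centered box is the sensible default when no explicit offset is known.
    """
    start = tuple((dim - sz) // 2 for dim, sz in zip(shape, size))
    if any(s < 0 for s in start):
        raise BoundsError(f"size {size} does not fit inside shape {shape}")
    return RoiBox(start=start, size=tuple(size))  # type: ignore[arg-type]


def crop_roi(volume: BrainVolume, box: RoiBox) -> BrainVolume:
    """Extract the sub-volume ``[start, start + size)`` along each axis."""
    box.validate_against(volume.shape)
    sl = tuple(slice(s, s + n) for s, n in zip(box.start, box.size))
    return replace(volume, data=volume.data[sl].copy())


def integral_normalize(
    volume: BrainVolume, exclusion_mask: np.ndarray | None = None
) -> BrainVolume:
    """Divide the volume by its mean intensity.

    The normalization constant approximates the integral of tracer uptake
    over the brain, making intensities comparable across subjects. When
    ``exclusion_mask`` is given, voxels where the mask is True (e.g. the
    striatum itself) are excluded from the mean; the default whole-image
    mean is a close approximation in practice.
    """
    data = volume.data
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != data.shape:
            raise ValueError(
                f"mask shape {exclusion_mask.shape} != volume shape {data.shape}"
            )
        ref = data[~exclusion_mask]
        if ref.size == 0:
            raise DegenerateInputError("exclusion mask covers the whole volume")
        norm = float(ref.mean())
    else:
        norm = float(data.mean())
    if norm <= 0:
        raise DegenerateInputError(f"mean intensity must be positive, got {norm}")
    return replace(volume, data=data / norm)


def minmax_scale(volume: BrainVolume) -> BrainVolume:
    """Affinely rescale intensities to span exactly ``[0, 1]``."""
    lo = float(volume.data.min())
    hi = float(volume.data.max())
    if hi <= lo:
        raise DegenerateInputError("constant volume cannot be min-max scaled")
    return replace(volume, data=(volume.data - lo) / (hi - lo))


def preprocess_volume(volume: BrainVolume, box: RoiBox | None = None) -> BrainVolume:
    """Full chain: crop (centered by default), integral normalize, scale."""
    if box is None:
        box = centered_box(volume.shape)
    return minmax_scale(integral_normalize(crop_roi(volume, box)))


def load_nifti(path: str, label: str = "unknown", subject_id: str | None = None) -> BrainVolume:
    """Read a NIfTI-1 volume in stored voxel order (no reorientation)."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if subject_id is None:
        subject_id = str(path)
    return BrainVolume(data=data, subject_id=subject_id, label=label)


def save_nifti(volume: BrainVolume, path: str) -> None:
    """Write a volume as NIfTI-1 with an identity affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, path)
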