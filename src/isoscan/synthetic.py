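"""Synthetic striatal phantoms emulating DaTSCAN-like ROI volumes.

The phantom reproduces the statistical structure the classifier exploits,
not anatomy: two high-uptake structures per hemisphere — a spherical
"caudate" and an elongated ellipsoidal "putamen" — on a low-uptake
background, blurred by a Gaussian point-spread function and corrupted by
additive Gaussian noise (SPECT reconstruction noise is approximately
Gaussian after filtering). Healthy controls (NC) are mirror-symmetric
about the mid-sagittal plane; Parkinsonian subjects (PD) show reduced and
asymmetric putaminal uptake while the caudate is spared — the classic
early-PD pattern.

All volumes are min-max scaled to ``[0, 1]`` on the default ``(29, 25, 41)``
ROI grid, so they satisfy the same contract as fully preprocessed clinical
volumes and can be fed to every downstream stage directly.
"""

from __future__ import annotations

import csv
import hashlib
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from isoscan.errors import ParameterError
from isoscan.preprocess import BrainVolume, save_nifti

Triple = tuple[float, float, float]

_DEFAULT_GRID = (29, 25, 41)


def _default_centers(grid: tuple[int, int, int]) -> dict[str, tuple[Triple, Triple]]:
    """Structure centers for a grid, mirrored about the mid-sagittal plane.

    Axis 0 is left-right (mid-plane at ``(nx - 1) / 2``), axis 2 the long
    anterior-posterior axis: caudate anterior, putamen posterior, as in a
    registered striatal ROI.
    """
    mid = (grid[0] - 1) / 2.0
    cy = grid[1] / 2.0 - 0.5
    caud_z = grid[2] * 0.62
    put_z = grid[2] * 0.34
    dx_caud, dx_put = grid[0] * 0.155, grid[0] * 0.24
    return {
        "caudate": ((mid - dx_caud, cy, caud_z), (mid + dx_caud, cy, caud_z)),
        "putamen": ((mid - dx_put, cy, put_z), (mid + dx_put, cy, put_z)),
    }


@dataclass
class PhantomParams:
    """Geometry, contrast and noise settings of the striatal phantom.

    Defaults give an easy-but-not-trivial contrast: the affected putamen
    retains half its uptake (``pd_putamen_factor=0.5``) with a clearly
    lateralized deficit (``asymmetry=0.5``), PSF blur of 1.2 voxels and 5%
    additive noise.

    The background level must stay small for the PD factor to be
    interpretable on the final ``[0, 1]`` volume: min-max scaling maps the
    putamen mean ratio to ``(f - b) / (1 - b)`` exactly (the Gaussian PSF
    cancels), so ``b = 0.02`` keeps the realized ratio within 2% of ``f``.
    """

    grid: tuple[int, int, int] = _DEFAULT_GRID
    caudate_centers: tuple[Triple, Triple] | None = None
    putamen_centers: tuple[Triple, Triple] | None = None
    caudate_radius: float = 3.0
    putamen_semiaxes: Triple = (2.5, 3.0, 5.5)
    background_level: float = 0.02
    striatal_level: float = 1.0
    pd_putamen_factor: float = 0.5
    asymmetry: float = 0.5
    psf_sigma: float = 1.2
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = tuple(int(v) for v in self.grid)  # type: ignore[assignment]
        centers = _default_centers(self.grid)
        if self.caudate_centers is None:
            self.caudate_centers = centers["caudate"]
        if self.putamen_centers is None:
            self.putamen_centers = centers["putamen"]
        if not (0.0 <= self.background_level < self.striatal_level):
            raise ParameterError(
                "levels must satisfy 0 <= background_level < striatal_level"
            )
        if not (0.0 < self.pd_putamen_factor <= 1.0):
            raise ParameterError("pd_putamen_factor must lie in (0, 1]")
        if not (0.0 <= self.asymmetry <= 1.0):
            raise ParameterError("asymmetry must lie in [0, 1]")
        for name, ctrs, ext in (
            ("caudate", self.caudate_centers, (self.caudate_radius,) * 3),
            ("putamen", self.putamen_centers, self.putamen_semiaxes),
        ):
            for c in ctrs:
                for ax in range(3):
                    if not (0.0 <= c[ax] - ext[ax] and c[ax] + ext[ax] <= self.grid[ax] - 1):
                        raise ParameterError(
                            f"{name} at {c} with extent {ext} leaves the grid {self.grid}"
                        )

    def params_hash(self) -> str:
        text = repr(sorted(self.__dict__.items()))
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def _ellipsoid_mask(grid: tuple[int, int, int], center: Triple, semiaxes: Triple
                    ) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid], indexing="ij")
    q = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semiaxes))
    return q <= 1.0


def striatal_masks(params: PhantomParams) -> dict[str, np.ndarray]:
    """Generating masks: caudate/putamen per hemisphere plus their union."""
    out: dict[str, np.ndarray] = {}
    for side, idx in (("left", 0), ("right", 1)):
        out[f"caudate_{side}"] = _ellipsoid_mask(
            params.grid, params.caudate_centers[idx], (params.caudate_radius,) * 3
        )
        out[f"putamen_{side}"] = _ellipsoid_mask(
            params.grid, params.putamen_centers[idx], params.putamen_semiaxes
        )
    out["striatum"] = (
        out["caudate_left"] | out["caudate_right"]
        | out["putamen_left"] | out["putamen_right"]
    )
    return out


def generate_phantom(params: PhantomParams, label: str) -> BrainVolume:
    """One phantom volume, fully determined by ``params`` (incl. its seed).

    NC volumes are mirror-symmetric; for PD the more-affected putamen keeps
    ``pd_putamen_factor`` of its uptake and the contralateral one keeps
    ``f + asymmetry * (1 - f)`` (so asymmetry 0 reduces both equally and
    asymmetry 1 spares the contralateral side). The affected hemisphere is
    drawn at random from the seed. Caudate uptake is spared, matching the
    putamen-dominant early-PD deficit.
    """
    if label not in ("NC", "PD"):
        raise ParameterError(f"label must be NC or PD, got {label!r}")
    rng = np.random.default_rng(params.seed)
    affected = int(rng.integers(0, 2))  # consumed for NC too, keeps streams aligned
    masks = striatal_masks(params)

    f = params.pd_putamen_factor
    putamen_factors = [1.0, 1.0]
    if label == "PD":
        putamen_factors[affected] = f
        putamen_factors[1 - affected] = f + params.asymmetry * (1.0 - f)

    field_ = np.full(params.grid, params.background_level, dtype=np.float64)
    for side, idx in (("left", 0), ("right", 1)):
        np.maximum(field_, params.striatal_level * masks[f"caudate_{side}"],
                   out=field_)
        np.maximum(
            field_,
            params.striatal_level * putamen_factors[idx] * masks[f"putamen_{side}"],
            out=field_,
        )
    if params.psf_sigma > 0:
        field_ = ndimage.gaussian_filter(field_, sigma=params.psf_sigma)
    if params.noise_sigma > 0:
        field_ = field_ + rng.normal(0.0, params.noise_sigma, size=params.grid)
    field_ = np.clip(field_, 0.0, None)
    lo, hi = field_.min(), field_.max()
    field_ = (field_ - lo) / (hi - lo)
    return BrainVolume(data=field_, subject_id=f"{label}-{params.seed}", label=label)


def generate_cohort(
    n_nc: int,
    n_pd: int,
    params: PhantomParams | None = None,
    jitter: float = 0.5,
    seed: int = 0,
) -> list[tuple[BrainVolume, str]]:
    """Reproducible labeled cohort with per-subject parameter jitter.

    Each subject's structure centers are displaced by up to ``jitter``
    voxels per coordinate and contrast levels scaled by up to
    ``10% * jitter``, emulating residual registration error and uptake
    variability.
    """
    if n_nc < 0 or n_pd < 0:
        raise ParameterError("cohort sizes must be non-negative")
    if params is None:
        params = PhantomParams()
    cohort: list[tuple[BrainVolume, str]] = []
    labels = ["NC"] * n_nc + ["PD"] * n_pd
    for i, label in enumerate(labels):
        rng = np.random.default_rng([seed, i])

        def _jit_center(c: Triple) -> Triple:
            return tuple(v + rng.uniform(-jitter, jitter) for v in c)  # type: ignore[return-value]

        scale = 1.0 + rng.uniform(-0.1, 0.1) * jitter
        subj = replace(
            params,
            caudate_centers=tuple(_jit_center(c) for c in params.caudate_centers),
            putamen_centers=tuple(_jit_center(c) for c in params.putamen_centers),
            striatal_level=params.striatal_level * scale,
            background_level=params.background_level * scale,
            pd_putamen_factor=min(1.0, params.pd_putamen_factor
                                  * (1.0 + rng.uniform(-0.1, 0.1) * jitter)),
            seed=int(rng.integers(0, 2**31)),
        )
        vol = generate_phantom(subj, label)
        vol.subject_id = f"{label}{i:04d}"
        cohort.append((vol, label))
    return cohort


def save_cohort(cohort: list[tuple[BrainVolume, str]], out_dir: str,
                params: PhantomParams | None = None, seed: int | None = None) -> str:
    """Write NIfTI volumes plus a CSV manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    phash = params.params_hash() if params is not None else ""
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path", "seed", "params_hash"])
        for vol, label in cohort:
            fname = f"{vol.subject_id}.nii.gz"
            save_nifti(vol, os.path.join(out_dir, fname))
            writer.writerow([vol.subject_id, label, fname,
                             "" if seed is None else seed, phash])
    return manifest
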