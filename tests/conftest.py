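import numpy as np
import pytest
from scipy import ndimage

from isoscan.cnn_models import ArchitectureSpec, LayerSpec
from isoscan.preprocess import BrainVolume

SMALL_GRID = (15, 13, 21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_volume():
    """Centered radial ramp on a 41^3 grid: level t sits at radius 20*(1-t)."""
    n = 41
    c = (n - 1) / 2
    g = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    rad = np.sqrt(sum((a - c) ** 2 for a in g))
    return BrainVolume(np.clip(1 - rad / c, 0, 1), subject_id="ramp")


def smoothed_sphere(radius: int, n: int, sigma: float = 1.0) -> BrainVolume:
    """Binary solid sphere anti-aliased with a fixed 1-voxel Gaussian."""
    c = (n - 1) / 2
    g = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    d2 = sum((a - c) ** 2 for a in g)
    f = (d2 <= radius * radius).astype(float)
    return BrainVolume(ndimage.gaussian_filter(f, sigma), subject_id=f"sphere{radius}")


def tiny_builder(input_shape=SMALL_GRID, hidden=8):
    """Cheap flatten->dense architecture factory for CV machinery tests."""

    def build(n_channels: int) -> ArchitectureSpec:
        return ArchitectureSpec(
            name="tiny",
            input_shape=tuple(input_shape),
            n_input_channels=n_channels,
            layers=[
                LayerSpec("flatten"),
                LayerSpec("dense", units=hidden, activation="relu"),
                LayerSpec("dense", units=2, activation="softmax"),
            ],
        )

    return build


def planted_signal_cohort(n_per_class=10, grid=SMALL_GRID, seed=0,
                          noise=0.01):
    """Cohort where only the 0.7 super-level set separates the classes.

    Everyone has a central blob at 0.65; PD subjects additionally have a
    sub-blob raised to 0.75. Channels at 0.4/0.5/0.6 are therefore
    class-identical (up to tiny noise), 0.8 is empty and 0.7 is perfectly
    informative.
    """
    rng = np.random.default_rng(seed)
    gx, gy, gz = grid
    blob = np.zeros(grid, dtype=bool)
    blob[gx // 4: 3 * gx // 4, gy // 4: 3 * gy // 4, gz // 4: 3 * gz // 4] = True
    sub = np.zeros(grid, dtype=bool)
    sub[gx // 3: 2 * gx // 3, gy // 3: 2 * gy // 3, gz // 3: 2 * gz // 3] = True
    cohort = []
    for i in range(2 * n_per_class):
        label = "NC" if i < n_per_class else "PD"
        data = np.full(grid, 0.3)
        data[blob] = 0.65
        if label == "PD":
            data[sub] = 0.75
        data = np.clip(data + rng.normal(0, noise, grid), 0.0, 1.0)
        cohort.append((BrainVolume(data, subject_id=f"{label}{i:03d}", label=label),
                       label))
    return cohort
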