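"""Isosurface and isoline extraction, and rasterization into CNN channels.

An isosurface at level ``t`` is the boundary of the super-level set
``{v : I(v) >= t}`` of the trilinearly interpolated intensity field — the
3D analogue of a contour line. Surfaces at increasing levels are nested and
never cross. Meshes are extracted with the topology-correct (Lewiner)
marching-cubes variant in voxel coordinates; isolines are 2D slices of the
same construction.

For classification the surfaces are rasterized back onto the ROI grid, one
channel per level, so that a stack of ``n`` levels is an ``n``-channel 3D
image — the channel count is the ``#inputs`` of the first convolutional
layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from isoscan.errors import ParameterError
from isoscan.preprocess import BrainVolume

MODES = ("binary", "fractional", "shell")


@dataclass
class TriangleMesh:
    """Triangulated isosurface in continuous voxel coordinates."""

    vertices: np.ndarray  # (n_vertices, 3) float
    faces: np.ndarray  # (n_faces, 3) int
    level: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def surface_area(self) -> float:
        """Total area of all triangles (voxel-length units squared)."""
        if self.is_empty:
            return 0.0
        return float(measure.mesh_surface_area(self.vertices, self.faces))

    def export_ply(self, path: str) -> None:
        """Write ASCII PLY."""
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"comment isosurface level {self.level}\n")
            fh.write(f"element vertex {len(self.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(self.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    def export_obj(self, path: str) -> None:
        """Write Wavefront OBJ (1-based face indices)."""
        with open(path, "w") as fh:
            fh.write(f"# isosurface level {self.level}\n")
            for v in self.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


@dataclass
class IsoPolyline:
    """Open or closed 2D contour at a fixed level, in continuous coordinates."""

    points: np.ndarray  # (n_points, 2)
    level: float
    closed: bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")

    def enclosed_area(self) -> float:
        """Absolute area by the shoelace formula (closed polylines)."""
        p = self.points
        x, y = p[:, 0], p[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def contains_point(self, point: np.ndarray) -> bool:
        """Ray-casting point-in-polygon test against the closed contour."""
        x, y = float(point[0]), float(point[1])
        p = self.points
        x0, y0 = p[:, 0], p[:, 1]
        x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
        crossing = (y0 > y) != (y1 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
        return bool(np.sum(crossing & (x < xint)) % 2 == 1)


@dataclass
class IsoChannelStack:
    """Multi-channel rasterized isosurface stack fed to the CNN.

    Channels are stored with levels sorted in strictly increasing order, so
    in binary mode channel ``i`` (lower level) is an element-wise superset
    of channel ``j > i`` (nesting of super-level sets).
    """

    channels: np.ndarray  # (n_levels, x, y, z) in [0, 1]
    levels: tuple[float, ...]
    mode: str = "binary"
    subject_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.levels = tuple(float(v) for v in self.levels)
        if self.channels.ndim != 4:
            raise ValueError("channels must be a 4D (n_levels, x, y, z) array")
        if len(self.levels) != self.channels.shape[0]:
            raise ValueError("len(levels) must equal the number of channels")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError(f"levels must be strictly increasing, got {self.levels}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def n_channels(self) -> int:
        return int(self.channels.shape[0])

    def select(self, levels: list[float] | tuple[float, ...]) -> "IsoChannelStack":
        """Sub-stack restricted to the given subset of levels."""
        wanted = sorted(float(v) for v in levels)
        idx = []
        for lv in wanted:
            matches = [i for i, have in enumerate(self.levels) if abs(have - lv) < 1e-12]
            if not matches:
                raise ParameterError(f"level {lv} not present in stack {self.levels}")
            idx.append(matches[0])
        return IsoChannelStack(
            channels=self.channels[idx],
            levels=tuple(wanted),
            mode=self.mode,
            subject_id=self.subject_id,
            label=self.label,
        )


def _check_level(level: float) -> float:
    level = float(level)
    if not (0.0 < level < 1.0):
        raise ParameterError(f"iso level must lie strictly in (0, 1), got {level}")
    return level


def extract_isosurface(volume: BrainVolume, level: float) -> TriangleMesh:
    """Marching-cubes isosurface of the interpolated field at ``level``.

    Uses the Lewiner topology-correct variant with per-edge linear
    interpolation, no smoothing, in voxel coordinates. A level that no voxel
    pair straddles yields an empty mesh (not an error).
    """
    level = _check_level(level)
    data = volume.data
    if data.min() >= level or data.max() < level:
        return TriangleMesh(
            vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=np.int64), level=level
        )
    verts, faces, _normals, _values = measure.marching_cubes(
        data, level=level, method="lewiner"
    )
    return TriangleMesh(vertices=verts, faces=faces, level=level)


_AXES = {"x": 0, "y": 1, "z": 2}


def extract_isolines(
    volume: BrainVolume, level: float, axis: str, slice_index: int
) -> list[IsoPolyline]:
    """2D contour polylines of one slice at ``level``.

    Isolines are slices of the corresponding isosurfaces: closed curves that
    never cross across levels, whose spacing encodes the intensity gradient.
    """
    level = _check_level(level)
    if axis not in _AXES:
        raise ParameterError(f"axis must be one of {tuple(_AXES)}, got {axis!r}")
    ax = _AXES[axis]
    extent = volume.shape[ax]
    slice_index = int(slice_index)
    if not (0 <= slice_index < extent):
        raise ParameterError(
            f"slice_index {slice_index} outside axis {axis!r} extent {extent}"
        )
    plane = np.take(volume.data, slice_index, axis=ax)
    contours = measure.find_contours(plane, level=level)
    out = []
    for pts in contours:
        closed = bool(np.allclose(pts[0], pts[-1]))
        out.append(IsoPolyline(points=pts, level=level, closed=closed))
    return out


def rasterize(volume: BrainVolume, level: float, mode: str = "binary") -> np.ndarray:
    """Rasterize the super-level set at ``level`` onto the voxel grid.

    binary
        1 where voxel intensity >= level, else 0 (ties count as inside).
    fractional
        per-voxel occupancy of the super-level set, estimated by 3x3x3
        trilinear supersampling of the interpolated field; uniform interior
        and exterior voxels come out exactly 1 and 0.
    shell
        1 only on voxels adjacent to a binary sign change, i.e. voxels the
        extracted surface passes through or next to.
    """
    level = _check_level(level)
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}, got {mode!r}")
    data = volume.data
    if mode == "binary":
        return (data >= level).astype(np.float32)
    if mode == "fractional":
        offsets = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
        grids = np.meshgrid(
            *[np.arange(n, dtype=np.float64) for n in data.shape], indexing="ij"
        )
        frac = np.zeros(data.shape, dtype=np.float64)
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    coords = np.stack(
                        [grids[0] + dx, grids[1] + dy, grids[2] + dz], axis=0
                    )
                    sample = ndimage.map_coordinates(
                        data, coords.reshape(3, -1), order=1, mode="nearest"
                    ).reshape(data.shape)
                    frac += sample >= level
        return (frac / offsets.size**3).astype(np.float32)
    # shell: voxels where the binary mask changes across any 6-neighbor edge
    b = data >= level
    edge = np.zeros(data.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        diff = b[tuple(sl_a)] != b[tuple(sl_b)]
        edge[tuple(sl_a)] |= diff
        edge[tuple(sl_b)] |= diff
    return edge.astype(np.float32)


def build_channel_stack(
    volume: BrainVolume, levels: list[float], mode: str = "binary"
) -> IsoChannelStack:
    """Rasterize one channel per level into a single stack.

    Levels are treated as a set and stored in increasing order; duplicates
    are rejected.
    """
    if not levels:
        raise ParameterError("levels must be non-empty")
    levels = [_check_level(v) for v in levels]
    srt = sorted(levels)
    if any(abs(b - a) < 1e-12 for a, b in zip(srt, srt[1:])):
        raise ParameterError(f"duplicate levels are not allowed: {levels}")
    channels = np.stack([rasterize(volume, lv, mode=mode) for lv in srt], axis=0)
    return IsoChannelStack(
        channels=channels,
        levels=tuple(srt),
        mode=mode,
        subject_id=volume.subject_id,
        label=volume.label,
    )


def isolines_to_csv(polylines: list[IsoPolyline], path: str) -> None:
    """Write polylines as rows (level, polyline_id, point_index, u, v)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "polyline_id", "point_index", "u", "v"])
        for pid, poly in enumerate(polylines):
            for i, (u, v) in enumerate(poly.points):
                writer.writerow([poly.level, pid, i, f"{u:.6f}", f"{v:.6f}"])
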