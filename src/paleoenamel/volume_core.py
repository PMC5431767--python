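"""Grey-level volume data model, TIFF I/O, reslicing and transect extraction.

Conventions used throughout the package:

* axis order is ``(z, y, x)`` where ``z`` is the stack-page axis, then row,
  then column;
* indices are 0-based and voxel-centred: voxel ``(i, j, k)`` sits at physical
  coordinate ``origin + (i, j, k) * voxel_size`` (micrometres);
* physical points are 3-vectors in the same ``(z, y, x)`` order, in µm.

Grey levels are an uncalibrated mineral-density proxy.  Values are kept in
floating point during analysis and only clamped to the 16-bit range when a
volume is written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import map_coordinates

__all__ = [
    "GreyLevelVolume",
    "Transect",
    "save_volume",
    "load_volume",
    "read_landmarks",
    "sample_points",
    "reslice_to_plane",
    "extract_transect",
]

_AXIS_ORDER = "zyx"
_EPS = 1e-9


@dataclass
class GreyLevelVolume:
    """3D grey-level array plus physical metadata.

    Parameters
    ----------
    values
        3D array of grey levels, axis order ``(z, y, x)``.
    voxel_size
        Edge length of a voxel per axis in µm (isotropic 7 µm by default).
    origin
        Physical coordinate (µm) of the centre of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.full(3, 7.0))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive on every axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def center_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent spanned by voxel centres (low, high) per axis."""
        low = self.origin.copy()
        high = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return low, high

    def cell_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent of the voxel cells including half-voxel margins."""
        low, high = self.center_extent()
        return low - self.voxel_size / 2, high + self.voxel_size / 2

    def to_index(self, point: np.ndarray) -> np.ndarray:
        """Convert a physical point (µm) to fractional voxel indices."""
        return (np.asarray(point, dtype=float) - self.origin) / self.voxel_size

    def contains_point(self, point: np.ndarray) -> bool:
        """True if ``point`` lies inside the voxel-centre extent."""
        low, high = self.center_extent()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= low - _EPS) and np.all(p <= high + _EPS))


@dataclass
class Transect:
    """A sampled straight line through a volume.

    ``start`` is the enamel-surface end, ``end`` the DEJ end; ``samples``
    run from start to end at ``step`` µm intervals (final step may be
    shorter so that the endpoint is always sampled).  Samples are obtained
    by trilinear interpolation.
    """

    start: np.ndarray
    end: np.ndarray
    samples: np.ndarray
    step: float
    positions: np.ndarray  # distance of each sample from start, µm
    orientation: str = "surface_to_dej"

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        self.samples = np.asarray(self.samples, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.samples.size < 2:
            raise ValueError("a transect needs at least 2 samples")
        if self.samples.shape != self.positions.shape:
            raise ValueError("samples and positions must have the same length")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    def reversed(self) -> "Transect":
        """Same line traversed end→start (sample order reversed)."""
        length = self.length_um
        orient = (
            "dej_to_surface"
            if self.orientation == "surface_to_dej"
            else "surface_to_dej"
        )
        return Transect(
            start=self.end,
            end=self.start,
            samples=self.samples[::-1].copy(),
            step=self.step,
            positions=(length - self.positions)[::-1].copy(),
            orientation=orient,
        )


# ---------------------------------------------------------------------------
# I/O


def save_volume(vol: GreyLevelVolume, tiff_path: str | Path) -> Path:
    """Write a volume as a 16-bit multi-page TIFF with a YAML sidecar.

    Float values are rounded and clamped to the 16-bit range at write time
    only.  The sidecar ``<stem>.yaml`` records voxel size, axis order and
    origin so that :func:`load_volume` can round-trip the volume.
    """
    tiff_path = Path(tiff_path)
    arr = np.asarray(vol.values)
    if arr.dtype != np.uint16:
        arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(tiff_path, arr)
    sidecar = tiff_path.with_suffix(".yaml")
    meta = {
        "voxel_size_um": [float(v) for v in vol.voxel_size],
        "axis_order": _AXIS_ORDER,
        "origin_um": [float(v) for v in vol.origin],
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return tiff_path


def load_volume(tiff_path: str | Path) -> GreyLevelVolume:
    """Read a volume written by :func:`save_volume` (bit-exact round trip)."""
    tiff_path = Path(tiff_path)
    values = tifffile.imread(tiff_path)
    sidecar = tiff_path.with_suffix(".yaml")
    voxel_size = np.full(3, 7.0)
    origin = np.zeros(3)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        voxel_size = np.asarray(meta.get("voxel_size_um", voxel_size), dtype=float)
        origin = np.asarray(meta.get("origin_um", origin), dtype=float)
        order = meta.get("axis_order", _AXIS_ORDER)
        if order != _AXIS_ORDER:
            raise ValueError(f"unsupported axis order {order!r}, expected {_AXIS_ORDER!r}")
    return GreyLevelVolume(values=values, voxel_size=voxel_size, origin=origin)


def read_landmarks(csv_path: str | Path) -> dict[str, np.ndarray]:
    """Read a landmark CSV ``label,x_um,y_um,z_um`` into (z, y, x) points."""
    import pandas as pd

    df = pd.read_csv(csv_path)
    required = {"label", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    return {
        str(row.label): np.array([row.z_um, row.y_um, row.x_um], dtype=float)
        for row in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Sampling


def sample_points(vol: GreyLevelVolume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the volume at physical points (n, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = (pts - vol.origin) / vol.voxel_size
    return map_coordinates(
        vol.values.astype(np.float64), idx.T, order=1, mode="nearest"
    )


def reslice_to_plane(
    vol: GreyLevelVolume,
    p_buccal1: np.ndarray,
    p_buccal2: np.ndarray,
    p_lingual: np.ndarray,
) -> GreyLevelVolume:
    """Resample the volume so its first axis is normal to a 3-point plane.

    The three points define the cervical plane of section; the output grid
    keeps the input voxel size and covers the input's voxel-centre bounding
    box, with grey values obtained by trilinear interpolation (regions
    outside the input are filled with 0).  Axis signs are canonicalised so
    that planes aligned with an existing axis reproduce the input grid.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float).reshape(3) for p in (p_buccal1, p_buccal2, p_lingual))
    for name, p in (("p_buccal1", p1), ("p_buccal2", p2), ("p_lingual", p3)):
        if not vol.contains_point(p):
            raise ValueError(f"{name} {p.tolist()} lies outside the volume")
    e1 = p2 - p1
    e2 = p3 - p1
    normal = np.cross(e1, e2)
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    if scale < _EPS or np.linalg.norm(normal) < 1e-8 * scale:
        raise ValueError("degenerate plane: points are collinear or coincident")
    n = _canonical_unit(normal)
    u = _canonical_unit(e1)
    v = _canonical_unit(np.cross(n, u))
    rot = np.stack([n, u, v])  # rows = new axes in old coordinates

    # Project the voxel-centre bounding box into the new frame.
    low, high = vol.center_extent()
    corners = np.array(
        [[a, b, c] for a in (low[0], high[0]) for b in (low[1], high[1]) for c in (low[2], high[2])]
    )
    proj = corners @ rot.T
    lo = proj.min(axis=0)
    hi = proj.max(axis=0)
    step = vol.voxel_size
    counts = np.floor((hi - lo) / step + 1e-6).astype(int) + 1

    grids = np.meshgrid(
        *[lo[a] + np.arange(counts[a]) * step[a] for a in range(3)], indexing="ij"
    )
    new_coords = np.stack([g.ravel() for g in grids], axis=1)
    old_coords = new_coords @ rot  # rot is orthonormal: inverse = transpose
    idx = (old_coords - vol.origin) / vol.voxel_size
    vals = map_coordinates(
        vol.values.astype(np.float64), idx.T, order=1, mode="constant", cval=0.0
    ).reshape(tuple(counts))
    return GreyLevelVolume(values=vals, voxel_size=vol.voxel_size.copy(), origin=np.zeros(3))


def _canonical_unit(vec: np.ndarray) -> np.ndarray:
    """Unit vector with the sign fixed so its largest component is positive."""
    unit = vec / np.linalg.norm(vec)
    lead = np.argmax(np.abs(unit))
    if unit[lead] < 0:
        unit = -unit
    # snap tiny components so axis-aligned frames are exact
    unit[np.abs(unit) < 1e-12] = 0.0
    return unit / np.linalg.norm(unit)


def extract_transect(
    vol: GreyLevelVolume, surface_pt: np.ndarray, dej_pt: np.ndarray
) -> Transect:
    """Sample the straight line surface→DEJ at voxel-size steps.

    Samples are taken every ``step`` µm from ``surface_pt`` towards
    ``dej_pt``; both endpoints are always sampled (the final step may be
    shorter).  ``step`` is the (isotropic) voxel size.
    """
    a = np.asarray(surface_pt, dtype=float).reshape(3)
    b = np.asarray(dej_pt, dtype=float).reshape(3)
    for name, p in (("surface_pt", a), ("dej_pt", b)):
        if not vol.contains_point(p):
            raise ValueError(f"{name} {p.tolist()} lies outside the volume")
    length = float(np.linalg.norm(b - a))
    if length < _EPS:
        raise ValueError("surface and DEJ points coincide")
    if not np.allclose(vol.voxel_size, vol.voxel_size[0]):
        raise ValueError("transect extraction requires isotropic voxels")
    step = float(vol.voxel_size[0])

    n_whole = int(np.floor(length / step + _EPS))
    positions = np.arange(n_whole + 1) * step
    if positions[-1] < length - step * 1e-9:
        positions = np.append(positions, length)
    else:
        positions[-1] = length  # guard against fp drift on exact multiples
    direction = (b - a) / length
    pts = a[None, :] + positions[:, None] * direction[None, :]
    samples = sample_points(vol, pts)
    return Transect(
        start=a, end=b, samples=samples, step=step, positions=positions,
        orientation="surface_to_dej",
    )
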