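"""Five-cube densitometry: paired normal/discoloured grey-level means over
two measurement rounds, the mdd table, and the per-tooth paired test.

Cube layout along a surface→DEJ transect: cube 1 at the surface, cube 5 at
the DEJ, cube 3 midway between 1 and 5, cube 2 midway between 1 and 3,
cube 4 midway between 3 and 5 — i.e. fractional positions 0, 1/4, 1/2, 3/4, 1
of the transect, each centre then clamped so the cube's voxel-centre
footprint stays inside the transect span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .npstats import WilcoxonResult, wilcoxon_signed_rank
from .volume_core import GreyLevelVolume, Transect

__all__ = [
    "DEFAULT_CUBE_EDGE_UM",
    "CubeSet",
    "MddTable",
    "place_cubes",
    "cube_mean",
    "paired_cube_analysis",
    "mdd_table_to_frame",
    "write_mdd_csv",
]

DEFAULT_CUBE_EDGE_UM = 49.0  # ~7 voxels at 7 µm
_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
_EPS = 1e-9


@dataclass
class CubeSet:
    """Five cube centres ordered cube1 (surface) … cube5 (DEJ)."""

    centers: np.ndarray  # (5, 3) physical points, µm
    edge: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(5, 3)
        if self.edge <= 0:
            raise ValueError("cube edge must be positive")


@dataclass
class MddTable:
    """Per-tooth mineral-density differences: 2 rounds x 5 cubes.

    ``mdd[i] = normal_mean[i] - discoloured_mean[i]`` exactly, ordered
    round 1 cubes 1–5 then round 2 cubes 1–5.  ``p_value`` is the two-sided
    paired signed-rank result over the 10 values (None when every mdd is
    zero, in which case ``label`` is ``"no difference"``).
    """

    tooth_id: str
    normal_means: np.ndarray  # (2, 5)
    discoloured_means: np.ndarray  # (2, 5)
    mdd: np.ndarray  # (10,)
    p_value: float | None
    method: str
    label: str = "tested"
    test: WilcoxonResult | None = None
    heights: dict = field(default_factory=dict)  # recorded, not validated

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05

    @property
    def median_mdd(self) -> float:
        return float(np.median(self.mdd))


def place_cubes(transect: Transect, edge: float = DEFAULT_CUBE_EDGE_UM) -> CubeSet:
    """Place the five analysis cubes along a transect.

    Unclamped centres sit at fractions 0, 1/4, 1/2, 3/4, 1 of the
    surface→DEJ line; each is then clamped so the cube's voxel-centre
    footprint (half-width ``(edge - step) / 2``) lies within the span.
    """
    length = transect.length_um
    if edge > length + _EPS:
        raise ValueError(
            f"cube edge {edge:g} µm exceeds transect length {length:g} µm"
        )
    half = max(0.0, (edge - transect.step) / 2.0)
    direction = (transect.end - transect.start) / length
    dists = np.clip([f * length for f in _FRACTIONS], half, length - half)
    centers = transect.start[None, :] + dists[:, None] * direction[None, :]
    return CubeSet(centers=centers, edge=float(edge))


def cube_mean(vol: GreyLevelVolume, center: np.ndarray, edge: float) -> float:
    """Arithmetic mean of all voxels whose centres fall inside the closed
    axis-aligned cube of the given edge around ``center``.

    Raises when the cube extends beyond the volume's voxel cells.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    lo_cell, hi_cell = vol.cell_extent()
    lo = center - edge / 2.0
    hi = center + edge / 2.0
    if np.any(lo < lo_cell - _EPS) or np.any(hi > hi_cell + _EPS):
        raise ValueError(
            f"cube at {center.tolist()} (edge {edge:g} µm) extends outside the volume"
        )
    sl = []
    for ax in range(3):
        coords = vol.origin[ax] + np.arange(vol.shape[ax]) * vol.voxel_size[ax]
        inside = np.nonzero((coords >= lo[ax] - _EPS) & (coords <= hi[ax] + _EPS))[0]
        if inside.size == 0:
            raise ValueError("cube contains no voxel centres")
        sl.append(slice(inside[0], inside[-1] + 1))
    block = vol.values[sl[0], sl[1], sl[2]]
    return float(np.mean(block.astype(np.float64)))


def paired_cube_analysis(
    vol: GreyLevelVolume,
    normal_transects,
    discoloured_transects,
    edge: float = DEFAULT_CUBE_EDGE_UM,
    method: str = "normal_approx",
    tooth_id: str = "tooth",
) -> MddTable:
    """Run the full 3D analysis: two rounds of five paired cube means, mdd
    values, and a two-sided signed-rank test of mdd against zero.

    Callers are responsible for placing the normal and discoloured transects
    of each round at the same coronal height; heights are recorded in the
    output but not validated.
    """
    normal_transects = list(normal_transects)
    discoloured_transects = list(discoloured_transects)
    if len(normal_transects) != 2 or len(discoloured_transects) != 2:
        raise ValueError("exactly 2 rounds of normal and discoloured transects are required")

    normal_means = np.empty((2, 5))
    disc_means = np.empty((2, 5))
    heights: dict = {}
    for r, (t_norm, t_disc) in enumerate(zip(normal_transects, discoloured_transects)):
        for label, transect, out in (
            ("normal", t_norm, normal_means),
            ("discoloured", t_disc, disc_means),
        ):
            cubes = place_cubes(transect, edge)
            out[r] = [cube_mean(vol, c, edge) for c in cubes.centers]
            heights[f"round{r + 1}_{label}_surface"] = transect.start.tolist()
            heights[f"round{r + 1}_{label}_dej"] = transect.end.tolist()

    mdd = (normal_means - disc_means).ravel()
    if np.all(mdd == 0.0):
        return MddTable(
            tooth_id=tooth_id,
            normal_means=normal_means,
            discoloured_means=disc_means,
            mdd=mdd,
            p_value=None,
            method=method,
            label="no difference",
            heights=heights,
        )
    result = wilcoxon_signed_rank(mdd, method=method)
    return MddTable(
        tooth_id=tooth_id,
        normal_means=normal_means,
        discoloured_means=disc_means,
        mdd=mdd,
        p_value=result.p_two_sided,
        method=method,
        label="tested",
        test=result,
        heights=heights,
    )


def mdd_table_to_frame(table: MddTable) -> pd.DataFrame:
    """Long-form frame with one row per (round, cube), mirroring the layout
    tooth / round / cube / normal_GL / discoloured_GL / mdd."""
    rows = []
    for r in range(2):
        for c in range(5):
            rows.append(
                {
                    "tooth": table.tooth_id,
                    "round": r + 1,
                    "cube": c + 1,
                    "normal_GL": table.normal_means[r, c],
                    "discoloured_GL": table.discoloured_means[r, c],
                    "mdd": table.mdd[r * 5 + c],
                }
            )
    return pd.DataFrame(rows)


def write_mdd_csv(table: MddTable, path: str | Path) -> Path:
    path = Path(path)
    mdd_table_to_frame(table).to_csv(path, index=False)
    return path
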