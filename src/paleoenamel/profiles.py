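"""DEJ→surface density profiles: 99-point equidistant resampling, deficit
curves and gradient-direction classification."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .volume_core import GreyLevelVolume, Transect, extract_transect

__all__ = [
    "N_PROFILE_POINTS",
    "MID_WINDOW",
    "DensityProfile",
    "GradientResult",
    "ProfileComparison",
    "resample_profile",
    "compare_profiles",
    "gradient_direction",
    "profile_from_lines",
    "comparison_to_frame",
    "write_comparison_csv",
    "plot_comparison",
]

N_PROFILE_POINTS = 99
#: mid-enamel averaging window, 1-based point numbers (u in [0.449, 0.551])
MID_WINDOW = (45, 55)
_RANK_CORR_THRESHOLD = 0.3


@dataclass
class DensityProfile:
    """Exactly 99 grey levels, point 1 at the DEJ (u=0), point 99 at the
    surface (u=1), positions strictly increasing."""

    values: np.ndarray
    positions: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, N_PROFILE_POINTS)
    )
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.positions = np.asarray(self.positions, dtype=float).ravel()
        if self.values.size != N_PROFILE_POINTS:
            raise ValueError(f"profile must have exactly {N_PROFILE_POINTS} points")
        if self.positions.size != N_PROFILE_POINTS:
            raise ValueError("positions must match the 99 profile points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if abs(self.positions[0]) > 1e-9 or abs(self.positions[-1] - 1.0) > 1e-9:
            raise ValueError("positions must span [0, 1] exactly")

    def reversed(self) -> "DensityProfile":
        return DensityProfile(
            values=self.values[::-1].copy(),
            positions=(1.0 - self.positions)[::-1].copy(),
            source=dict(self.source, reversed=True),
        )


@dataclass(frozen=True)
class GradientResult:
    slope: float  # grey level per unit u, least squares
    rank_corr: float  # Spearman correlation of value vs position
    label: str  # increasing | reversed | flat


@dataclass
class ProfileComparison:
    deficit_curve: np.ndarray  # (normal - lesion) / normal per point
    max_deficit: float
    mid_deficit: float  # mean deficit over the mid-enamel window
    gradient_normal: GradientResult
    gradient_lesion: GradientResult
    positions: np.ndarray
    normal_values: np.ndarray
    lesion_values: np.ndarray
    mid_window: tuple[int, int] = MID_WINDOW


def resample_profile(raw: Transect | DensityProfile) -> DensityProfile:
    """Resample a native-step transect to the 99 equidistant DEJ→surface
    points by linear interpolation; endpoints are preserved exactly.

    Accepts a :class:`Transect` in either orientation (the orientation
    metadata is used to flip surface→DEJ samples) or an existing profile,
    on which the operation is idempotent.
    """
    if isinstance(raw, DensityProfile):
        pos, vals, source = raw.positions, raw.values, dict(raw.source)
    else:
        if raw.samples.size < 2:
            raise ValueError("need at least 2 raw samples to resample")
        length = raw.length_um
        if raw.orientation == "surface_to_dej":
            vals = raw.samples[::-1]
            pos = (length - raw.positions)[::-1] / length
        else:
            vals = raw.samples
            pos = raw.positions / length
        source = {
            "start": raw.start.tolist(),
            "end": raw.end.tolist(),
            "length_um": length,
            "step_um": raw.step,
            "orientation": raw.orientation,
        }
    target = np.linspace(0.0, 1.0, N_PROFILE_POINTS)
    out = np.interp(target, pos, vals)
    out[0] = vals[0]
    out[-1] = vals[-1]
    return DensityProfile(values=out, positions=target, source=source)


def profile_from_lines(vol: GreyLevelVolume, lines) -> DensityProfile:
    """Average several parallel surface→DEJ transects into one profile.

    ``lines`` is an iterable of ``(surface_pt, dej_pt)`` pairs of identical
    geometry (same length); the native-step samples are averaged pointwise
    before the 99-point resampling.  Lateral averaging mirrors reading a
    profile as the mean grey level across the width of the plotted line.
    """
    lines = list(lines)
    if not lines:
        raise ValueError("need at least one line")
    transects = [extract_transect(vol, s, d) for s, d in lines]
    n = transects[0].samples.size
    if any(t.samples.size != n for t in transects):
        raise ValueError("all averaged lines must have the same sample count")
    mean_samples = np.mean([t.samples for t in transects], axis=0)
    t0 = transects[0]
    merged = Transect(
        start=t0.start,
        end=t0.end,
        samples=mean_samples,
        step=t0.step,
        positions=t0.positions,
        orientation=t0.orientation,
    )
    prof = resample_profile(merged)
    prof.source["n_lines"] = len(lines)
    return prof


def gradient_direction(
    profile,
    positions=None,
    rank_threshold: float = _RANK_CORR_THRESHOLD,
) -> GradientResult:
    """Least-squares slope of value against u, Spearman rank correlation,
    and a direction label.

    ``reversed`` iff slope < 0 and rank_corr <= -threshold; ``increasing``
    iff slope > 0 and rank_corr >= threshold; ``flat`` otherwise (including
    constant profiles, whose rank correlation is taken as 0).
    """
    if isinstance(profile, DensityProfile):
        values, u = profile.values, profile.positions
    else:
        values = np.asarray(profile, dtype=float).ravel()
        u = (
            np.linspace(0.0, 1.0, values.size)
            if positions is None
            else np.asarray(positions, dtype=float).ravel()
        )
    if values.size < 2:
        raise ValueError("need at least 2 points")
    du = u - u.mean()
    slope = float(np.dot(du, values - values.mean()) / np.dot(du, du))
    if np.ptp(values) == 0:
        rank_corr = 0.0
    else:
        rho = _sps.spearmanr(u, values).statistic
        rank_corr = 0.0 if np.isnan(rho) else float(rho)
    if slope < 0 and rank_corr <= -rank_threshold:
        label = "reversed"
    elif slope > 0 and rank_corr >= rank_threshold:
        label = "increasing"
    else:
        label = "flat"
    return GradientResult(slope=slope, rank_corr=rank_corr, label=label)


def compare_profiles(
    normal: DensityProfile,
    lesion: DensityProfile,
    mid_window: tuple[int, int] = MID_WINDOW,
) -> ProfileComparison:
    """Pointwise fractional deficit of the lesion profile relative to the
    normal profile at matched positions, with mid-window and gradient
    summaries."""
    if not np.allclose(normal.positions, lesion.positions):
        raise ValueError("profiles must share the same positions")
    if np.any(normal.values <= 0):
        raise ValueError("non-positive normal value: deficit undefined")
    lo, hi = mid_window
    if not (1 <= lo <= hi <= N_PROFILE_POINTS):
        raise ValueError("mid window must lie within the 99 points")
    deficit = (normal.values - lesion.values) / normal.values
    window = deficit[lo - 1 : hi]
    return ProfileComparison(
        deficit_curve=deficit,
        max_deficit=float(deficit.max()),
        mid_deficit=float(window.mean()),
        gradient_normal=gradient_direction(normal),
        gradient_lesion=gradient_direction(lesion),
        positions=normal.positions.copy(),
        normal_values=normal.values.copy(),
        lesion_values=lesion.values.copy(),
        mid_window=mid_window,
    )


def comparison_to_frame(cmp: ProfileComparison) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "point": np.arange(1, N_PROFILE_POINTS + 1),
            "u": cmp.positions,
            "normal_GL": cmp.normal_values,
            "lesion_GL": cmp.lesion_values,
            "deficit": cmp.deficit_curve,
        }
    )


def write_comparison_csv(cmp: ProfileComparison, path: str | Path) -> Path:
    path = Path(path)
    comparison_to_frame(cmp).to_csv(path, index=False)
    return path


def plot_comparison(cmp: ProfileComparison, path: str | Path) -> Path:
    """Two-line profile figure: DEJ on the left, surface on the right."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    pts = np.arange(1, N_PROFILE_POINTS + 1)
    ax.plot(pts, cmp.normal_values, color="tab:blue", label="normal enamel")
    ax.plot(pts, cmp.lesion_values, color="tab:red", label="discoloured enamel")
    ax.set_xlabel("point (1 = DEJ, 99 = surface)")
    ax.set_ylabel("grey level (mineral density proxy)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
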