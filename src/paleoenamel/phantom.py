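"""Synthetic enamel phantoms with known ground truth.

A phantom is a flat enamel slab: the first array axis (``z``) is the
DEJ→surface depth axis with normalised depth ``u = z / (nz - 1)`` (``u = 0``
at the DEJ, ``u = 1`` at the outer surface).  The second axis (``y``) is the
lateral axis splitting the slab into a normal half and a lesion half; the
third axis (``x``) runs along the "coronal height" direction so repeated
measurement rounds use different x positions.

Noiseless normal enamel increases linearly from ``dej_grey`` at the DEJ to
``surface_grey`` at the surface.  Lesion models per class:

* ``sound`` — no lesion; both halves identical.
* ``hypomineralised`` — the lesion profile is the mirrored normal profile
  scaled so that the fractional deficit at ``u = 0.5`` equals
  ``deficit_mid``: linear, strictly decreasing from DEJ to surface.
* ``taphonomic_stain`` — the discoloured area is marked in the truth record
  and elemental multipliers are raised, but grey levels are untouched.
* ``hypomineralised_with_uptake`` — hypomineralised density model plus
  elemental contamination.
* ``acid_dissolution`` — constant fractional deficit restricted to the outer
  shell ``u > 1 - dissolution_depth_fraction``.

All randomness flows through explicit seeds; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .npstats import RatingTable
from .volume_core import GreyLevelVolume

__all__ = [
    "LESION_CLASSES",
    "XRF_ELEMENTS",
    "PhantomSpec",
    "PhantomTruth",
    "RaterModel",
    "generate_phantom",
    "simulate_xrf",
    "simulate_ratings",
    "systematic_disagreement_panel",
    "normal_profile_value",
    "lesion_profile_value",
    "region_slices",
    "line_endpoints",
]

LESION_CLASSES = (
    "sound",
    "hypomineralised",
    "taphonomic_stain",
    "hypomineralised_with_uptake",
    "acid_dissolution",
)
XRF_ELEMENTS = ("Mn", "Fe", "Cu", "Pb")

#: minimum slab thickness: five measurement cubes of 49 µm edge
CUBE_EDGE_UM = 49.0
MIN_ENAMEL_THICKNESS_UM = 5 * CUBE_EDGE_UM

_DEFAULT_MULTIPLIERS = {
    "sound": {},
    "hypomineralised": {},
    "acid_dissolution": {},
    "taphonomic_stain": {"Mn": 10.0},
    "hypomineralised_with_uptake": {"Fe": 10.0},
}

#: default baselines on the relative-concentration scale of normal enamel
DEFAULT_XRF_BASELINE = {"Mn": 0.03, "Fe": 0.03, "Cu": 0.01, "Pb": 0.04}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic enamel slab.

    ``shape`` may be omitted: the depth extent is then derived from
    ``enamel_thickness`` (``nz = round(thickness / voxel) + 1`` so that the
    DEJ and surface sit exactly on voxel centres) with a 40 x 40 lateral
    grid.  Grey levels default to the 3e4 range so that mineral-density
    differences land in the 1e3–1e4 range of real 16-bit reconstructions.
    """

    shape: tuple[int, int, int] | None = None
    voxel_size: float = 7.0
    enamel_thickness: float = 686.0
    dej_grey: float = 30000.0
    surface_grey: float = 31500.0
    lesion_class: str = "sound"
    deficit_mid: float = 0.07
    dissolution_depth_fraction: float = 0.3
    noise_sd: float = 0.0
    lesion_footprint: float = 140.0  # lateral (y) extent of the lesion, µm
    seed: int = 0
    element_multipliers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ValueError(
                f"unknown lesion_class {self.lesion_class!r}; expected one of {LESION_CLASSES}"
            )
        if not (0.0 <= self.deficit_mid < 0.5):
            raise ValueError("deficit_mid must lie in [0, 0.5)")
        if not (0.0 < self.dissolution_depth_fraction < 1.0):
            raise ValueError("dissolution_depth_fraction must lie in (0, 1)")
        if self.surface_grey <= self.dej_grey:
            raise ValueError("surface_grey must exceed dej_grey (normal gradient rises DEJ→surface)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.shape is not None:
            self.shape = tuple(int(s) for s in self.shape)
            if len(self.shape) != 3 or any(s < 2 for s in self.shape):
                raise ValueError("shape must be three axis lengths >= 2")
            # depth extent is authoritative when an explicit shape is given
            self.enamel_thickness = (self.shape[0] - 1) * self.voxel_size
        if self.element_multipliers is not None:
            unknown = set(self.element_multipliers) - set(XRF_ELEMENTS)
            if unknown:
                raise ValueError(
                    f"unknown element(s) {sorted(unknown)}; supported: {list(XRF_ELEMENTS)}"
                )

    def resolved_shape(self) -> tuple[int, int, int]:
        if self.shape is not None:
            return self.shape
        nz = int(round(self.enamel_thickness / self.voxel_size)) + 1
        return (nz, 40, 40)

    def resolved_multipliers(self) -> dict[str, float]:
        mult = {el: 1.0 for el in XRF_ELEMENTS}
        mult.update(_DEFAULT_MULTIPLIERS[self.lesion_class])
        if self.element_multipliers is not None:
            mult.update(self.element_multipliers)
        if self.lesion_class in ("sound", "hypomineralised") and any(
            v != 1.0 for v in mult.values()
        ):
            raise ValueError(
                f"class {self.lesion_class!r} must have all element multipliers equal to 1"
            )
        return mult


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    lesion_mask: np.ndarray  # bool voxels of the discoloured area
    deficit_field: np.ndarray  # per-voxel fractional density deficit
    class_label: str
    element_multipliers: dict[str, float]
    spec: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# Noiseless profiles


def normal_profile_value(spec: PhantomSpec, u):
    """Noiseless normal-enamel grey level at normalised depth u (DEJ=0)."""
    u = np.asarray(u, dtype=float)
    return spec.dej_grey + (spec.surface_grey - spec.dej_grey) * u


def lesion_profile_value(spec: PhantomSpec, u):
    """Noiseless lesion grey level at normalised depth u for the spec class."""
    u = np.asarray(u, dtype=float)
    normal = normal_profile_value(spec, u)
    return normal * (1.0 - _deficit_at(spec, u))


def _deficit_at(spec: PhantomSpec, u: np.ndarray) -> np.ndarray:
    """Fractional deficit d(u) of the lesion model; 0 outside density lesions."""
    u = np.asarray(u, dtype=float)
    cls = spec.lesion_class
    if cls in ("hypomineralised", "hypomineralised_with_uptake"):
        # mirrored-and-scaled normal profile: lesion(u) = (1-dm) * normal(1-u),
        # linear and strictly decreasing, deficit exactly dm at u = 0.5
        normal = normal_profile_value(spec, u)
        mirrored = normal_profile_value(spec, 1.0 - u)
        return 1.0 - (1.0 - spec.deficit_mid) * mirrored / normal
    if cls == "acid_dissolution":
        return np.where(u > 1.0 - spec.dissolution_depth_fraction, spec.deficit_mid, 0.0)
    return np.zeros_like(u)


# ---------------------------------------------------------------------------
# Geometry helpers


def region_slices(spec: PhantomSpec) -> tuple[slice, slice]:
    """(normal, lesion) lateral y-slices: mirror images about the slab midline."""
    _, ny, _ = spec.resolved_shape()
    w = int(round(spec.lesion_footprint / spec.voxel_size))
    w = max(2, min(w, ny // 2))
    c_norm, c_les = ny // 4, 3 * ny // 4
    half = w // 2
    return (
        slice(max(0, c_norm - half), min(ny // 2, c_norm - half + w)),
        slice(max(ny // 2, c_les - half), min(ny, c_les - half + w)),
    )


def line_endpoints(
    spec: PhantomSpec, region: str, x_index: int, y_index: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(surface_pt, dej_pt) in µm of a depth transect through a region."""
    nz, ny, nx = spec.resolved_shape()
    if region not in ("normal", "lesion"):
        raise ValueError("region must be 'normal' or 'lesion'")
    if y_index is None:
        y_index = ny // 4 if region == "normal" else 3 * ny // 4
    if not (0 <= x_index < nx and 0 <= y_index < ny):
        raise ValueError("transect position outside the phantom")
    d = spec.voxel_size
    surface = np.array([(nz - 1) * d, y_index * d, x_index * d])
    dej = np.array([0.0, y_index * d, x_index * d])
    return surface, dej


# ---------------------------------------------------------------------------
# Generators


def generate_phantom(spec: PhantomSpec) -> tuple[GreyLevelVolume, PhantomTruth]:
    """Generate a phantom volume and its ground-truth record.

    Deterministic for a given spec (seed included).  Raises when the slab is
    too thin to host the five-cube densitometry layout.
    """
    if spec.enamel_thickness < MIN_ENAMEL_THICKNESS_UM:
        raise ValueError(
            "degenerate geometry: enamel_thickness "
            f"{spec.enamel_thickness:g} µm is below the minimum "
            f"{MIN_ENAMEL_THICKNESS_UM:g} µm (five {CUBE_EDGE_UM:g} µm cube edges)"
        )
    nz, ny, nx = spec.resolved_shape()
    u = np.arange(nz, dtype=float) / (nz - 1)
    normal_col = normal_profile_value(spec, u)  # (nz,)
    values = np.broadcast_to(normal_col[:, None, None], (nz, ny, nx)).astype(float).copy()

    deficit_field = np.zeros((nz, ny, nx))
    lesion_mask = np.zeros((nz, ny, nx), dtype=bool)
    if spec.lesion_class != "sound":
        _, les = region_slices(spec)
        lesion_mask[:, les, :] = True
        d_col = _deficit_at(spec, u)
        deficit_field[:, les, :] = d_col[:, None, None]
        values[:, les, :] = (normal_col * (1.0 - d_col))[:, None, None]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)

    vol = GreyLevelVolume(values=values, voxel_size=np.full(3, spec.voxel_size))
    truth = PhantomTruth(
        lesion_mask=lesion_mask,
        deficit_field=deficit_field,
        class_label=spec.lesion_class,
        element_multipliers=spec.resolved_multipliers(),
        spec=spec,
    )
    return vol, truth


def simulate_xrf(
    truth: PhantomTruth,
    baseline: dict[str, float] | None = None,
    cv: float = 0.25,
    n_repeats: int = 2,
    seed: int = 0,
    tooth_id: str = "phantom",
) -> pd.DataFrame:
    """Simulate paired XRF spot measurements on stained (DC) and normal (NO)
    enamel.

    Concentrations are lognormal with the requested coefficient of variation;
    the stained-spot mean is ``baseline x element_multiplier`` and the
    normal-spot mean is ``baseline``.  Returns a tidy table with columns
    ``tooth, element, condition, repeat, value``.
    """
    if baseline is None:
        baseline = dict(DEFAULT_XRF_BASELINE)
    unknown = set(baseline) - set(XRF_ELEMENTS)
    if unknown:
        raise ValueError(f"unknown element(s) {sorted(unknown)}; supported: {list(XRF_ELEMENTS)}")
    missing = set(XRF_ELEMENTS) - set(baseline)
    if missing:
        raise ValueError(f"baseline missing element(s) {sorted(missing)}")
    if any(baseline[el] <= 0 for el in XRF_ELEMENTS):
        raise ValueError("baseline concentrations must be positive")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 (two measures per area)")
    if cv < 0:
        raise ValueError("cv must be non-negative")

    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    rows = []
    for el in XRF_ELEMENTS:
        for condition in ("DC", "NO"):
            mult = truth.element_multipliers.get(el, 1.0) if condition == "DC" else 1.0
            mean = baseline[el] * mult
            if cv == 0:
                vals = np.full(n_repeats, mean)
            else:
                mu = np.log(mean) - sigma2 / 2.0
                vals = rng.lognormal(mu, sigma, size=n_repeats)
            for r, v in enumerate(vals, start=1):
                rows.append((tooth_id, el, condition, r, float(v)))
    return pd.DataFrame(rows, columns=["tooth", "element", "condition", "repeat", "value"])


@dataclass
class RaterModel:
    """Panel of raters drawing categorical responses from per-class confusion."""

    confusion: dict[str, tuple[float, ...]] = field(default_factory=dict)
    n_raters: int = 19
    categories: tuple[str, ...] = ("yes", "no", "unsure")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 2:
            raise ValueError("need at least 2 raters")
        self.categories = tuple(self.categories)
        for cls, probs in self.confusion.items():
            probs = tuple(float(p) for p in probs)
            if len(probs) != len(self.categories):
                raise ValueError(f"confusion vector for {cls!r} has wrong length")
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"confusion vector for {cls!r} must be a probability vector")
            self.confusion[cls] = probs


def simulate_ratings(true_classes, model: RaterModel) -> RatingTable:
    """Draw per-item rating counts: each rater rates independently from the
    confusion row of the item's true class."""
    true_classes = list(true_classes)
    if len(true_classes) < 2:
        raise ValueError("need at least 2 items to rate")
    rng = np.random.default_rng(model.seed)
    counts = np.zeros((len(true_classes), len(model.categories)), dtype=int)
    for i, cls in enumerate(true_classes):
        if cls not in model.confusion:
            raise ValueError(f"no confusion vector for class {cls!r}")
        counts[i] = rng.multinomial(model.n_raters, model.confusion[cls])
    return RatingTable(
        counts=counts,
        categories=model.categories,
        items=tuple(f"item{i + 1}" for i in range(len(true_classes))),
    )


def systematic_disagreement_panel(
    n_items: int, n_raters: int = 19, n_categories: int = 3
) -> RatingTable:
    """Deterministic worse-than-chance panel: each item's ratings are spread
    as evenly as possible over the categories, with the remainder rotated
    across items so the pooled marginals stay balanced.  Yields kappa < 0."""
    if n_items < 2:
        raise ValueError("need at least 2 items")
    base, rem = divmod(n_raters, n_categories)
    counts = np.full((n_items, n_categories), base, dtype=int)
    for i in range(n_items):
        for j in range(rem):
            counts[i, (i + j) % n_categories] += 1
    return RatingTable(counts=counts, categories=tuple(f"c{j}" for j in range(n_categories)))
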