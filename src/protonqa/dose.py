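"""Simplified analytical pencil-beam dose recomputation.

A deliberately simple, fully-disclosed stand-in for a commissioned clinical
dose engine, sufficient to quantify *relative* dosimetric impact of spot
position/MU changes: each spot deposits

    dose(v) = MU_s * scale * DD_E(z_v) * G(x_v - x_s, y_v - y_s; sigma_E)

on a uniform 3-D grid (default 2-mm isotropic), with the beam axis fixed
along +z (fixed gantry angle), DD_E a normalised analytic Bragg depth-dose
curve for the layer energy, and G a 2-D isotropic Gaussian *density*
(mm^-2), truncated beyond 5 sigma.  Dose is exactly linear in MU.

The Bragg curve uses a Bragg-Kleeman range (R ~ alpha * E^p in water) with a
plateau-plus-peak shape and a sharp distal falloff; absolute magnitudes are
engine-dependent by construction and carry no clinical calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compare import ProjectionFactors
from .errors import ConfigurationError, SynchronizationError, ValidationError
from .log_io import DeliverySession
from .plan_io import EnergyLayer, IonPlan, PlannedSpot

# Bragg-Kleeman range-energy parameters for water (R in mm, E in MeV)
_BK_ALPHA = 0.022
_BK_P = 1.77


def range_in_water(energy: float) -> float:
    """Proton range in water (mm), Bragg-Kleeman R = alpha * E^p."""
    return _BK_ALPHA * energy**_BK_P


def _bragg_curve(energy: float, dz: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated normalised depth-dose: plateau, Gaussian-broadened peak just
    proximal of the range, sigmoid distal falloff.  Peak normalised to 1."""
    r = range_in_water(energy)
    w = 0.025 * r  # peak width grows with range (range straggling)
    z = np.arange(0.0, 1.15 * r + dz, dz)
    peak_z = r - 0.7 * w
    shape = 0.35 + 0.65 * np.exp(-0.5 * ((z - peak_z) / w) ** 2)
    falloff = 1.0 / (1.0 + np.exp((z - r) / (0.35 * w)))
    dd = shape * falloff
    return z, dd / dd.max()


def lateral_sigma(energy: float) -> float:
    """In-water lateral spot sigma at isocenter depth (mm); shrinks with energy."""
    return 2.5 + 450.0 / energy


@dataclass
class BeamModel:
    """Per-energy depth-dose tables, lateral sigmas and a global MU-to-dose
    scale (Gy * mm^2 per MU)."""

    energies: np.ndarray
    ranges: np.ndarray  # mm, increasing with energy
    depth_dose: dict[float, tuple[np.ndarray, np.ndarray]]
    sigmas: dict[float, float]
    mu_to_dose: float = 1.0

    @classmethod
    def analytic(cls, energies, mu_to_dose: float = 1.0) -> "BeamModel":
        energies = np.sort(np.unique(np.asarray(energies, dtype=float)))
        ranges = np.array([range_in_water(e) for e in energies])
        if not np.all(np.diff(ranges) > 0) and len(ranges) > 1:
            raise ValidationError("range must increase with energy")
        return cls(
            energies=energies,
            ranges=ranges,
            depth_dose={float(e): _bragg_curve(e) for e in energies},
            sigmas={float(e): lateral_sigma(e) for e in energies},
            mu_to_dose=mu_to_dose,
        )

    def lookup(self, energy: float):
        key = float(energy)
        if key not in self.depth_dose:
            raise ConfigurationError(f"energy {energy} MeV not in beam model table")
        return self.depth_dose[key], self.sigmas[key]


@dataclass
class GridSpec:
    """Uniform 3-D dose grid: origin (mm), isotropic spacing (mm), shape."""

    origin: tuple[float, float, float]
    spacing: float = 2.0
    shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self):
        if not self.spacing > 0:
            raise ValidationError("grid spacing must be > 0")

    def axes(self):
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)
        )

    @classmethod
    def covering(cls, plan: IonPlan, spacing: float = 2.0, margin: float = 30.0) -> "GridSpec":
        arrays = plan.spot_arrays()
        x0, x1 = arrays["x"].min() - margin, arrays["x"].max() + margin
        y0, y1 = arrays["y"].min() - margin, arrays["y"].max() + margin
        zmax = range_in_water(float(plan.energies.max())) * 1.15
        shape = (
            int(np.ceil((x1 - x0) / spacing)) + 1,
            int(np.ceil((y1 - y0) / spacing)) + 1,
            int(np.ceil(zmax / spacing)) + 1,
        )
        return cls(origin=(float(x0), float(y0), 0.0), spacing=spacing, shape=shape)


@dataclass
class DoseGrid:
    spec: GridSpec
    values: np.ndarray  # Gy, shape = spec.shape

    def congruent(self, other: "DoseGrid") -> bool:
        return (
            self.spec.shape == other.spec.shape
            and self.spec.spacing == other.spec.spacing
            and np.allclose(self.spec.origin, other.spec.origin)
        )


@dataclass
class DoseComparison:
    """Summary statistics of two congruent dose grids and their difference."""

    stats_a: dict
    stats_b: dict
    mean_dose_diff: float  # |mean(a) - mean(b)|
    max_abs_voxel_diff: float
    sd_voxel_diff: float
    mean_abs_voxel_diff: float


def _grid_stats(values: np.ndarray) -> dict:
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=0)),
        "min": float(values.min()),
        "max": float(values.max()),
    }


def spots_to_plan(
    source,
    template: IonPlan,
    factors: ProjectionFactors = ProjectionFactors(),
    plan_id_suffix: str = "-DELIVERED",
) -> IonPlan:
    """Build a plan with the template's structure but substituted spot
    positions and MUs.

    ``source`` is either a :class:`DeliverySession` (SPM coordinates are
    projected to isocenter; delivered MU substituted) or a tuple
    ``(positions, mus)`` with an (n, 2) isocenter-plane array and an MU array
    (``mus=None`` keeps planned MUs) in the template's delivery order —
    e.g. the per-axis model predictions.
    """
    arrays = template.spot_arrays()
    n = len(arrays["x"])
    if isinstance(source, DeliverySession):
        if source.n_spots != n:
            raise SynchronizationError(
                f"session has {source.n_spots} spots, template has {n}"
            )
        order = np.argsort(source.layer_index, kind="stable")
        xs = source.x_spm[order] * factors.f_x
        ys = source.y_spm[order] * factors.f_y
        mus = source.mu[order]
    else:
        positions, mus = source
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n, 2):
            raise SynchronizationError(
                f"positions shape {positions.shape} != ({n}, 2)"
            )
        xs, ys = positions[:, 0], positions[:, 1]
        mus = arrays["mu"] if mus is None else np.asarray(mus, dtype=float)

    layers, k = [], 0
    for layer in template.layers:
        spots = []
        for si in range(layer.n_spots):
            spots.append(
                PlannedSpot(
                    layer.layer_index, si,
                    float(xs[k]), float(ys[k]), float(max(mus[k], 1e-12)),
                )
            )
            k += 1
        layers.append(EnergyLayer(layer.layer_index, layer.energy, spots))
    return IonPlan(
        plan_id=template.plan_id + plan_id_suffix,
        gantry_angle=template.gantry_angle,
        layers=layers,
    )


def compute_dose(
    plan: IonPlan, model: BeamModel, grid: GridSpec, truncate_sigma: float = 5.0
) -> DoseGrid:
    """Superpose all spots' pencil-beam kernels on the grid.

    Deterministic; Gaussians are evaluated only within ``truncate_sigma``
    standard deviations of each spot (mass beyond 5 sigma < 1e-5).
    """
    xs_axis, ys_axis, zs_axis = grid.axes()
    values = np.zeros(grid.shape, dtype=float)
    for layer in plan.layers:
        (z_tab, dd_tab), sigma = model.lookup(layer.energy)
        dd = np.interp(zs_axis, z_tab, dd_tab, left=0.0, right=0.0)
        norm = 1.0 / (2.0 * np.pi * sigma**2)
        half = truncate_sigma * sigma
        for spot in layer.spots:
            i0, i1 = np.searchsorted(xs_axis, [spot.x_iso - half, spot.x_iso + half])
            j0, j1 = np.searchsorted(ys_axis, [spot.y_iso - half, spot.y_iso + half])
            if i0 == i1 or j0 == j1:
                continue
            gx = np.exp(-0.5 * ((xs_axis[i0:i1] - spot.x_iso) / sigma) ** 2)
            gy = np.exp(-0.5 * ((ys_axis[j0:j1] - spot.y_iso) / sigma) ** 2)
            amp = spot.meterset * model.mu_to_dose * norm
            values[i0:i1, j0:j1, :] += amp * (
                gx[:, None, None] * gy[None, :, None] * dd[None, None, :]
            )
    return DoseGrid(spec=grid, values=values)


def compare_dose(a: DoseGrid, b: DoseGrid) -> DoseComparison:
    """Voxel-wise comparison of two congruent dose grids."""
    if not a.congruent(b):
        raise ValidationError("dose grids are not congruent (origin/spacing/shape)")
    diff = b.values - a.values
    return DoseComparison(
        stats_a=_grid_stats(a.values),
        stats_b=_grid_stats(b.values),
        mean_dose_diff=float(abs(a.values.mean() - b.values.mean())),
        max_abs_voxel_diff=float(np.abs(diff).max()),
        sd_voxel_diff=float(diff.std(ddof=0)),
        mean_abs_voxel_diff=float(np.abs(diff).mean()),
    )
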