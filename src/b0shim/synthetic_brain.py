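"""Seeded synthetic subjects for shim simulation.

Each subject is an ellipsoidal brain mask on the acquisition grid
(2.4 x 2.4 x 2 mm voxels over a 214 x 250 x 120 mm field of view), an
off-resonance field composed of a smooth background polynomial plus the
external dipole fields of air cavities anchored at the frontal sinus and
both ear canals, and box ROIs over the prefrontal cortex and the medial
temporal lobe / temporal pole.  Air-tissue susceptibility interfaces at
those sites are what produce the strong, spatially concentrated,
high-spatial-order inhomogeneity that low-order spherical-harmonic shims
cannot correct; the sphere-in-uniform-field dipole is the simplest model
with the right geometry and falloff.

Axes: x left-right, y posterior-anterior, z inferior-superior (B0).
All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .fieldmap_io import BrainMask, FieldMap

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "CavitySpec",
    "GridSpec",
    "SubjectConfig",
    "Subject",
    "make_brain_mask",
    "cavity_dipole_field",
    "generate_subject",
    "generate_cohort",
    "save_subject",
]

GAMMA_BAR_HZ_PER_T = 42.577e6

#: Air-tissue volume susceptibility difference (SI), dimensionless x 1e-6.
DEFAULT_DELTA_CHI_PPM = 9.4

#: Scanner field strength, tesla.
DEFAULT_B0_TESLA = 3.0

# background polynomial term order: 1, x, y, z, x^2, y^2, z^2, xy, xz, yz
# with coordinates in cm; coefficients in Hz per cm^n.
_POLY_TERMS = 10


@dataclass(frozen=True)
class CavitySpec:
    """Spherical air cavity: center (mm), radius (mm), susceptibility step."""

    center: tuple[float, float, float]
    radius: float
    delta_chi_ppm: float = DEFAULT_DELTA_CHI_PPM

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.radius <= 0:
            raise ValueError("cavity radius must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: voxel spacing (mm) and field of view (mm), centered on 0."""

    spacing: tuple[float, float, float] = (2.4, 2.4, 2.0)
    fov_mm: tuple[float, float, float] = (214.0, 250.0, 120.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(f / s)) for f, s in zip(self.fov_mm, self.spacing)
        )

    @property
    def origin(self) -> tuple[float, float, float]:
        return tuple(
            -(n - 1) * s / 2.0 for n, s in zip(self.shape, self.spacing)
        )

    def coarsened(self, factor: int = 2) -> "GridSpec":
        """Same FOV at ``factor`` x coarser spacing."""
        return GridSpec(tuple(s * factor for s in self.spacing), self.fov_mm)


# Cavity anchors sit just outside the brain ellipsoid, like the real
# sinus and ear canals sit outside the BET brain mask: the nearest brain
# voxels are a few mm from the air surface, giving peak perturbations of
# a few hundred Hz at 3 T that decay over 2-3 cm.
_DEFAULT_CAVITIES = (
    CavitySpec((0.0, 78.0, -40.0), 14.0),   # frontal sinus
    CavitySpec((68.0, 0.0, -35.0), 11.0),   # left ear canal
    CavitySpec((-68.0, 0.0, -35.0), 11.0),  # right ear canal
)

# Quadratic part chosen nearly trace-free: fields from sources outside
# the head are harmonic, so a strongly non-harmonic background would be
# invisible to every shim method alike.
_DEFAULT_POLY = (0.0, 2.2, 1.5, 3.8, -1.35, 0.63, 0.8, 0.5, -0.6, 0.75)


@dataclass(frozen=True)
class SubjectConfig:
    """Everything needed to generate one synthetic subject."""

    seed: int = 0
    ellipsoid_semiaxes: tuple[float, float, float] = (65.0, 80.0, 55.0)
    cavities: tuple[CavitySpec, ...] = _DEFAULT_CAVITIES
    background_poly: tuple[float, ...] = _DEFAULT_POLY
    noise_sd_hz: float = 2.5
    grid: GridSpec = field(default_factory=GridSpec)
    b0_tesla: float = DEFAULT_B0_TESLA

    def __post_init__(self) -> None:
        object.__setattr__(self, "cavities", tuple(self.cavities))
        object.__setattr__(
            self, "background_poly", tuple(float(c) for c in self.background_poly)
        )
        if len(self.background_poly) != _POLY_TERMS:
            raise ValueError(f"background_poly needs {_POLY_TERMS} coefficients")
        if self.noise_sd_hz < 0:
            raise ValueError("noise SD must be nonnegative")
        if any(a <= 0 for a in self.ellipsoid_semiaxes):
            raise ValueError("ellipsoid semiaxes must be positive")


@dataclass(frozen=True)
class Subject:
    """Generated subject bundle."""

    fieldmap: FieldMap
    mask: BrainMask
    roi_pfc: BrainMask
    roi_mtl: BrainMask
    config: SubjectConfig


def _grid_coords(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    origin, spacing, shape = grid.origin, grid.spacing, grid.shape
    ax = [origin[d] + spacing[d] * np.arange(shape[d]) for d in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def make_brain_mask(config: SubjectConfig) -> BrainMask:
    """Ellipsoid brain minus the air-cavity spheres."""
    a, b, c = config.ellipsoid_semiaxes
    half_fov = [f / 2.0 for f in config.grid.fov_mm]
    if a > half_fov[0] or b > half_fov[1] or c > half_fov[2]:
        raise ValueError("brain ellipsoid does not fit inside the FOV")
    x, y, z = _grid_coords(config.grid)
    inside = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    for cav in config.cavities:
        cx, cy, cz = cav.center
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        inside &= r2 > cav.radius**2
    return BrainMask(inside, spacing=config.grid.spacing, origin=config.grid.origin)


def cavity_dipole_field(
    cavity: CavitySpec,
    grid: GridSpec,
    b0_tesla: float = DEFAULT_B0_TESLA,
) -> FieldMap:
    """External dipole field of a spherical susceptibility inclusion, Hz.

    Outside the sphere the frequency shift is
    f0 * (dchi/3) * (a/r)^3 * (3 cos^2 theta - 1), theta measured from
    the main-field (z) axis; inside the sphere the value is set to 0
    (those voxels are excluded by the mask anyway).
    """
    if b0_tesla <= 0:
        raise ValueError("field strength must be positive")
    f0 = GAMMA_BAR_HZ_PER_T * b0_tesla
    x, y, z = _grid_coords(grid)
    cx, cy, cz = cavity.center
    dx, dy, dz = x - cx, y - cy, z - cz
    r2 = dx**2 + dy**2 + dz**2
    with np.errstate(invalid="ignore", divide="ignore"):
        cos2 = dz**2 / r2
        amp = f0 * (cavity.delta_chi_ppm * 1e-6 / 3.0) * (
            cavity.radius**2 / r2
        ) ** 1.5
        f = amp * (3.0 * cos2 - 1.0)
    f = np.where(r2 > cavity.radius**2, f, 0.0)
    return FieldMap(f, spacing=grid.spacing, origin=grid.origin)


def _background_field(config: SubjectConfig) -> np.ndarray:
    x, y, z = (c / 10.0 for c in _grid_coords(config.grid))  # cm
    c = config.background_poly
    return (
        c[0]
        + c[1] * x + c[2] * y + c[3] * z
        + c[4] * x**2 + c[5] * y**2 + c[6] * z**2
        + c[7] * x * y + c[8] * x * z + c[9] * y * z
    )


def _box_mask(
    grid: GridSpec,
    lo: tuple[float, float, float],
    hi: tuple[float, float, float],
) -> np.ndarray:
    x, y, z = _grid_coords(grid)
    return (
        (x >= lo[0]) & (x <= hi[0])
        & (y >= lo[1]) & (y <= hi[1])
        & (z >= lo[2]) & (z <= hi[2])
    )


def _roi_masks(config: SubjectConfig, brain: np.ndarray):
    """PFC box ahead of the frontal cavity; MTL boxes around the ear cavities.

    Boxes are placed relative to the cavity anchors so the region
    analysis stresses the same areas the dipoles perturb.
    """
    grid = config.grid
    if not config.cavities:
        empty = np.zeros(grid.shape, dtype=bool)
        return empty, empty
    frontal = config.cavities[0].center
    pfc = _box_mask(
        grid,
        (frontal[0] - 38.0, frontal[1] - 40.0, frontal[2] - 12.0),
        (frontal[0] + 38.0, frontal[1] + 5.0, frontal[2] + 45.0),
    )
    mtl = np.zeros(grid.shape, dtype=bool)
    for cav in config.cavities[1:]:
        cx, cy, cz = cav.center
        inward = -1.0 if cx > 0 else 1.0
        mtl |= _box_mask(
            grid,
            (min(cx, cx + inward * 42.0), cy - 32.0, cz - 12.0),
            (max(cx, cx + inward * 42.0), cy + 32.0, cz + 32.0),
        )
    return pfc & brain, mtl & brain


def generate_subject(config: SubjectConfig) -> Subject:
    """Deterministic subject: mask, dipole+polynomial+noise field, ROIs."""
    mask = make_brain_mask(config)
    fld = _background_field(config)
    for cav in config.cavities:
        fld = fld + cavity_dipole_field(cav, config.grid, config.b0_tesla).data
    if config.noise_sd_hz > 0:
        rng = np.random.default_rng(config.seed)
        fld = fld + rng.normal(0.0, config.noise_sd_hz, size=config.grid.shape)
    fieldmap = FieldMap(
        fld,
        spacing=config.grid.spacing,
        origin=config.grid.origin,
        subject_id=f"synthetic-{config.seed:04d}",
    )
    pfc, mtl = _roi_masks(config, mask.data)
    spacing, origin = config.grid.spacing, config.grid.origin
    return Subject(
        fieldmap,
        mask,
        BrainMask(pfc, spacing=spacing, origin=origin),
        BrainMask(mtl, spacing=spacing, origin=origin),
        config,
    )


def generate_cohort(
    n: int,
    base: SubjectConfig | None = None,
    master_seed: int = 42,
    center_jitter_mm: float = 3.0,
    radius_jitter_mm: float = 0.8,
    poly_jitter_rel: float = 0.25,
) -> list[Subject]:
    """n subjects with seeded jitter of cavity geometry and background.

    Cavity centers receive isotropic Gaussian jitter, radii a truncated
    Gaussian jitter (floored at 40% of nominal), and every background
    polynomial coefficient an independent relative Gaussian jitter.
    """
    if n < 2:
        raise ValueError("cohort statistics need at least 2 subjects")
    base = base or SubjectConfig()
    seeds = np.random.SeedSequence(master_seed).spawn(n)
    subjects = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        cavities = []
        for cav in base.cavities:
            center = tuple(
                np.asarray(cav.center) + rng.normal(0.0, center_jitter_mm, 3)
            )
            radius = max(
                0.4 * cav.radius, cav.radius + rng.normal(0.0, radius_jitter_mm)
            )
            cavities.append(CavitySpec(center, radius, cav.delta_chi_ppm))
        poly = tuple(
            c * (1.0 + rng.normal(0.0, poly_jitter_rel))
            for c in base.background_poly
        )
        noise_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(
            base,
            seed=noise_seed,
            cavities=tuple(cavities),
            background_poly=poly,
        )
        subjects.append(generate_subject(cfg))
    return subjects


def save_subject(subject: Subject, outdir) -> None:
    """Write the subject volumes as NIfTI plus a JSON config sidecar."""
    from pathlib import Path

    from .fieldmap_io import save_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(subject.fieldmap, outdir / "field_hz.nii.gz")
    save_volume(subject.mask, outdir / "brain_mask.nii.gz")
    save_volume(subject.roi_pfc, outdir / "roi_pfc.nii.gz")
    save_volume(subject.roi_mtl, outdir / "roi_mtl.nii.gz")
    cfg = subject.config
    doc = {
        "seed": cfg.seed,
        "ellipsoid_semiaxes": list(cfg.ellipsoid_semiaxes),
        "cavities": [
            {
                "center_mm": list(c.center),
                "radius_mm": c.radius,
                "delta_chi_ppm": c.delta_chi_ppm,
            }
            for c in cfg.cavities
        ],
        "background_poly": list(cfg.background_poly),
        "noise_sd_hz": cfg.noise_sd_hz,
        "grid": {"spacing": list(cfg.grid.spacing), "fov_mm": list(cfg.grid.fov_mm)},
        "b0_tesla": cfg.b0_tesla,
    }
    with open(outdir / "subject.json", "w") as fh:
        json.dump(doc, fh, indent=1)
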