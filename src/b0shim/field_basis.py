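"""Per-channel shim basis fields.

Two families of basis fields are supported:

* Biot-Savart fields of circular current loops, computed numerically from
  a polygonal discretization of the wire (with a closed-form
  elliptic-integral implementation serving as an independent oracle), and
* real solid spherical harmonics r^n P_n^m(cos theta) {cos, sin}(m phi)
  up to degree 5, the field shapes produced by concentric SH shim coils.

Only the z-component of the magnetic field perturbs the resonance
frequency (standard MR approximation); fields are returned in Hz per
ampere (loops) or Hz per unit coefficient (harmonics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk, lpmv

from .coil_layouts import CoilLayout, LoopSpec
from .fieldmap_io import BrainMask, FieldMap

__all__ = [
    "GAMMA_BAR_HZ_PER_T",
    "MU0",
    "BasisMatrix",
    "SHBasisSpec",
    "loop_bz_numeric",
    "loop_bz_analytic",
    "sh_basis",
    "sh_term_count",
    "assemble_coil_basis",
]

#: Proton gyromagnetic ratio / 2 pi, Hz per tesla.
GAMMA_BAR_HZ_PER_T = 42.577e6

#: Vacuum permeability, T m / A.
MU0 = 4.0e-7 * np.pi

#: Points closer than this to the wire (mm) raise a singularity error.
_WIRE_CLEARANCE_MM = 0.1


@dataclass(frozen=True)
class BasisMatrix:
    """Shim basis sampled at masked voxels.

    ``values`` is (n_masked_voxels, n_channels) in Hz/A (coil basis) or
    Hz per unit coefficient (SH basis); ``voxel_index`` maps each row to
    its (i, j, k) voxel index.
    """

    values: np.ndarray
    channel_labels: tuple[str, ...]
    voxel_index: np.ndarray  # (n_masked, 3) int
    units: str = "Hz/A"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        object.__setattr__(
            self, "voxel_index", np.asarray(self.voxel_index, dtype=int)
        )
        if values.ndim != 2 or values.shape[1] < 1:
            raise ValueError("basis must be 2-D with at least one channel")
        if not np.all(np.isfinite(values)):
            raise ValueError("basis entries must be finite")
        if len(self.channel_labels) != values.shape[1]:
            raise ValueError("one label per channel required")
        if self.voxel_index.shape != (values.shape[0], 3):
            raise ValueError("voxel_index must be (n_masked, 3)")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SHBasisSpec:
    """Real solid-harmonic basis specification.

    max_degree 0..5; degree n contributes 2n+1 terms, so the full basis
    has (max_degree + 1)^2 columns.  The expansion origin defaults to the
    brain-mask centroid; each column is scaled to unit RMS over the mask
    (pure conditioning — the fitted field is invariant to column scale
    when coefficients are unbounded).
    """

    max_degree: int = 2
    center: tuple[float, float, float] | None = None
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_degree <= 5:
            raise ValueError("max_degree must be in 0..5")


def sh_term_count(max_degree: int) -> int:
    """Number of solid-harmonic terms for degrees 0..max_degree."""
    return (max_degree + 1) ** 2


def _loop_frame(loop: LoopSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (u, v, n) with n the loop normal."""
    n = np.asarray(loop.normal, dtype=float)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def _check_wire_clearance(loop: LoopSpec, points: np.ndarray) -> None:
    u, v, n = _loop_frame(loop)
    rel = points - np.asarray(loop.center)
    z = rel @ n
    rho = np.sqrt(np.maximum((rel @ u) ** 2 + (rel @ v) ** 2, 0.0))
    d_wire = np.sqrt((rho - loop.radius) ** 2 + z**2)
    if np.any(d_wire <= _WIRE_CLEARANCE_MM):
        raise ValueError("evaluation point lies on or next to the loop wire")


def loop_bz_numeric(
    loop: LoopSpec, points: np.ndarray, n_segments: int = 256
) -> np.ndarray:
    """Bz of a polygonal loop discretization, in Hz per ampere.

    Each of the ``n_segments`` straight segments contributes its exact
    finite-wire Biot-Savart field.  The polygon circumradius is scaled so
    the polygon area equals the circle area, which cancels the leading
    O(1/n^2) dipole-moment bias of a plainly inscribed polygon; the
    remaining discretization error decays like 1/n_segments^4 away from
    the wire.  Multi-turn loops scale linearly with ``turns``.
    """
    if n_segments < 8:
        raise ValueError("n_segments must be at least 8")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _check_wire_clearance(loop, points)

    u, v, n = _loop_frame(loop)
    ang = 2.0 * np.pi * np.arange(n_segments + 1) / n_segments
    # area-matched circumradius: (1/2) n r^2 sin(2 pi/n) = pi a^2
    theta = 2.0 * np.pi / n_segments
    r_eff = loop.radius * np.sqrt(theta / np.sin(theta))
    # vertices in mm -> meters for SI Biot-Savart
    verts = (
        np.asarray(loop.center)
        + r_eff * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
    ) * 1e-3
    pts_m = points * 1e-3

    bz = np.zeros(len(points))
    a = verts[:-1]  # segment starts, (S, 3)
    b = verts[1:]   # segment ends
    # exact field of a finite straight segment, vectorized over segments
    for k in range(n_segments):
        r1 = pts_m - a[k]
        r2 = pts_m - b[k]
        n1 = np.linalg.norm(r1, axis=1)
        n2 = np.linalg.norm(r2, axis=1)
        cross = np.cross(r1, r2)
        denom = n1 * n2 * (n1 * n2 + np.einsum("ij,ij->i", r1, r2))
        bz += (n1 + n2) / denom * cross[:, 2]
    bz *= MU0 / (4.0 * np.pi)
    return bz * loop.turns * GAMMA_BAR_HZ_PER_T


def loop_bz_analytic(loop: LoopSpec, points: np.ndarray) -> np.ndarray:
    """Closed-form Bz of an ideal circular loop, in Hz per ampere.

    Uses the complete-elliptic-integral expression for the field of a
    circular filament; serves as the independent oracle for
    :func:`loop_bz_numeric`.  Note the returned component is along the
    laboratory z axis, so it combines the loop-frame axial and radial
    field components for tilted loops.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _check_wire_clearance(loop, points)

    u, v, n = _loop_frame(loop)
    rel = (points - np.asarray(loop.center)) * 1e-3
    a = loop.radius * 1e-3
    z = rel @ n
    xu = rel @ u
    xv = rel @ v
    rho = np.sqrt(xu**2 + xv**2)

    alpha2 = a**2 + rho**2 + z**2 - 2.0 * a * rho
    beta2 = a**2 + rho**2 + z**2 + 2.0 * a * rho
    m = 4.0 * a * rho / beta2
    K = ellipk(m)
    E = ellipe(m)
    pref = MU0 / (2.0 * np.pi * np.sqrt(beta2))

    # axial (along loop normal) component
    b_ax = pref * ((a**2 - rho**2 - z**2) / alpha2 * E + K)
    # radial component; vanishes on axis
    with np.errstate(invalid="ignore", divide="ignore"):
        b_rad = (
            pref
            * z
            / rho
            * ((a**2 + rho**2 + z**2) / alpha2 * E - K)
        )
    b_rad = np.where(rho > 1e-12, b_rad, 0.0)

    rho_hat_z = np.zeros(len(points))
    nz = rho > 1e-12
    # unit radial direction in lab coordinates, z-component only
    rho_hat = (xu[nz, None] * u + xv[nz, None] * v) / rho[nz, None]
    rho_hat_z[nz] = rho_hat[:, 2]

    bz = b_ax * n[2] + b_rad * rho_hat_z
    return bz * loop.turns * GAMMA_BAR_HZ_PER_T


def _real_solid_harmonic(
    degree: int, order: int, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """r^n P_n^m(cos theta) * cos(m phi) (order >= 0) or sin(|m| phi)."""
    r = np.sqrt(x**2 + y**2 + z**2)
    m = abs(order)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, z / r, 1.0)
    phi = np.arctan2(y, x)
    pnm = lpmv(m, degree, cos_t)
    rad = r**degree
    azim = np.cos(m * phi) if order >= 0 else np.sin(m * phi)
    out = rad * pnm * azim
    # r=0: only the (0,0) term is nonzero (=1); others vanish with r^n
    if degree == 0:
        return np.ones_like(out)
    return np.where(r > 0, out, 0.0)


def sh_basis(
    spec: SHBasisSpec, fieldmap: FieldMap, mask: BrainMask
) -> BasisMatrix:
    """Real solid-harmonic basis over the masked voxels.

    Columns are ordered by degree n = 0..max_degree and within each
    degree by order m = 0, 1c, 1s, 2c, 2s, ...; degree 0 is the global
    frequency term.  Coordinates are taken relative to the expansion
    center (mask centroid by default) and expressed in cm to keep raw
    column magnitudes comparable across degrees.
    """
    if fieldmap.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    idx = np.argwhere(mask.data)
    if len(idx) == 0:
        raise ValueError("mask selects no voxels")
    centers = fieldmap.voxel_centers()[mask.data]  # (n_masked, 3) mm

    if spec.center is None:
        center = centers.mean(axis=0)
    else:
        center = np.asarray(spec.center, dtype=float)
    rel = (centers - center) / 10.0  # cm
    if np.all(np.linalg.norm(rel, axis=1) < 1e-9) and len(rel) > 0:
        raise ValueError("degenerate mask: all points at the expansion center")

    x, y, z = rel[:, 0], rel[:, 1], rel[:, 2]
    cols, labels = [], []
    for n in range(spec.max_degree + 1):
        orders = [0] + [s * m for m in range(1, n + 1) for s in (1, -1)]
        for m in orders:
            cols.append(_real_solid_harmonic(n, m, x, y, z))
            tag = "c" if m >= 0 else "s"
            labels.append(f"sh{n}{abs(m)}{tag}" if n else "sh00")
    values = np.stack(cols, axis=1)
    if spec.normalize:
        rms = np.sqrt(np.mean(values**2, axis=0))
        if np.any(rms <= 0):
            raise ValueError("degenerate mask: zero-RMS basis column")
        values = values / rms
    return BasisMatrix(values, labels, idx, units="Hz/unit")


def assemble_coil_basis(
    layout: CoilLayout,
    fieldmap: FieldMap,
    mask: BrainMask,
    n_segments: int = 256,
) -> BasisMatrix:
    """Stack per-loop Biot-Savart fields at masked voxel centers, Hz/A."""
    if fieldmap.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    idx = np.argwhere(mask.data)
    if len(idx) == 0:
        raise ValueError("mask selects no voxels")
    centers = fieldmap.voxel_centers()[mask.data]

    cols = []
    for loop in layout.loops:
        # loops must stay clear of the tissue they shim
        d = np.linalg.norm(centers - np.asarray(loop.center), axis=1)
        if np.any(d < loop.radius * 0.5):
            raise ValueError(
                f"loop {loop.label!r} intersects the masked volume"
            )
        cols.append(loop_bz_numeric(loop, centers, n_segments))
    values = np.stack(cols, axis=1)
    return BasisMatrix(values, layout.labels, idx, units="Hz/A")
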