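"""Field-map containers and I/O.

Off-resonance field maps are 3-D scalar volumes in Hz on a regular grid.
Axes are ordered (x, y, z) with z the main-field (B0) axis; world
coordinates in mm are ``origin + index * spacing`` with 0-based voxel
indices (voxel centers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "FieldMap",
    "BrainMask",
    "EchoPair",
    "phase_diff_to_hz",
    "load_volume",
    "save_volume",
    "masked_stats",
]


@dataclass(frozen=True)
class FieldMap:
    """Off-resonance frequency volume.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Frequency offset in Hz at each voxel center.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm; strictly positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    subject_id : str
        Free-form identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError("field data must be a 3-D array with dims >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("field data must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3) in mm."""
        axes = [
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
            for d in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)

    def with_data(self, data: np.ndarray) -> "FieldMap":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass(frozen=True)
class BrainMask:
    """Boolean volume sharing geometry with its paired :class:`FieldMap`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            data = data > 0.5
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if data.ndim != 3:
            raise ValueError("mask must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_true(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass(frozen=True)
class EchoPair:
    """Dual-echo phase volumes (radians) with their echo times in ms."""

    phase1: np.ndarray
    phase2: np.ndarray
    te1_ms: float
    te2_ms: float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase1", np.asarray(self.phase1, dtype=float))
        object.__setattr__(self, "phase2", np.asarray(self.phase2, dtype=float))
        if self.phase1.shape != self.phase2.shape:
            raise ValueError("echo phase volumes must have identical shapes")
        if self.te2_ms <= self.te1_ms:
            raise ValueError("second echo time must exceed the first")


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map phase into [-pi, pi)."""
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def phase_diff_to_hz(echoes: EchoPair) -> FieldMap:
    """Convert a dual-echo phase pair to an off-resonance map in Hz.

    f = wrap(phi2 - phi1) / (2*pi*dTE) with dTE in seconds.  Frequencies
    are alias-free only within +-1/(2*dTE); no unwrapping beyond the
    single wrap of the echo difference is attempted.
    """
    dte_s = (echoes.te2_ms - echoes.te1_ms) / 1000.0
    dphi = _wrap_phase(echoes.phase2 - echoes.phase1)
    hz = dphi / (2.0 * np.pi * dte_s)
    return FieldMap(hz, spacing=echoes.spacing, origin=echoes.origin)


def _geometry_from_header(img: nib.nifti1.Nifti1Image):
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("NIfTI header has non-positive voxel sizes")
    affine = img.affine
    origin = tuple(float(v) for v in affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def load_volume(path, kind: str = "field"):
    """Load a NIfTI volume as a :class:`FieldMap` or :class:`BrainMask`.

    ``kind`` is one of ``field``, ``mask`` or ``roi``; mask/roi volumes are
    binarized at > 0.5.  Spacing comes from the header zooms and the origin
    from the affine translation.
    """
    if kind not in ("field", "mask", "roi"):
        raise ValueError(f"unknown volume kind {kind!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    spacing, origin = _geometry_from_header(img)
    if kind == "field":
        return FieldMap(data.astype(float), spacing=spacing, origin=origin)
    return BrainMask(data > 0.5, spacing=spacing, origin=origin)


def save_volume(vol, path) -> None:
    """Write a FieldMap (float32, Hz) or BrainMask (uint8) as NIfTI-1."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    if isinstance(vol, BrainMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def masked_stats(fieldmap: FieldMap, mask: BrainMask) -> tuple[float, float, int]:
    """Mean, population SD (ddof=0) and count over masked voxels."""
    if fieldmap.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    vals = fieldmap.data[mask.data]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    return float(vals.mean()), float(vals.std(ddof=0)), int(vals.size)
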