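"""MRSI linewidth model and brain-coverage metric.

The modelled spectral linewidth of an MRSI voxel is

    linewidth = baseline + SD(intravoxel field)

where the baseline (default 9 Hz) lumps the T2 term 1/(pi*T2) with the
microscopic susceptibility broadening, and the macroscopic term is the
population SD of the field-map pixels inside the voxel.  A voxel is
usable when its linewidth is strictly below the threshold (default
18 Hz); brain coverage is the percentage of brain voxels that are
usable.  At the default 2.4 x 2.4 x 2 mm field-map grid a 12 x 12 x 10
mm MRSI voxel comprises a 5 x 5 x 5 = 125-pixel block (1.44 cc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fieldmap_io import BrainMask, FieldMap

__all__ = [
    "LinewidthModel",
    "MRSIGrid",
    "CoverageResult",
    "block_partition",
    "voxel_linewidth",
    "compute_coverage",
    "region_coverage",
]


@dataclass(frozen=True)
class LinewidthModel:
    """Baseline linewidth plus usability threshold, both in Hz."""

    baseline_hz: float = 9.0
    threshold_hz: float = 18.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_hz < self.threshold_hz:
            raise ValueError("require 0 < baseline_hz < threshold_hz")


@dataclass(frozen=True)
class MRSIGrid:
    """MRSI voxel expressed as a block of field-map pixels per axis."""

    block_dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (2.4, 2.4, 2.0)

    def __post_init__(self) -> None:
        bd = tuple(int(b) for b in self.block_dims)
        object.__setattr__(self, "block_dims", bd)
        if any(b < 1 for b in bd):
            raise ValueError("block dims must be >= 1")

    @property
    def pixels_per_voxel(self) -> int:
        bx, by, bz = self.block_dims
        return bx * by * bz

    @property
    def voxel_volume_cc(self) -> float:
        mm3 = np.prod(
            [b * s for b, s in zip(self.block_dims, self.spacing_mm)]
        )
        return float(mm3) / 1000.0


@dataclass(frozen=True)
class CoverageResult:
    """Per-MRSI-voxel linewidths and the coverage they imply."""

    linewidth: np.ndarray        # (nbx, nby, nbz), Hz; NaN outside brain
    usable: np.ndarray           # boolean, same shape
    brain_voxel: np.ndarray      # boolean, same shape
    n_brain_voxels: int
    n_usable: int
    coverage_pct: float
    grid: MRSIGrid
    threshold_hz: float
    # bookkeeping for region coverage: per-block in-mask pixel count
    in_mask_count: np.ndarray = None


def block_partition(
    spacing_mm: tuple[float, float, float],
    voxel_size_mm: tuple[float, float, float],
) -> MRSIGrid:
    """Express an MRSI voxel size as whole field-map pixels per axis.

    Per-axis block dimension is round-half-up(voxel/spacing), floored at
    1; a realized volume deviating more than 15% from the request emits a
    warning (the metric is still well defined on the realized grid).
    """
    if any(s <= 0 for s in spacing_mm) or any(v <= 0 for v in voxel_size_mm):
        raise ValueError("spacings and voxel sizes must be positive")
    dims = tuple(
        max(1, int(np.floor(v / s + 0.5)))
        for v, s in zip(voxel_size_mm, spacing_mm)
    )
    grid = MRSIGrid(dims, tuple(float(s) for s in spacing_mm))
    requested_cc = float(np.prod(voxel_size_mm)) / 1000.0
    if abs(grid.voxel_volume_cc - requested_cc) > 0.15 * requested_cc:
        warnings.warn(
            f"realized MRSI voxel {grid.voxel_volume_cc:.3f} cc deviates "
            f">15% from requested {requested_cc:.3f} cc",
            stacklevel=2,
        )
    return grid


def voxel_linewidth(block_values: np.ndarray, model: LinewidthModel) -> float:
    """Linewidth of one MRSI voxel from its in-mask pixel frequencies."""
    vals = np.asarray(block_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty block")
    return model.baseline_hz + float(vals.std(ddof=0))


def _block_reduce(vol: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Sum over non-overlapping blocks; trailing partial blocks kept."""
    out = vol
    for ax, b in enumerate(dims):
        n = out.shape[ax]
        edges = np.arange(0, n, b)
        out = np.add.reduceat(out, edges, axis=ax)
    return out


def compute_coverage(
    fieldmap: FieldMap,
    mask: BrainMask,
    grid: MRSIGrid,
    model: LinewidthModel = LinewidthModel(),
) -> CoverageResult:
    """Coverage over the MRSI grid tiled from the volume origin.

    A block counts as a brain voxel when more than half of its pixels are
    in the brain mask; its SD is computed over the in-mask pixels only.
    Usable means linewidth strictly below the threshold.
    """
    if fieldmap.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    dims = grid.block_dims
    m = mask.data.astype(float)
    f = fieldmap.data * mask.data

    n_in = _block_reduce(m, dims)                    # in-mask pixels per block
    s1 = _block_reduce(f, dims)                      # sum of in-mask values
    s2 = _block_reduce(f * fieldmap.data, dims)      # sum of squares

    # pixels actually present in each (possibly partial) block
    ones = np.ones(fieldmap.shape)
    n_tot = _block_reduce(ones, dims)

    brain = n_in > 0.5 * n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n_in
        var = s2 / n_in - mean**2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var)
    linewidth = np.where(brain, model.baseline_hz + sd, np.nan)
    usable = brain & (linewidth < model.threshold_hz)

    n_brain = int(brain.sum())
    if n_brain == 0:
        raise ValueError("no brain voxels on the MRSI grid")
    n_usable = int(usable.sum())
    return CoverageResult(
        linewidth=linewidth,
        usable=usable,
        brain_voxel=brain,
        n_brain_voxels=n_brain,
        n_usable=n_usable,
        coverage_pct=100.0 * n_usable / n_brain,
        grid=grid,
        threshold_hz=model.threshold_hz,
        in_mask_count=n_in,
    )


def region_coverage(
    cov: CoverageResult, mask: BrainMask, roi: BrainMask
) -> float:
    """Coverage restricted to brain voxels majority-inside the ROI.

    A brain voxel belongs to the region when more than half of its
    in-mask pixels fall inside the ROI; numerator and denominator of the
    coverage percentage are restricted accordingly.
    """
    if roi.shape != mask.shape:
        raise ValueError("ROI and mask shapes differ")
    dims = cov.grid.block_dims
    both = (roi.data & mask.data).astype(float)
    n_roi = _block_reduce(both, dims)
    in_region = cov.brain_voxel & (n_roi > 0.5 * cov.in_mask_count)
    n_brain = int(in_region.sum())
    if n_brain == 0:
        raise ValueError("ROI intersects no brain voxels")
    n_usable = int((in_region & cov.usable).sum())
    return 100.0 * n_usable / n_brain
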