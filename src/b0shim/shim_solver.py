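"""Current-bounded least-squares shimming.

The shim problem is: given the masked off-resonance field f (Hz) and a
basis matrix A (Hz per ampere or per unit coefficient), find coefficients
c minimizing ||f + A c||^2 subject to per-channel box bounds (coil
currents limited to +-3.0 A; spherical-harmonic coefficients unbounded).
A global frequency column (all ones, unbounded) mirrors the scanner
center-frequency adjustment and is included for every method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .field_basis import BasisMatrix

__all__ = ["ShimProblem", "ShimResult", "solve_shim", "sd_reduction_pct", "kkt_check"]


@dataclass(frozen=True)
class ShimProblem:
    """Bounded least-squares shim problem over masked voxels."""

    basis: BasisMatrix
    field: np.ndarray  # masked voxel frequencies, Hz
    lower: np.ndarray  # per-channel lower bounds (A or -inf)
    upper: np.ndarray
    include_f0: bool = True

    def __post_init__(self) -> None:
        field = np.asarray(self.field, dtype=float)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "field", field)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if field.ndim != 1 or len(field) != self.basis.values.shape[0]:
            raise ValueError("field length must equal basis row count")
        nch = self.basis.n_channels
        if lower.shape != (nch,) or upper.shape != (nch,):
            raise ValueError("one bound pair per channel required")
        if np.any(lower > 0) or np.any(upper < 0):
            raise ValueError("zero current must be feasible (lower <= 0 <= upper)")
        if not np.all(np.isfinite(field)):
            raise ValueError("field values must be finite")

    @classmethod
    def from_basis(
        cls,
        basis: BasisMatrix,
        field: np.ndarray,
        current_bound_a: float | None = 3.0,
        include_f0: bool = True,
    ) -> "ShimProblem":
        """Symmetric bounds of +-current_bound_a; None means unbounded."""
        nch = basis.n_channels
        if current_bound_a is None:
            lo = np.full(nch, -np.inf)
            hi = np.full(nch, np.inf)
        else:
            lo = np.full(nch, -float(current_bound_a))
            hi = np.full(nch, float(current_bound_a))
        return cls(basis, field, lo, hi, include_f0)


@dataclass(frozen=True)
class ShimResult:
    """Optimal coefficients and the residual field they leave behind."""

    coefficients: np.ndarray  # per basis channel (excludes the f0 term)
    f0_hz: float              # fitted global frequency offset, Hz
    residual: np.ndarray      # field + basis @ c + f0, Hz
    sd_before: float
    sd_after: float
    active_bounds: tuple[int, ...]


def _augmented_system(problem: ShimProblem):
    A = problem.basis.values
    lo, hi = problem.lower, problem.upper
    if problem.include_f0:
        A = np.hstack([A, np.ones((A.shape[0], 1))])
        lo = np.append(lo, -np.inf)
        hi = np.append(hi, np.inf)
    return A, lo, hi


def solve_shim(problem: ShimProblem, tol: float = 1e-10) -> ShimResult:
    """Minimize ||field + A c||^2 subject to the box bounds.

    Unbounded problems go through the minimum-norm least-squares solution
    (lstsq); bounded ones through bounded-variable least squares.  The
    residual SD can never exceed the pre-shim SD because zero current is
    always feasible.
    """
    A, lo, hi = _augmented_system(problem)
    f = problem.field
    if A.shape[0] < 1 or np.all(A == 0):
        raise ValueError("degenerate problem: no voxels or zero basis")

    if np.all(np.isinf(lo)) and np.all(np.isinf(hi)):
        c, *_ = np.linalg.lstsq(A, -f, rcond=None)
    else:
        res = lsq_linear(
            A, -f, bounds=(lo, hi), method="bvls", tol=tol, max_iter=10_000
        )
        c = res.x
        # clip the solver's tiny feasibility slack so bounds hold exactly
        c = np.clip(c, lo, hi)

    residual = f + A @ c
    sd_before = float(f.std(ddof=0))
    sd_after = float(residual.std(ddof=0))
    nch = problem.basis.n_channels
    coeff = c[:nch]
    f0 = float(c[nch]) if problem.include_f0 else 0.0
    atol = 1e-9
    active = tuple(
        int(i)
        for i in range(nch)
        if (np.isfinite(problem.lower[i]) and coeff[i] <= problem.lower[i] + atol)
        or (np.isfinite(problem.upper[i]) and coeff[i] >= problem.upper[i] - atol)
    )
    return ShimResult(coeff, f0, residual, sd_before, sd_after, active)


def sd_reduction_pct(sd_before: float, sd_after: float) -> float:
    """Percent reduction 100 * (1 - sd_after / sd_before)."""
    if sd_before <= 0:
        raise ValueError("sd_before must be positive")
    return 100.0 * (1.0 - sd_after / sd_before)


def kkt_check(
    problem: ShimProblem, result: ShimResult, tol: float = 1e-6
) -> tuple[bool, dict]:
    """First-order optimality audit of a shim solution.

    The objective gradient is g = 2 A^T (f + A c).  At an optimum,
    interior channels have |g_i| < tol (relative to the gradient scale),
    channels at an upper bound have g_i <= tol (increasing c_i is
    infeasible, decreasing it must not help), and symmetrically at lower
    bounds.
    """
    A, lo, hi = _augmented_system(problem)
    c = np.append(result.coefficients, result.f0_hz) if problem.include_f0 \
        else result.coefficients
    g = 2.0 * A.T @ (problem.field + A @ c)
    scale = max(float(np.abs(A.T @ problem.field).max()) * 2.0, 1.0)
    gtol = tol * scale
    atol = 1e-9
    per_channel = []
    for i in range(len(c)):
        at_lo = np.isfinite(lo[i]) and c[i] <= lo[i] + atol
        at_hi = np.isfinite(hi[i]) and c[i] >= hi[i] - atol
        if at_hi and not at_lo:
            ok = g[i] <= gtol
        elif at_lo and not at_hi:
            ok = g[i] >= -gtol
        else:
            ok = abs(g[i]) <= gtol
        per_channel.append(bool(ok))
    report = {
        "gradient": g,
        "per_channel": per_channel,
        "tolerance": gtol,
    }
    return all(per_channel), report
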