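# Methods

## Field maps and conventions

A field map is a 3-D array of off-resonance frequencies in Hz on a
regular grid; axes are (x, y, z) with z along B0, 0-based voxel indices,
and world coordinates `origin + index * spacing` (voxel centers, mm).
Dual-echo phase pairs convert to Hz as `wrap(phi2 - phi1) / (2 pi dTE)`;
with the default echo times (2.00 / 4.46 ms) the alias-free band is
±203.25 Hz, and no unwrapping beyond the single wrap of the echo
difference is attempted — inputs are assumed alias-free.

All SDs in the package are population SDs (denominator n). The choice
is arbitrary at the block sizes involved (n = 125 changes the result by
0.4%), but a single convention applied everywhere keeps the linewidth
metric, the homogeneity metric and the cohort aggregates mutually
consistent and deterministic.

## Coil fields

The per-ampere field of a circular loop is the z-component of the
Biot–Savart field, converted to Hz with the proton gyromagnetic ratio
(42.577 MHz/T, declared once). The numeric path discretizes the loop
into straight segments, each contributing its exact finite-wire field.
The polygon's circumradius is scaled so the polygon area equals the
circle area; this cancels the leading O(1/n²) dipole-moment bias of an
inscribed polygon and leaves errors that decay like 1/n⁴ away from the
wire (raw relative error ~7e-7 at 256 segments, ~2e-4 at 64). The
independent oracle is the closed-form circular-filament solution in
complete elliptic integrals, combining the loop-frame axial and radial
components into the laboratory z-component for tilted loops.

Defaults: 256 segments for basis construction in general, 64 inside the
cohort pipeline (the discretization error there is orders of magnitude
below every metric of interest, and the pipeline evaluates ~80 loops
per subject). Points within 0.1 mm of the wire raise an error. Only the
z-component of B perturbs resonance (standard MR approximation).
Transverse components, finite conductor cross-sections, eddy currents
and inter-loop coupling are ignored.

## Coil layouts

Measured loop coordinates for the two arrays are hardware-specific and
not published, so layouts are deterministic constructions from a simple
helmet model — a spherical dome (radius 115 mm) over a cylindrical
skirt (half-height 60 mm), enclosing the 214×250×120 mm field of view
with clearance. Because the area element is 2πR dz on both the sphere
and the cylinder, a golden-angle spiral uniform in z distributes loops
evenly over the whole surface:

* **32-channel array**: 32 single-turn loops of radius 47.5 mm (9.5 cm
  diameter) spread evenly.
* **51-channel array**: 27 such large loops, plus a 2×4 forehead grid of
  5 cm 2-turn loops straddling the dome equator (facing the PFC), plus a
  ring of eight 4 cm 2-turn loops around each ear anchor on the skirt.
  The 24 small loops split 8 + 8 + 8, forced by the 51 − 27 = 24 count
  and the per-region grouping of the design.

Every loop center lies exactly on the helmet surface with the outward
surface normal. Per-channel current bounds default to ±3.0 A for both
arrays. Layouts serialize to JSON so measured coordinates can replace
the defaults without code changes; normals within 1e-6 of unit length
are renormalized on load, anything worse is rejected.

## Spherical-harmonic basis

Real solid harmonics rⁿPₙᵐ(cos θ){cos, sin}(mφ) for degrees 0–5 about
the brain-mask centroid (the shim isocenter convention), coordinates in
cm. Degree n contributes 2n + 1 terms — 9 terms through degree 2, then
+7, +9, +11 for degrees 3–5. Degree 0 is the global frequency term.
Columns are scaled to unit RMS over the mask for conditioning only;
with unbounded coefficients the fitted field is invariant to column
scale. Harmonicity is verified discretely: the central-difference
Laplacian of every raw column stays below 1e-6 × column RMS per mm² on
a 48³ lattice.

## Shim solver

Bounded linear least squares: minimize ‖f + A c‖² over the masked
voxels, subject to per-channel boxes. Coil channels are bounded ±3.0 A;
SH coefficients are unbounded (the current constraint applies to
surface coils, not to idealized harmonic terms). A global frequency
column (all ones, unbounded) is always appended, mirroring the scanner
center-frequency adjustment; SD-based metrics are insensitive to it.
Bounded problems use BVLS (tolerance 1e-10, iteration cap 10 000) with
a final exact clip to the box; unbounded problems use the minimum-norm
least-squares solution. Optimality is auditable: the KKT check verifies
a vanishing gradient on interior channels and an outward-pushing
gradient on active bounds, and randomized problems are compared against
dense grid search over the box.

Consequences asserted as invariants: zero current is always feasible,
so the residual SD never exceeds the pre-shim SD; nested SH bases give
monotonically non-increasing residual SD; adding channels never hurts.

## Linewidth and coverage

Modelled MRSI voxel linewidth = baseline + SD(intravoxel frequencies).
The baseline (default 9 Hz) lumps the T2 term 1/(πT2) with microscopic
susceptibility broadening; the macroscopic term is the population SD of
the field-map pixels in the voxel's block, used unscaled (no FWHM
factor — the SD itself is the transformation into linewidth space).
A voxel is usable iff linewidth < 18 Hz, strictly.

Blocks tile the volume from its origin; per-axis block size is
round-half-up(voxel size / pixel spacing), floored at 1, with a warning
when the realized volume deviates more than 15% from the request.
Trailing partial blocks are kept. A block is a brain voxel when more
than half of its pixels are in-mask; its SD uses in-mask pixels only.
ROI membership follows the same majority rule over in-mask pixels.
Coverage = 100 × usable / brain voxels, with numerator and denominator
restricted for ROI coverage.

## Synthetic subjects

The generator emulates the statistical structure of 3 T brain field
maps on the acquisition grid (2.4×2.4×2 mm voxels, 214×250×120 mm FOV):

* **Brain mask**: ellipsoid (default semiaxes 65×80×55 mm ≈ 1.2 L)
  minus any cavity spheres that intersect it.
* **Cavity fields**: each air cavity is a sphere of susceptibility
  contrast Δχ = 9.4 ppm (air − tissue, SI) in a uniform 3 T field,
  contributing the external Lorentz-sphere dipole
  f0·(Δχ/3)·(a/r)³·(3cos²θ − 1) outside radius a and 0 inside. Default
  anchors: frontal sinus (0, 78, −40) mm radius 14, ear canals
  (±68, 0, −35) mm radius 11 — just outside the brain ellipsoid, as the
  real cavities sit outside a BET mask, so the nearest brain voxels see
  a few hundred Hz decaying over 2–3 cm.
* **Background**: a degree-2 polynomial in cm with a nearly trace-free
  quadratic part. Fields from sources outside the head are harmonic, so
  a strongly non-harmonic background would be equally invisible to
  every shim method and would only mask their differences.
* **Noise**: i.i.d. Gaussian per voxel, default SD 2.5 Hz, representing
  field-map estimation noise plus unmodelled fine texture.
* **ROIs**: fixed boxes placed relative to the cavity anchors (a PFC box
  behind the frontal sinus, MTL boxes inboard of each ear canal),
  intersected with the brain mask. Atlas-based ROIs are out of scope.

Defaults put the unshimmed whole-brain SD near 28 Hz (a plausible 3 T
value) and were chosen so the generator exercises the same contrast the
study design targets: localized high-order inhomogeneity at the sinus
and ears on a smooth shimmable background. Cohorts jitter cavity
centers (SD 3 mm), radii (SD 0.8 mm, floored), and polynomial
coefficients (25% relative), all from a master seed via spawned
sequences; every subject is bit-reproducible.

What the generator does **not** model: gyral/tissue microstructure,
within-brain susceptibility sources (real in-brain fields are not
harmonic), CSF/bone geometry, motion or physiological drift. Passing
cohort tests therefore demonstrate correct mechanics and the expected
qualitative method ordering, not quantitative agreement with human
data — whole-brain coverage on synthetic subjects runs in the 90s of
percent, whereas real brains at 3 T sit far lower.

## Cohort pipeline and statistics

Each subject is shimmed by all six methods; coverage is evaluated on
the residual field at 12×12×10 mm and 4.8×4.8×4 mm requested voxel
sizes, whole-brain and per ROI. Aggregates are mean ± population SD per
method. The omnibus test is one-way ANOVA across methods; pairwise
comparisons are paired t-tests across subjects (the same subjects are
shimmed by every method, so the paired design is the honest one;
unpaired tests are available via a flag), Bonferroni-multiplied by
C(n_methods, 2) and capped at 1. Degenerate all-equal data defines
F = 0, p = 1.

The default study runs 24 subjects on a grid 2× coarser than the
acquisition grid (4.8×4.8×4 mm). This is the package's chosen default
problem size: it cuts basis construction ~8-fold while leaving the
method ordering and all solver/coverage mechanics unchanged. Two
consequences are worth knowing. First, the 12×12×10 mm MRSI voxel
realizes as a 3×3×3 block (14.4×14.4×12 mm) on the coarse grid — the
partition warns about the volume mismatch, and the pipeline proceeds on
the realized grid. Second, the 4.8 mm high-resolution voxel maps to a
single coarse pixel, whose intravoxel SD is zero, so high-resolution
coverage is 100% by construction at this grid; its per-method ordering
is meaningful only on the acquisition grid.

## Known limitations

* Loop geometry is a documented approximation of the physical helmets;
  absolute per-channel efficiencies depend on it.
* The solver has no regularization, current-sum limit or power
  constraint beyond the per-channel box.
* Coverage uses a single global linewidth baseline; T2 variation across
  tissue is not modelled.
* The statistics module implements exactly one-way ANOVA plus
  Bonferroni-adjusted pairwise t-tests; no repeated-measures ANOVA or
  post-hoc alternatives.
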