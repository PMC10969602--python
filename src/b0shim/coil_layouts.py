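"""Parametric shim-coil layouts.

Two helmet-mounted multi-coil arrays are provided:

* a 32-channel array of large shared shim/RF loops (9.5 cm diameter,
  single turn) distributed evenly over the helmet, and
* a 51-channel array combining 27 evenly distributed large loops with 24
  size-matched small 2-turn loops (8 of 5 cm over the forehead, 8 of 4 cm
  around each ear canal) targeting the regions worst affected by
  air-tissue susceptibility fields.

Exact measured loop coordinates for such coils are hardware-specific, so
the constructors here place loops deterministically from a simple helmet
model (spherical dome over a cylindrical skirt); layouts serialize to
JSON so measured coordinates can replace the defaults without touching
code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoopSpec",
    "HelmetModel",
    "CoilLayout",
    "layout_ipres32",
    "layout_unic51",
    "save_layout",
    "load_layout",
    "DEFAULT_CURRENT_BOUND_A",
]

#: Per-channel DC current limit (A), applied to both layouts by default.
DEFAULT_CURRENT_BOUND_A = 3.0

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class LoopSpec:
    """A circular shim loop: center/normal geometry plus electrical turns."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float
    turns: int = 1
    current_bound_a: float = DEFAULT_CURRENT_BOUND_A
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("loop normal must be a unit vector")
        object.__setattr__(self, "normal", tuple(n / norm))
        if self.radius <= 0:
            raise ValueError("loop radius must be positive")
        if self.turns < 1:
            raise ValueError("turns must be a positive integer")
        if self.current_bound_a <= 0:
            raise ValueError("current bound must be positive")


@dataclass(frozen=True)
class HelmetModel:
    """Helmet surface: spherical dome on top of a cylindrical skirt.

    The dome is the upper hemisphere (z >= dome_center_z) of a sphere of
    ``dome_radius``; below it a cylinder of the same radius extends down
    by ``cylinder_half_height``.  Defaults enclose a 214 x 250 x 120 mm
    brain field of view with clearance.
    """

    dome_radius: float = 115.0
    dome_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cylinder_half_height: float = 60.0

    def __post_init__(self) -> None:
        if self.dome_radius <= 0 or self.cylinder_half_height < 0:
            raise ValueError("helmet dimensions must be positive")
        object.__setattr__(
            self, "dome_center", tuple(float(c) for c in self.dome_center)
        )

    def surface_point(self, z: float, phi: float):
        """Point and outward normal on the helmet at height z, azimuth phi.

        z is relative to the dome center; sphere for z >= 0, cylinder below.
        """
        cx, cy, cz = self.dome_center
        R = self.dome_radius
        if z >= 0.0:
            z = min(z, R)
            rho = math.sqrt(max(R * R - z * z, 0.0))
            p = (cx + rho * math.cos(phi), cy + rho * math.sin(phi), cz + z)
            n = ((p[0] - cx) / R, (p[1] - cy) / R, z / R)
        else:
            p = (cx + R * math.cos(phi), cy + R * math.sin(phi), cz + z)
            n = (math.cos(phi), math.sin(phi), 0.0)
        return p, n


@dataclass(frozen=True)
class CoilLayout:
    """Named, ordered collection of shim loops; channel order is loop order."""

    name: str
    loops: tuple[LoopSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "loops", tuple(self.loops))

    @property
    def n_channels(self) -> int:
        return len(self.loops)

    @property
    def labels(self) -> list[str]:
        return [lp.label for lp in self.loops]


def _even_helmet_loops(
    helmet: HelmetModel,
    n: int,
    radius: float,
    turns: int,
    current_bound_a: float,
    prefix: str,
    z_top_margin: float = 18.0,
) -> list[LoopSpec]:
    """Distribute n loops evenly over dome + skirt using a golden-angle spiral.

    Surface area per unit height is 2*pi*R*dz on both the sphere and the
    cylinder, so uniform sampling in z is area-uniform across the whole
    helmet.  A margin below the pole keeps the top loop well defined.
    """
    z_hi = helmet.dome_radius - z_top_margin
    z_lo = -helmet.cylinder_half_height
    loops = []
    for k in range(n):
        z = z_hi + (z_lo - z_hi) * (k + 0.5) / n
        phi = k * _GOLDEN_ANGLE
        p, nrm = helmet.surface_point(z, phi)
        loops.append(
            LoopSpec(p, nrm, radius, turns, current_bound_a, f"{prefix}{k:02d}")
        )
    return loops


def _frontal_grid_loops(
    helmet: HelmetModel, radius: float, turns: int, current_bound_a: float
) -> list[LoopSpec]:
    """2 x 4 grid of small loops over the forehead patch (+y anterior).

    Rows sit just below and just above the dome equator so the patch
    faces the prefrontal cortex and the frontal-sinus field it suffers.
    """
    loops = []
    heights = (-18.0, 14.0)  # mm relative to the dome center
    azimuths = (-0.48, -0.16, 0.16, 0.48)  # radians around +y
    k = 0
    for z in heights:
        for az in azimuths:
            phi = math.pi / 2.0 + az  # +y is anterior
            p, nrm = helmet.surface_point(z, phi)
            loops.append(
                LoopSpec(p, nrm, radius, turns, current_bound_a, f"F{k:02d}")
            )
            k += 1
    return loops


def _ear_ring_loops(
    helmet: HelmetModel,
    side: int,
    radius: float,
    turns: int,
    current_bound_a: float,
    ring_radius: float = 26.0,
    z_anchor: float = -35.0,
) -> list[LoopSpec]:
    """Ring of 8 small loops around an ear-canal anchor on the skirt.

    side is +1 (left, +x) or -1 (right, -x).  The ring is laid out in
    (arc-length, z) surface coordinates of the cylinder so every center
    sits exactly on the helmet with the outward radial normal.
    """
    R = helmet.dome_radius
    phi0 = 0.0 if side > 0 else math.pi
    tag = "L" if side > 0 else "R"
    loops = []
    for k in range(8):
        ang = 2.0 * math.pi * k / 8.0
        phi = phi0 + (ring_radius * math.cos(ang)) / R
        z = z_anchor + ring_radius * math.sin(ang)
        p, nrm = helmet.surface_point(z, phi)
        loops.append(
            LoopSpec(p, nrm, radius, turns, current_bound_a, f"E{tag}{k:02d}")
        )
    return loops


def layout_ipres32(helmet: HelmetModel | None = None) -> CoilLayout:
    """32 single-turn 9.5 cm loops distributed evenly over the helmet."""
    helmet = helmet or HelmetModel()
    loops = _even_helmet_loops(
        helmet, 32, 47.5, 1, DEFAULT_CURRENT_BOUND_A, "I"
    )
    return CoilLayout("ipres32", loops)


def layout_unic51(helmet: HelmetModel | None = None) -> CoilLayout:
    """27 large loops + 8 frontal (5 cm) + 8 per ear (4 cm) 2-turn loops."""
    helmet = helmet or HelmetModel()
    loops = _even_helmet_loops(
        helmet, 27, 47.5, 1, DEFAULT_CURRENT_BOUND_A, "B"
    )
    loops += _frontal_grid_loops(helmet, 25.0, 2, DEFAULT_CURRENT_BOUND_A)
    loops += _ear_ring_loops(helmet, +1, 20.0, 2, DEFAULT_CURRENT_BOUND_A)
    loops += _ear_ring_loops(helmet, -1, 20.0, 2, DEFAULT_CURRENT_BOUND_A)
    return CoilLayout("unic51", loops)


_REQUIRED_LOOP_KEYS = {"center_mm", "normal", "radius_mm", "turns",
                       "current_bound_a", "label"}


def save_layout(layout: CoilLayout, path) -> None:
    """Serialize a layout to JSON at full float precision."""
    doc = {
        "name": layout.name,
        "loops": [
            {
                "center_mm": list(lp.center),
                "normal": list(lp.normal),
                "radius_mm": lp.radius,
                "turns": lp.turns,
                "current_bound_a": lp.current_bound_a,
                "label": lp.label,
            }
            for lp in layout.loops
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_layout(path) -> CoilLayout:
    """Load a JSON layout; normals are renormalized if |norm - 1| < 1e-6."""
    with open(path) as fh:
        doc = json.load(fh)
    if "name" not in doc or "loops" not in doc:
        raise ValueError("layout file missing 'name' or 'loops'")
    loops = []
    for i, entry in enumerate(doc["loops"]):
        missing = _REQUIRED_LOOP_KEYS - set(entry)
        if missing:
            raise ValueError(f"loop {i} missing fields: {sorted(missing)}")
        n = np.asarray(entry["normal"], dtype=float)
        norm = float(np.linalg.norm(n))
        if abs(norm - 1.0) >= 1e-6:
            raise ValueError(f"loop {i} normal norm {norm} outside tolerance")
        loops.append(
            LoopSpec(
                tuple(entry["center_mm"]),
                tuple(n / norm),
                float(entry["radius_mm"]),
                int(entry["turns"]),
                float(entry["current_bound_a"]),
                str(entry["label"]),
            )
        )
    return CoilLayout(str(doc["name"]), loops)
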