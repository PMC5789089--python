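"""Discretized membrane topographies for clathrin-coated-pit bending models.

Two membrane-bending models are supported, each describing how a flat patch
of plasma membrane evolves into a closed ~100 nm vesicle:

* **Class 1 (fixed-radius bending)** — the pit is a sphere of fixed radius
  ``r`` intersecting the coverslip-proximal plane. Shifting the sphere center
  vertically from ``z_center = -r`` (tangent below the plane, i.e. flat) to
  ``z_center = +r`` (full sphere resting on the plane) sweeps the exposed
  spherical cap from nothing to a complete vesicle. Clathrin covers the cap,
  so clathrin content grows together with curvature.

* **Class 2 (constant-area bending)** — a circular membrane patch of fixed
  area, pre-covered with clathrin, is bent into spherical caps of decreasing
  curvature radius ``r_i``. The cap height is ``z_shift = area / (2 pi r_i)``
  (spherical-cap area ``A = 2 pi r h``), so sweeping ``r_i`` from very large
  (essentially flat) down to ``sqrt(area / 4 pi)`` closes the sphere while
  the clathrin amount stays constant.

Surfaces are discretized as parametric samples with exact per-element area
weights (sphere bands in theta, uniformly split in phi; the plane on a square
grid), which makes area conservation testable to float precision rather than
voxelization accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PLANE",
    "SPHERE",
    "COMPARTMENT_LABELS",
    "InvalidStageError",
    "GeometricOverclosureError",
    "MembraneSurface",
    "PitState",
    "make_class1_surface",
    "make_class2_surface",
    "build_surface",
    "stage_sequence",
    "total_area",
    "cap_base_radius",
]

# compartment codes (kept as uint8 for compact storage of large surfaces)
PLANE = 0
SPHERE = 1
COMPARTMENT_LABELS = {PLANE: "plane", SPHERE: "sphere"}
_LABEL_CODES = {v: k for k, v in COMPARTMENT_LABELS.items()}


class InvalidStageError(ValueError):
    """Raised when a pit-stage parameterization is geometrically impossible."""


class GeometricOverclosureError(InvalidStageError):
    """Raised when a constant-area cap would exceed a full sphere
    (``z_shift > 2 r_i``)."""


@dataclass
class MembraneSurface:
    """Struct-of-arrays container for discretized membrane elements.

    All positional quantities are in nanometres; ``z >= 0`` is the distance
    above the coverslip. ``theta`` / ``phi`` are spherical coordinates of a
    sphere element about its sphere center, with ``theta = 0`` pointing along
    +z (the pit apex). They are stored as 0 for plane elements, where the
    excitation weights do not use them.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    area: np.ndarray
    compartment: np.ndarray  # uint8 codes, see COMPARTMENT_LABELS
    clathrin_density: np.ndarray
    grid: float = 2.0
    extent: float = 2000.0

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "z", "theta", "phi", "area", "compartment", "clathrin_density"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if n and float(np.min(self.z)) < -1e-9:
            raise ValueError("membrane elements must satisfy z >= 0")
        if n and float(np.min(self.area)) <= 0:
            raise ValueError("element areas must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_sphere(self) -> np.ndarray:
        return self.compartment == SPHERE

    @property
    def is_plane(self) -> np.ndarray:
        return self.compartment == PLANE

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar debug view (one row per element), compartments as labels."""
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "theta": self.theta,
                "phi": self.phi,
                "area": self.area,
                "compartment": np.where(self.is_sphere, "sphere", "plane"),
                "clathrin_density": self.clathrin_density,
            }
        )

    @classmethod
    def concatenate(cls, parts: list["MembraneSurface"]) -> "MembraneSurface":
        if not parts:
            raise ValueError("nothing to concatenate")
        kw = {
            name: np.concatenate([getattr(p, name) for p in parts])
            for name in ("x", "y", "z", "theta", "phi", "area", "compartment", "clathrin_density")
        }
        return cls(grid=parts[0].grid, extent=parts[0].extent, **kw)


@dataclass(frozen=True)
class PitState:
    """One morphological stage of a pit progression.

    For the fixed-radius model the free parameter is the sphere-center height
    ``z_center``; for the constant-area model it is the curvature radius
    ``r_i`` (with ``z_shift`` derived). ``stage_index`` counts stages from
    flat (0) upward.
    """

    model: Literal["class1_fixed_radius", "class2_constant_area"]
    stage_index: int
    r: float | None = None
    z_center: float | None = None
    r_i: float | None = None
    area: float | None = None
    z_shift: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.stage_index < 0:
            raise InvalidStageError("stage_index must be >= 0")
        if self.model == "class1_fixed_radius":
            if self.r is None or self.z_center is None:
                raise InvalidStageError("class 1 state needs r and z_center")
            if self.r <= 0:
                raise InvalidStageError("sphere radius must be positive")
            if not (-self.r <= self.z_center <= self.r):
                raise InvalidStageError(
                    f"z_center={self.z_center} outside [-r, r] = [{-self.r}, {self.r}]"
                )
        elif self.model == "class2_constant_area":
            if self.r_i is None or self.area is None:
                raise InvalidStageError("class 2 state needs r_i and area")
            if self.r_i <= 0 or self.area <= 0:
                raise InvalidStageError("r_i and area must be positive")
            zs = self.area / (2.0 * np.pi * self.r_i)
            object.__setattr__(self, "z_shift", zs)
            if zs > 2.0 * self.r_i * (1 + 1e-9):
                raise GeometricOverclosureError(
                    f"z_shift={zs:.3f} exceeds sphere diameter 2*r_i={2 * self.r_i:.3f}"
                )
        else:
            raise InvalidStageError(f"unknown model {self.model!r}")

    @property
    def apex_height(self) -> float:
        """Height of the topmost membrane point above the coverslip (nm)."""
        if self.model == "class1_fixed_radius":
            return max(0.0, self.z_center + self.r)
        return float(self.z_shift)


def _sample_cap(
    r: float,
    theta_max: float,
    center_z: float,
    grid: float,
    clathrin_density: float,
) -> dict[str, np.ndarray]:
    """Sample a spherical cap theta in [0, theta_max] about a center at height
    ``center_z`` into elements of linear size <= grid with exact area weights."""
    if theta_max <= 0:
        return {k: np.empty(0) for k in ("x", "y", "z", "theta", "phi", "area")} | {
            "compartment": np.empty(0, dtype=np.uint8),
            "clathrin_density": np.empty(0),
        }
    n_t = max(1, int(np.ceil(r * theta_max / grid)))
    t_edges = np.linspace(0.0, theta_max, n_t + 1)
    xs, ys, zs, ths, phs, ars = [], [], [], [], [], []
    for t0, t1 in zip(t_edges[:-1], t_edges[1:]):
        t_mid = 0.5 * (t0 + t1)
        band_area = 2.0 * np.pi * r * r * (np.cos(t0) - np.cos(t1))
        n_p = max(1, int(np.ceil(2.0 * np.pi * r * np.sin(t_mid) / grid)))
        phi = (np.arange(n_p) + 0.5) * (2.0 * np.pi / n_p)
        sin_t = np.sin(t_mid)
        xs.append(r * sin_t * np.cos(phi))
        ys.append(r * sin_t * np.sin(phi))
        zs.append(np.full(n_p, center_z + r * np.cos(t_mid)))
        ths.append(np.full(n_p, t_mid))
        phs.append(phi)
        ars.append(np.full(n_p, band_area / n_p))
    x = np.concatenate(xs)
    z = np.maximum(np.concatenate(zs), 0.0)  # clip float dust at the base circle
    return {
        "x": x,
        "y": np.concatenate(ys),
        "z": z,
        "theta": np.concatenate(ths),
        "phi": np.concatenate(phs),
        "area": np.concatenate(ars),
        "compartment": np.full(len(x), SPHERE, dtype=np.uint8),
        "clathrin_density": np.full(len(x), clathrin_density),
    }


def _sample_plane(extent: float, grid: float, hole_radius: float) -> dict[str, np.ndarray]:
    """Square plane of side ``extent`` centered at the origin, grid-cell
    elements, excluding cells whose center lies inside the hole circle."""
    n = max(1, int(round(extent / grid)))
    c = (np.arange(n) + 0.5) * grid - extent / 2.0
    xg, yg = np.meshgrid(c, c, indexing="ij")
    x = xg.ravel()
    y = yg.ravel()
    if hole_radius > 0:
        keep = x * x + y * y > hole_radius * hole_radius
        x, y = x[keep], y[keep]
    m = len(x)
    zero = np.zeros(m)
    return {
        "x": x,
        "y": y,
        "z": zero,
        "theta": zero,
        "phi": zero,
        "area": np.full(m, grid * grid),
        "compartment": np.full(m, PLANE, dtype=np.uint8),
        "clathrin_density": zero,
    }


def make_class1_surface(
    r: float,
    z_center: float,
    grid: float = 2.0,
    extent: float = 2000.0,
    hole_radius: float | None = None,
) -> MembraneSurface:
    """Fixed-radius pit: sphere of radius ``r`` centered at height ``z_center``
    intersecting the plane; returns the exposed cap (z > 0) plus the plane
    with a hole at the intersection circle.

    ``hole_radius`` overrides the default rule (hole = base circle of the
    exposed cap); the treatment of the plane-cap junction is a modeling
    choice, so it is exposed.
    """
    if r <= 0:
        raise InvalidStageError("sphere radius must be positive")
    if not (-r <= z_center <= r):
        raise InvalidStageError(f"z_center={z_center} outside [-r, r]")
    cos_cut = np.clip(-z_center / r, -1.0, 1.0)
    theta_max = float(np.arccos(cos_cut))  # exposed cap: z = z_center + r cos(theta) > 0
    if hole_radius is None:
        hole_radius = r * np.sin(theta_max)
    cap = _sample_cap(r, theta_max, z_center, grid, clathrin_density=1.0)
    plane = _sample_plane(extent, grid, hole_radius)
    parts = {k: np.concatenate([cap[k], plane[k]]) for k in cap}
    return MembraneSurface(grid=grid, extent=extent, **parts)


def make_class2_surface(
    area: float,
    r_i: float,
    grid: float = 2.0,
    extent: float = 2000.0,
) -> MembraneSurface:
    """Constant-area pit: spherical cap of curvature radius ``r_i`` whose area
    equals ``area``; cap height ``z_shift = area / (2 pi r_i)``. Clathrin is
    uniform on the cap and absent from the surrounding plane."""
    if area <= 0 or r_i <= 0:
        raise InvalidStageError("area and r_i must be positive")
    z_shift = area / (2.0 * np.pi * r_i)
    if z_shift > 2.0 * r_i * (1 + 1e-9):
        raise GeometricOverclosureError(
            f"cap height {z_shift:.3f} nm exceeds sphere diameter {2 * r_i:.3f} nm"
        )
    cos_cut = np.clip(1.0 - z_shift / r_i, -1.0, 1.0)
    theta_c = float(np.arccos(cos_cut))
    center_z = z_shift - r_i  # apex sits at z = z_shift, base circle at z = 0
    hole_radius = r_i * np.sin(theta_c)
    cap = _sample_cap(r_i, theta_c, center_z, grid, clathrin_density=1.0)
    plane = _sample_plane(extent, grid, hole_radius)
    parts = {k: np.concatenate([cap[k], plane[k]]) for k in cap}
    return MembraneSurface(grid=grid, extent=extent, **parts)


def build_surface(state: PitState, grid: float = 2.0, extent: float = 2000.0) -> MembraneSurface:
    """Materialize the discretized surface for one pit stage."""
    if state.model == "class1_fixed_radius":
        return make_class1_surface(state.r, state.z_center, grid=grid, extent=extent)
    return make_class2_surface(state.area, state.r_i, grid=grid, extent=extent)


def stage_sequence(
    model: str,
    n_stages: int,
    r: float = 50.0,
    area: float | None = None,
    r_i_start: float = 25000.0,
) -> list[PitState]:
    """Discrete morphological progression from flat membrane to closed vesicle.

    Class 1 sweeps the sphere center linearly from ``-r`` to ``+r``. Class 2
    sweeps the curvature radius from ``r_i_start`` (essentially flat) down to
    the closed-sphere radius ``sqrt(area / 4 pi)``; stages are spaced linearly
    in cap height ``z_shift`` so the apex advances uniformly per stage, as in
    the class-1 sweep.
    """
    if n_stages < 2:
        raise InvalidStageError("need at least 2 stages")
    if model in ("class1", "class1_fixed_radius"):
        centers = np.linspace(-r, r, n_stages)
        return [
            PitState("class1_fixed_radius", k, r=r, z_center=float(zc))
            for k, zc in enumerate(centers)
        ]
    if model in ("class2", "class2_constant_area"):
        if area is None:
            area = 4.0 * np.pi * r * r  # full-sphere area of the default 50 nm vesicle
        r_end = float(np.sqrt(area / (4.0 * np.pi)))
        z_first = area / (2.0 * np.pi * r_i_start)
        z_last = 2.0 * r_end
        z_shifts = np.linspace(z_first, z_last, n_stages)
        return [
            PitState(
                "class2_constant_area",
                k,
                area=area,
                r_i=float(area / (2.0 * np.pi * zs)),
            )
            for k, zs in enumerate(z_shifts)
        ]
    raise InvalidStageError(f"unknown model {model!r}")


def total_area(surface: MembraneSurface, compartment: str) -> float:
    """Sum of element areas (nm^2) in one compartment ('plane' or 'sphere')."""
    if compartment not in _LABEL_CODES:
        raise ValueError(f"unknown compartment {compartment!r}")
    return float(surface.area[surface.compartment == _LABEL_CODES[compartment]].sum())


def cap_base_radius(r_i: float, z_shift: float) -> float:
    """Radius of a spherical cap's base circle: sqrt(h (2 r - h))."""
    return float(np.sqrt(max(0.0, z_shift * (2.0 * r_i - z_shift))))
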