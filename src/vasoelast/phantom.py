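"""Vessel phantoms: geometry, materials, and synthetic measurements.

A phantom is an annular (optionally intima-thickened) mouse-carotid
cross-section with region-wise Young's moduli, loaded by a uniform
luminal pressure.  This module generates the phantom mesh/material pair,
noisy "measured" displacement fields that stand in for tracking output,
and scatterer sets that feed the RF simulator.  Everything is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.tri import LinearTriInterpolator, Triangulation

from vasoelast.geometry import GeometryError, TriMesh, build_annulus_mesh
from vasoelast.fem import (
    DisplacementField,
    MaterialField,
    PressureLoad,
    solve_forward,
)


@dataclass
class IntimaSpec:
    """Inner (intimal) thickening of the phantom wall.

    ``angular_extent_deg = 360`` gives a concentric ring of uniform
    ``max_thickness_mm``; smaller extents give an eccentric crescent whose
    thickness tapers cosinusoidally to zero at the edges, centred at
    ``center_angle_deg``.
    """

    angular_extent_deg: float
    max_thickness_mm: float
    center_angle_deg: float = 0.0

    def thickness(self, theta: float) -> float:
        """Intima thickness at polar angle ``theta`` (radians), mm."""
        if self.angular_extent_deg >= 360.0:
            return self.max_thickness_mm
        half = math.radians(self.angular_extent_deg) / 2.0
        d = math.atan2(
            math.sin(theta - math.radians(self.center_angle_deg)),
            math.cos(theta - math.radians(self.center_angle_deg)),
        )
        if abs(d) >= half:
            return 0.0
        return self.max_thickness_mm * 0.5 * (1.0 + math.cos(math.pi * d / half))


@dataclass
class PhantomSpec:
    """Geometry, material and load of one synthetic vessel cross-section.

    Defaults reflect mouse-carotid scale: lumen radius ~0.19 mm, wall
    thickness ~0.11 mm, near-incompressible wall (``nu = 0.495``), and a
    luminal pressure of 131 mmHg.
    """

    inner_radius: float = 0.19       # mm
    outer_radius: float = 0.30       # mm
    intima_spec: IntimaSpec | None = None
    region_moduli: dict[str, float] = field(default_factory=lambda: {"wall": 18.0})
    poisson_ratio: float = 0.495
    lumen_pressure: float = 131.0    # mmHg
    mesh_density: float = 0.02       # target element edge, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise GeometryError(
                f"need 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius}, {self.outer_radius}"
            )
        for name, e in self.region_moduli.items():
            if not e > 0:
                raise ValueError(f"modulus of region {name!r} must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.intima_spec is not None:
            t = self.intima_spec.max_thickness_mm
            if not 0 < t < (self.outer_radius - self.inner_radius):
                raise GeometryError(
                    "intima thickness must lie strictly inside the wall"
                )


@dataclass
class ScattererSet:
    """Point scatterers with reflectivities, positions in mm."""

    positions: np.ndarray  # (K, 2) (axial, lateral) mm
    amplitudes: np.ndarray  # (K,)
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)


def make_phantom(spec: PhantomSpec) -> tuple[TriMesh, MaterialField]:
    """Mesh + material for a phantom spec.

    Concentric intima interfaces are mesh-conforming (a node ring sits
    exactly on the interface); eccentric crescents are labelled by element
    centroid.  Deterministic: identical specs give identical tables.
    """
    a, b = spec.inner_radius, spec.outer_radius
    if spec.intima_spec is None:
        mesh = build_annulus_mesh(a, b, spec.mesh_density)
        region_moduli = dict(spec.region_moduli)
        if set(region_moduli) != {"wall"}:
            # single-region phantom without intima must be labelled "wall"
            if len(region_moduli) == 1:
                (only_e,) = region_moduli.values()
                region_moduli = {"wall": only_e}
            else:
                raise ValueError(
                    "phantom without intima_spec must define a single 'wall' region"
                )
        return mesh, MaterialField(region_moduli, spec.poisson_ratio)

    ints = spec.intima_spec
    concentric = ints.angular_extent_deg >= 360.0

    def label(r: float, theta: float) -> str:
        return "intima" if r < a + ints.thickness(theta) else "media"

    mesh = build_annulus_mesh(
        a,
        b,
        spec.mesh_density,
        interface_radius=(a + ints.max_thickness_mm) if concentric else None,
        region_of_radius=label,
    )
    moduli = dict(spec.region_moduli)
    if "intima" not in moduli or "media" not in moduli:
        raise ValueError("phantom with intima_spec needs 'intima' and 'media' moduli")
    present = set(mesh.region_names())
    moduli = {k: v for k, v in moduli.items() if k in present}
    return mesh, MaterialField(moduli, spec.poisson_ratio)


def synth_displacement_measurement(
    mesh: TriMesh,
    material: MaterialField,
    pressure_mmhg: float,
    noise_sd_fraction: float,
    seed: int,
) -> DisplacementField:
    """FEM forward solution plus i.i.d. Gaussian noise, flagged "measured".

    The noise SD is ``noise_sd_fraction`` times the peak displacement
    magnitude of the clean field; a fraction of 0 returns the exact
    forward solution.  Stands in for echo-tracking output when the RF
    route is bypassed.
    """
    clean = solve_forward(mesh, material, PressureLoad(pressure_mmhg))
    vals = clean.values.copy()
    if noise_sd_fraction > 0:
        peak = float(np.max(np.hypot(vals[:, 0], vals[:, 1])))
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd_fraction * peak, size=vals.shape)
    return DisplacementField(vals, provenance="measured")


def scatter_and_warp(
    spec: PhantomSpec,
    mesh: TriMesh,
    field: DisplacementField,
    density_per_mm2: float = 4000.0,
    seed: int = 0,
) -> tuple[ScattererSet, ScattererSet]:
    """Uniform wall scatterers, before and after deformation.

    Pre-deformation positions are drawn uniformly over the wall annulus at
    the stated density; post-deformation positions add the displacement
    field linearly interpolated (on the mesh triangulation) at each
    scatterer.  Amplitudes (standard normal reflectivities) are preserved.
    Scatterers falling outside the interpolation support are dropped.
    """
    rng = np.random.default_rng(seed)
    a, b = spec.inner_radius, spec.outer_radius
    area = math.pi * (b**2 - a**2)
    n = rng.poisson(density_per_mm2 * area)
    # uniform in the annulus via inverse-CDF in r^2
    r = np.sqrt(rng.uniform(a**2, b**2, n))
    th = rng.uniform(0.0, 2 * math.pi, n)
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    amp = rng.normal(0.0, 1.0, n)

    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements)
    fx = LinearTriInterpolator(tri, field.values[:, 0])
    fy = LinearTriInterpolator(tri, field.values[:, 1])
    ux = fx(pos[:, 0], pos[:, 1])
    uy = fy(pos[:, 0], pos[:, 1])
    ok = ~(np.ma.getmaskarray(ux) | np.ma.getmaskarray(uy))
    n_drop = int((~ok).sum())
    if n_drop:
        import logging

        logging.getLogger(__name__).info(
            "scatter_and_warp: dropped %d/%d scatterers outside mesh support",
            n_drop,
            n,
        )
    pos = pos[ok]
    amp = amp[ok]
    disp = np.column_stack([np.ma.filled(ux, 0.0)[ok], np.ma.filled(uy, 0.0)[ok]])
    pre = ScattererSet(pos, amp, seed=seed)
    post = ScattererSet(pos + disp, amp.copy(), seed=seed)
    return pre, post
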