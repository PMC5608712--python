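"""Elastogram and histology-stack rendering.

Elastograms use the blue-to-red convention: the lowest modulus (zero)
maps to blue, the scale maximum (54 kPa by default) to red.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from vasoelast.geometry import TriMesh
from vasoelast.fem import MaterialField
from vasoelast.histology import COMPARTMENT_COLORS, COMPARTMENTS, SectionAreas, stacked_surface_model


def plot_elastogram(
    mesh: TriMesh,
    material: MaterialField,
    path,
    vmax: float = 54.0,
    title: str | None = None,
) -> None:
    """Render a per-element modulus map to PNG (deterministic output)."""
    e_elem = material.element_moduli(mesh)
    fig, ax = plt.subplots(figsize=(4, 4))
    tpc = ax.tripcolor(
        mesh.nodes[:, 1],
        -mesh.nodes[:, 0],
        mesh.elements,
        facecolors=e_elem,
        cmap="jet",
        vmin=0.0,
        vmax=vmax,
    )
    fig.colorbar(tpc, ax=ax, label="Young's modulus (kPa)")
    ax.set_aspect("equal")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def plot_stacked_surface(areas: SectionAreas, path, cutaway: bool = False) -> None:
    """Stacked-disc 3D surface of the compartment radii along the artery."""
    radii = stacked_surface_model(areas)
    theta_max = 1.5 * np.pi if cutaway else 2 * np.pi
    theta = np.linspace(0.0, theta_max, 73)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="3d")
    Z = np.repeat(areas.stations_um[:, None], theta.size, axis=1)
    for k in reversed(range(len(COMPARTMENTS))):
        R = radii[:, [k]] * np.ones_like(theta)[None, :]
        ax.plot_surface(
            R * np.cos(theta)[None, :],
            R * np.sin(theta)[None, :],
            Z,
            color=COMPARTMENT_COLORS[COMPARTMENTS[k]],
            alpha=0.9,
            linewidth=0,
        )
    ax.set_zlabel("distance from bifurcation (um)")
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
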