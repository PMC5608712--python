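"""Triangulated annular vessel cross-sections.

The mesh is a structured triangulation of the annulus between the lumen
(inner) and adventitial (outer) surfaces, with per-element material-region
labels and ordered boundary edge loops.  A quadratic (6-node) node layer is
derived lazily for the finite-element solver; the public mesh exposes the
corner (vertex) nodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent mesh geometry."""


@dataclass
class TriMesh:
    """Triangulated annular cross-section.

    Parameters
    ----------
    nodes : (N, 2) float array
        Vertex coordinates, mm. Convention: column 0 is the axial (beam
        propagation) coordinate, column 1 the lateral coordinate.
    elements : (M, 3) int array
        Counter-clockwise vertex triples.
    region : (M,) str array
        Material-region label per element.
    inner_edges : (Ki, 2) int array
        Ordered, closed CCW loop of vertex pairs on the lumen boundary.
    outer_edges : (Ko, 2) int array
        Ordered, closed CCW loop on the adventitial surface.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    inner_edges: np.ndarray
    outer_edges: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region)
        self.inner_edges = np.asarray(self.inner_edges, dtype=np.int64)
        self.outer_edges = np.asarray(self.outer_edges, dtype=np.int64)

    # -- basic queries -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @cached_property
    def inner_nodes(self) -> np.ndarray:
        return np.unique(self.inner_edges)

    @cached_property
    def outer_nodes(self) -> np.ndarray:
        return np.unique(self.outer_edges)

    @cached_property
    def element_areas(self) -> np.ndarray:
        """Signed triangle areas (positive for CCW elements), mm^2."""
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    @cached_property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def region_names(self) -> list[str]:
        """Region labels in stable (first-appearance) order."""
        seen: list[str] = []
        for r in self.region:
            if r not in seen:
                seen.append(str(r))
        return seen

    def region_area(self, name: str) -> float:
        return float(self.element_areas[self.region == name].sum())

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if np.any(self.element_areas <= 0):
            bad = int(np.argmin(self.element_areas))
            raise GeometryError(
                f"element {bad} has non-positive signed area "
                f"{self.element_areas[bad]:.3e} mm^2"
            )
        for name, edges in (("inner", self.inner_edges), ("outer", self.outer_edges)):
            if not np.array_equal(np.roll(edges[:, 0], -1), edges[:, 1]):
                raise GeometryError(f"{name} boundary edges do not form a single closed loop")
        if np.intersect1d(self.inner_nodes, self.outer_nodes).size:
            raise GeometryError("inner and outer boundaries share nodes")


@dataclass
class QuadraticSpace:
    """Six-node (quadratic) layer over a :class:`TriMesh`.

    ``all_nodes`` lists the corner nodes first (in mesh order) followed by
    one midside node per unique edge; ``elements6`` follows the usual
    convention (corners 0-2, then midsides opposite... along edges 0-1,
    1-2, 2-0).
    """

    mesh: TriMesh
    all_nodes: np.ndarray = field(init=False)
    elements6: np.ndarray = field(init=False)
    inner_edge_mid: np.ndarray = field(init=False)
    outer_edge_mid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tri = self.mesh.elements
        edges = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        key = np.sort(edges, axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        n_c = self.mesh.n_nodes
        mid = 0.5 * (self.mesh.nodes[uniq[:, 0]] + self.mesh.nodes[uniq[:, 1]])
        self.all_nodes = np.vstack([self.mesh.nodes, mid])
        m = tri.shape[0]
        e01 = n_c + inv[:m]
        e12 = n_c + inv[m : 2 * m]
        e20 = n_c + inv[2 * m :]
        self.elements6 = np.column_stack([tri, e01, e12, e20])

        def _mid_ids(boundary_edges: np.ndarray) -> np.ndarray:
            bkey = np.sort(boundary_edges, axis=1)
            # locate each boundary edge in the unique-edge table
            order = np.lexsort((uniq[:, 1], uniq[:, 0]))
            srt = uniq[order]
            idx = np.searchsorted(
                srt[:, 0] * (srt[:, 1].max() + 1) + srt[:, 1],
                bkey[:, 0] * (srt[:, 1].max() + 1) + bkey[:, 1],
            )
            return n_c + order[idx]

        self.inner_edge_mid = _mid_ids(self.mesh.inner_edges)
        self.outer_edge_mid = _mid_ids(self.mesh.outer_edges)
        # pull boundary midside nodes onto the circular arc through their
        # edge endpoints (better geometric fidelity of the pressure load)
        for edges_, mids in (
            (self.mesh.inner_edges, self.inner_edge_mid),
            (self.mesh.outer_edges, self.outer_edge_mid),
        ):
            ra = np.linalg.norm(self.all_nodes[edges_[:, 0]], axis=1)
            rb = np.linalg.norm(self.all_nodes[edges_[:, 1]], axis=1)
            target = 0.5 * (ra + rb)
            cur = self.all_nodes[mids]
            nrm = np.linalg.norm(cur, axis=1)
            good = nrm > 0
            self.all_nodes[mids[good]] = cur[good] * (target[good] / nrm[good])[:, None]

    @property
    def n_nodes(self) -> int:
        return self.all_nodes.shape[0]

    @cached_property
    def outer_node_ids(self) -> np.ndarray:
        return np.unique(np.concatenate([self.mesh.outer_nodes, self.outer_edge_mid]))

    @cached_property
    def inner_node_ids(self) -> np.ndarray:
        return np.unique(np.concatenate([self.mesh.inner_nodes, self.inner_edge_mid]))


_SPACE_CACHE: dict[int, QuadraticSpace] = {}


def quadratic_space(mesh: TriMesh) -> QuadraticSpace:
    """Quadratic node layer for ``mesh`` (memoized per mesh object)."""
    key = id(mesh)
    sp = _SPACE_CACHE.get(key)
    if sp is None or sp.mesh is not mesh:
        sp = QuadraticSpace(mesh)
        if len(_SPACE_CACHE) > 32:
            _SPACE_CACHE.clear()
        _SPACE_CACHE[key] = sp
    return sp


def build_annulus_mesh(
    inner_radius: float,
    outer_radius: float,
    edge_length: float,
    interface_radius: float | None = None,
    region_of_radius=None,
) -> TriMesh:
    """Structured triangulation of an annulus centred at the origin.

    Parameters
    ----------
    inner_radius, outer_radius : float
        Lumen and adventitial radii, mm.
    edge_length : float
        Target element edge length, mm.
    interface_radius : float, optional
        If given, a node ring is placed exactly at this radius so a
        concentric material interface is mesh-conforming.
    region_of_radius : callable, optional
        ``f(r, theta) -> str`` mapping element centroids to region labels.
        Defaults to labelling everything ``"wall"``.

    Fully deterministic: identical arguments give identical node and
    element tables.
    """
    a, b = float(inner_radius), float(outer_radius)
    if not 0 < a < b:
        raise GeometryError(f"need 0 < inner_radius < outer_radius, got {a}, {b}")
    h = float(edge_length)
    if h <= 0:
        raise GeometryError("edge_length must be positive")

    if interface_radius is not None:
        c = float(interface_radius)
        if not a < c < b:
            raise GeometryError("interface_radius must lie strictly inside the wall")
        n1 = max(1, round((c - a) / h))
        n2 = max(1, round((b - c) / h))
        radii = np.concatenate([np.linspace(a, c, n1 + 1), np.linspace(c, b, n2 + 1)[1:]])
    else:
        nr = max(2, round((b - a) / h))
        radii = np.linspace(a, b, nr + 1)

    n_t = max(12, int(round(2 * np.pi * 0.5 * (a + b) / h)))
    theta = np.arange(n_t) * (2 * np.pi / n_t)

    n_r = radii.size
    nodes = np.empty((n_r * n_t, 2))
    for i, r in enumerate(radii):
        nodes[i * n_t : (i + 1) * n_t, 0] = r * np.cos(theta)
        nodes[i * n_t : (i + 1) * n_t, 1] = r * np.sin(theta)

    tris = []
    for i in range(n_r - 1):
        for j in range(n_t):
            jp = (j + 1) % n_t
            n00 = i * n_t + j
            n01 = i * n_t + jp
            n10 = (i + 1) * n_t + j
            n11 = (i + 1) * n_t + jp
            tris.append((n00, n10, n11))
            tris.append((n00, n11, n01))
    elements = np.asarray(tris, dtype=np.int64)

    # enforce positive (CCW) orientation
    p = nodes[elements]
    s = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = s < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    cent = nodes[elements].mean(axis=1)
    if region_of_radius is None:
        region = np.full(elements.shape[0], "wall", dtype="U16")
    else:
        rc = np.hypot(cent[:, 0], cent[:, 1])
        tc = np.arctan2(cent[:, 1], cent[:, 0])
        region = np.array(
            [region_of_radius(r, t) for r, t in zip(rc, tc)], dtype="U16"
        )

    inner = np.array([[j, (j + 1) % n_t] for j in range(n_t)], dtype=np.int64)
    off = (n_r - 1) * n_t
    outer = np.array([[off + j, off + (j + 1) % n_t] for j in range(n_t)], dtype=np.int64)

    mesh = TriMesh(nodes, elements, region, inner, outer)
    mesh.validate()
    return mesh
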