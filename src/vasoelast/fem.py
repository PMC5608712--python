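"""Plane-strain linear elasticity on a vessel cross-section.

Forward model for the modulus inverse problem: a linear, isotropic,
nearly incompressible (``nu = 0.495``) wall loaded by a uniform luminal
pressure, optionally with measured displacements imposed as Dirichlet
data on the outer boundary.  Discretization uses isoparametric 6-node
(quadratic) triangles, which do not lock at near-incompressible Poisson
ratios; the 3-node constant-strain triangle is retained only as a
textbook reference element for unit testing.

The closed-form Lamé solution for a pressurized thick-walled cylinder is
provided as the independent accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from vasoelast.geometry import TriMesh, QuadraticSpace, quadratic_space
from vasoelast.units import mmhg_to_kpa


class AssemblyError(ValueError):
    """Raised when a degenerate element prevents stiffness assembly."""


class SolverError(RuntimeError):
    """Raised when the constrained linear system cannot be solved."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class MaterialField:
    """Region-wise Young's modulus map plus a global Poisson ratio.

    ``region_moduli`` maps region label -> E in kPa; the element-to-region
    assignment lives on the mesh.
    """

    region_moduli: dict[str, float]
    poisson_ratio: float = 0.495

    def __post_init__(self) -> None:
        for name, e in self.region_moduli.items():
            if not e > 0:
                raise ValueError(f"region {name!r}: Young's modulus must be > 0, got {e}")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"Poisson ratio must be in [0, 0.5), got {self.poisson_ratio}")

    def modulus_vector(self, region_names: list[str]) -> np.ndarray:
        return np.array([self.region_moduli[r] for r in region_names], dtype=float)

    def element_moduli(self, mesh: TriMesh) -> np.ndarray:
        lut = {r: e for r, e in self.region_moduli.items()}
        return np.array([lut[str(r)] for r in mesh.region], dtype=float)

    def scaled(self, factor: float) -> "MaterialField":
        return MaterialField(
            {r: e * factor for r, e in self.region_moduli.items()}, self.poisson_ratio
        )


@dataclass
class PressureLoad:
    """Uniform luminal pressure, mmHg, applied as inward-normal traction
    on the inner boundary (pushing the wall outward)."""

    lumen_pressure_mmhg: float

    def __post_init__(self) -> None:
        if self.lumen_pressure_mmhg < 0:
            raise ValueError("lumen pressure must be >= 0")

    @property
    def kpa(self) -> float:
        return mmhg_to_kpa(self.lumen_pressure_mmhg)


@dataclass
class DisplacementField:
    """Per-corner-node (axial, lateral) displacements in mm.

    ``provenance`` distinguishes tracked ("measured") from model-computed
    ("computed") fields.  ``mask`` optionally marks nodes whose values were
    filled rather than measured.
    """

    values: np.ndarray  # (N, 2) mm
    provenance: str = "computed"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("displacement values must have shape (N, 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class DirichletBC:
    """Prescribed displacements on the outer-boundary corner nodes."""

    node_ids: np.ndarray
    values: np.ndarray  # (K, 2) mm

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.node_ids.shape[0] != self.values.shape[0]:
            raise ValueError("node_ids and values length mismatch")

    @classmethod
    def zero(cls, mesh: TriMesh) -> "DirichletBC":
        ids = mesh.outer_nodes
        return cls(ids, np.zeros((ids.size, 2)))

    @classmethod
    def from_field(cls, field: DisplacementField, mesh: TriMesh) -> "DirichletBC":
        ids = mesh.outer_nodes
        return cls(ids, field.values[ids])

    def validate_cover(self, mesh: TriMesh) -> None:
        if not np.array_equal(np.sort(self.node_ids), mesh.outer_nodes):
            raise ValueError("Dirichlet data must cover every outer-boundary node exactly once")


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def plane_strain_d(nu: float) -> np.ndarray:
    """Plane-strain constitutive matrix for unit Young's modulus."""
    c = 1.0 / ((1 + nu) * (1 - 2 * nu))
    return c * np.array(
        [[1 - nu, nu, 0.0], [nu, 1 - nu, 0.0], [0.0, 0.0, 0.5 * (1 - 2 * nu)]]
    )


def cst_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Stiffness of a single 3-node constant-strain triangle (plane strain).

    Textbook reference element; production solves use quadratic triangles.
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[:, 0], coords[:, 1]
    area2 = (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
    if area2 <= 0:
        raise AssemblyError("CST element is degenerate or clockwise")
    b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]]) / area2
    c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]]) / area2
    B = np.zeros((3, 6))
    B[0, 0::2] = b
    B[1, 1::2] = c
    B[2, 0::2] = c
    B[2, 1::2] = b
    D = E * plane_strain_d(nu)
    return 0.5 * area2 * B.T @ D @ B


# 6-point, degree-4 quadrature on the reference triangle (weights sum to 1/2)
_QP = np.array(
    [
        [0.445948490915965, 0.445948490915965],
        [0.445948490915965, 0.108103018168070],
        [0.108103018168070, 0.445948490915965],
        [0.091576213509771, 0.091576213509771],
        [0.091576213509771, 0.816847572980459],
        [0.816847572980459, 0.091576213509771],
    ]
)
_QW = np.array(
    [0.223381589678011] * 3 + [0.109951743655322] * 3
) * 0.5


def _shape_p2(xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """P2 shape functions and reference gradients at one point."""
    l1, l2, l3 = 1 - xi - eta, xi, eta
    N = np.array(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ]
    )
    dl = np.array([[-1, -1], [1, 0], [0, 1]], dtype=float)
    dN = np.vstack(
        [
            (4 * l1 - 1) * dl[0],
            (4 * l2 - 1) * dl[1],
            (4 * l3 - 1) * dl[2],
            4 * (l2 * dl[0] + l1 * dl[1]),
            4 * (l3 * dl[1] + l2 * dl[2]),
            4 * (l1 * dl[2] + l3 * dl[0]),
        ]
    )
    return N, dN


def _element_matrices_unit_e(space: QuadraticSpace, nu: float) -> np.ndarray:
    """(M, 12, 12) stiffness of every quadratic element at E = 1."""
    conn = space.elements6
    xy = space.all_nodes[conn]  # (M, 6, 2)
    M = conn.shape[0]
    D = plane_strain_d(nu)
    Ke = np.zeros((M, 12, 12))
    for (xi, eta), w in zip(_QP, _QW):
        _, dN = _shape_p2(xi, eta)  # (6, 2)
        J = np.einsum("mia,ib->mab", xy, dN)  # (M, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.argmin(detJ))
            raise AssemblyError(
                f"element {bad} has non-positive Jacobian at a quadrature point"
            )
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ /= detJ[:, None, None]
        g = np.einsum("ib,mba->mia", dN, invJ)  # (M, 6, 2) grad wrt x,y
        B = np.zeros((M, 3, 12))
        B[:, 0, 0::2] = g[:, :, 0]
        B[:, 1, 1::2] = g[:, :, 1]
        B[:, 2, 0::2] = g[:, :, 1]
        B[:, 2, 1::2] = g[:, :, 0]
        DB = np.einsum("ab,mbj->maj", D, B)
        Ke += w * detJ[:, None, None] * np.einsum("mai,maj->mij", B, DB)
    return Ke


def _dof_indices(conn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dofs = np.empty((conn.shape[0], 12), dtype=np.int64)
    dofs[:, 0::2] = 2 * conn
    dofs[:, 1::2] = 2 * conn + 1
    rows = np.repeat(dofs, 12, axis=1).reshape(-1)
    cols = np.tile(dofs, (1, 12)).reshape(-1)
    return rows, cols


def assemble_unit_stiffness(mesh: TriMesh, nu: float) -> dict[str, sp.csr_matrix]:
    """Per-region global stiffness blocks at unit Young's modulus.

    The full operator is ``K = sum_r E_r * K_r``; the blocks also supply
    the exact modulus sensitivities ``dK/dE_r = K_r``.
    """
    space = quadratic_space(mesh)
    Ke = _element_matrices_unit_e(space, nu)
    rows, cols = _dof_indices(space.elements6)
    rows = rows.reshape(mesh.n_elements, 144)
    cols = cols.reshape(mesh.n_elements, 144)
    n_dof = 2 * space.n_nodes
    blocks: dict[str, sp.csr_matrix] = {}
    for name in mesh.region_names():
        sel = mesh.region == name
        K = sp.coo_matrix(
            (Ke[sel].reshape(-1), (rows[sel].reshape(-1), cols[sel].reshape(-1))),
            shape=(n_dof, n_dof),
        ).tocsr()
        K.sum_duplicates()
        blocks[name] = K
    return blocks


def assemble_stiffness(mesh: TriMesh, material: MaterialField) -> sp.csr_matrix:
    """Global stiffness operator (symmetric PSD before constraints).

    Acts on interleaved quadratic nodal displacements ``[ux0, uy0, ...]``
    in kPa*mm units; entries scale linearly in each region's modulus.
    """
    blocks = assemble_unit_stiffness(mesh, material.poisson_ratio)
    K = None
    for name, Kr in blocks.items():
        term = material.region_moduli[str(name)] * Kr
        K = term if K is None else K + term
    return K.tocsr()


def pressure_load_vector(space: QuadraticSpace, p_kpa: float) -> np.ndarray:
    """Consistent nodal load of a uniform luminal pressure.

    Integrates ``p * n`` over each (curved) quadratic inner-boundary edge
    with 3-point Gauss; the normal points from the lumen into the wall.
    """
    n_dof = 2 * space.n_nodes
    f = np.zeros(n_dof)
    if p_kpa == 0:
        return f
    gauss_x = np.array([0.5 - np.sqrt(0.15), 0.5, 0.5 + np.sqrt(0.15)])
    gauss_w = np.array([5 / 18, 8 / 18, 5 / 18])
    edges = space.mesh.inner_edges
    mids = space.inner_edge_mid
    for (n0, n1), nm in zip(edges, mids):
        xy = space.all_nodes[[n0, n1, nm]]  # endpoints then midside
        ctr = xy.mean(axis=0)
        for xi, w in zip(gauss_x, gauss_w):
            N = np.array([2 * (xi - 0.5) * (xi - 1), 2 * xi * (xi - 0.5), 4 * xi * (1 - xi)])
            dN = np.array([4 * xi - 3, 4 * xi - 1, 4 - 8 * xi])
            tangent = dN @ xy  # dx/dxi, length absorbs |J|
            normal = np.array([tangent[1], -tangent[0]])
            # orient away from the lumen centre (outward radial push)
            if normal @ ctr < 0:
                normal = -normal
            for k, node in enumerate((n0, n1, nm)):
                f[2 * node : 2 * node + 2] += w * p_kpa * N[k] * normal
    return f


def rigid_body_modes(space: QuadraticSpace) -> np.ndarray:
    """(2n, 3) basis of in-plane rigid translations and rotation."""
    xy = space.all_nodes - space.all_nodes.mean(axis=0)
    n = space.n_nodes
    R = np.zeros((2 * n, 3))
    R[0::2, 0] = 1.0
    R[1::2, 1] = 1.0
    R[0::2, 2] = -xy[:, 1]
    R[1::2, 2] = xy[:, 0]
    return R / np.linalg.norm(R, axis=0)


# ---------------------------------------------------------------------------
# forward solver
# ---------------------------------------------------------------------------

@dataclass
class ForwardSolution:
    """Full quadratic-space solution plus the reusable factorization."""

    u_full: np.ndarray          # (2 n_p2,) interleaved displacements, mm
    lu: spla.SuperLU
    free: np.ndarray | None     # free dof ids (Dirichlet case) or None
    n_dof: int
    saddle: bool                # True when rigid-mode multipliers are appended

    def solve_adjoint(self, rhs_full: np.ndarray) -> np.ndarray:
        """Solve K du = rhs under the same constraints; returns full vector."""
        if self.free is not None:
            du = np.zeros(self.n_dof)
            du[self.free] = self.lu.solve(rhs_full[self.free])
            return du
        ext = np.concatenate([rhs_full, np.zeros(3)])
        return self.lu.solve(ext)[: self.n_dof]


class ForwardModel:
    """Cached assembly + factorization machinery for one mesh/load/BC setup.

    Reused across Gauss-Newton iterations and sensitivity columns.
    """

    def __init__(
        self,
        mesh: TriMesh,
        poisson_ratio: float,
        load: PressureLoad,
        bc: DirichletBC | None = None,
    ) -> None:
        self.mesh = mesh
        self.nu = float(poisson_ratio)
        self.load = load
        self.bc = bc
        self.space = quadratic_space(mesh)
        self.blocks = assemble_unit_stiffness(mesh, self.nu)
        self.region_names = list(self.blocks.keys())
        self.f_pressure = pressure_load_vector(self.space, load.kpa)
        self.n_dof = 2 * self.space.n_nodes
        if bc is not None:
            bc.validate_cover(mesh)
            self._u_fixed, self._fixed, self._free = self._expand_bc(bc)
        else:
            self._R = rigid_body_modes(self.space)

    def _expand_bc(self, bc: DirichletBC):
        space = self.space
        vals = np.zeros((space.n_nodes, 2))
        vals[bc.node_ids] = bc.values
        # outer midside nodes take the mean of their edge endpoints
        for (n0, n1), nm in zip(self.mesh.outer_edges, space.outer_edge_mid):
            vals[nm] = 0.5 * (vals[n0] + vals[n1])
        fixed_nodes = space.outer_node_ids
        fixed = np.sort(np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1]))
        free = np.setdiff1d(np.arange(self.n_dof), fixed)
        return vals.reshape(-1), fixed, free

    @property
    def free_dofs(self) -> np.ndarray | None:
        return getattr(self, "_free", None)

    def stiffness(self, moduli: dict[str, float]) -> sp.csr_matrix:
        K = None
        for name, Kr in self.blocks.items():
            term = moduli[name] * Kr
            K = term if K is None else K + term
        return K.tocsr()

    def solve(self, moduli: dict[str, float]) -> ForwardSolution:
        K = self.stiffness(moduli)
        if self.bc is not None:
            Kc = K.tocsc()
            free = self._free
            Kff = Kc[free][:, free]
            rhs = self.f_pressure[free] - (Kc[free] @ self._u_fixed)
            try:
                lu = spla.splu(Kff.tocsc())
            except RuntimeError as exc:  # pragma: no cover
                raise SolverError(f"stiffness factorization failed: {exc}") from exc
            u = self._u_fixed.copy()
            u[free] = lu.solve(rhs)
            sol = ForwardSolution(u, lu, free, self.n_dof, saddle=False)
            resid = np.linalg.norm(Kff @ u[free] - rhs)
            scale = max(np.linalg.norm(rhs), 1e-30)
        else:
            R = self._R
            A = sp.bmat([[K, sp.csr_matrix(R)], [sp.csr_matrix(R.T), None]], format="csc")
            try:
                lu = spla.splu(A)
            except RuntimeError as exc:
                raise SolverError(
                    "singular system: no Dirichlet data and rigid-mode "
                    f"constraints failed ({exc})"
                ) from exc
            ext = np.concatenate([self.f_pressure, np.zeros(3)])
            x = lu.solve(ext)
            u = x[: self.n_dof]
            sol = ForwardSolution(u, lu, None, self.n_dof, saddle=True)
            resid = np.linalg.norm(K @ u + R @ x[self.n_dof :] - self.f_pressure)
            scale = max(np.linalg.norm(self.f_pressure), 1e-30)
        if resid / scale > 1e-8:
            raise SolverError(f"linear solve residual {resid / scale:.2e} exceeds 1e-8")
        return sol

    def corner_field(self, sol: ForwardSolution) -> DisplacementField:
        vals = sol.u_full.reshape(-1, 2)[: self.mesh.n_nodes]
        return DisplacementField(vals.copy(), provenance="computed")


def solve_forward(
    mesh: TriMesh,
    material: MaterialField,
    load: PressureLoad,
    bc: DirichletBC | None = None,
) -> DisplacementField:
    """Displacement of the pressurized cross-section (model side of the misfit).

    With ``bc`` given, tracked displacements are imposed on the outer
    boundary; otherwise the three in-plane rigid-body modes are removed by
    orthogonality constraints (appropriate for the self-equilibrated
    pressure load), leaving the elastic field unchanged.
    """
    model = ForwardModel(mesh, material.poisson_ratio, load, bc)
    sol = model.solve({r: float(e) for r, e in material.region_moduli.items()})
    return model.corner_field(sol)


def lame_radial_displacement(
    a: float, b: float, E: float, nu: float, p_mmhg: float, r
) -> np.ndarray:
    """Plane-strain thick-walled-cylinder radial displacement, mm.

    Internal pressure ``p`` (mmHg), traction-free outer surface:

        u(r) = (1 + nu)/E * [(1 - 2 nu) A r + B / r],
        A = p a^2 / (b^2 - a^2),  B = A b^2.

    The closed-form oracle used to validate the finite-element solver.
    """
    if not a < b:
        raise ValueError(f"need a < b, got a={a}, b={b}")
    r = np.asarray(r, dtype=float)
    if np.any(r < a * (1 - 1e-9)) or np.any(r > b * (1 + 1e-9)):
        raise ValueError("r outside the wall [a, b]")
    p = mmhg_to_kpa(p_mmhg)
    A = p * a**2 / (b**2 - a**2)
    B = A * b**2
    return (1 + nu) / E * ((1 - 2 * nu) * A * r + B / r)


def interior_displacement_extract(field: DisplacementField, mesh: TriMesh) -> np.ndarray:
    """Flattened displacements at all non-outer-boundary corner nodes.

    Defines the entries that enter the data misfit when outer-boundary
    Dirichlet data are imposed (boundary entries then carry no information).
    Ordered by node index, (axial, lateral) interleaved.
    """
    keep = np.setdiff1d(np.arange(mesh.n_nodes), mesh.outer_nodes)
    return field.values[keep].reshape(-1)


def interior_displacement_insert(
    vec: np.ndarray, mesh: TriMesh, boundary_values: np.ndarray | None = None
) -> DisplacementField:
    """Inverse of :func:`interior_displacement_extract` (round-trip exact)."""
    keep = np.setdiff1d(np.arange(mesh.n_nodes), mesh.outer_nodes)
    vals = np.zeros((mesh.n_nodes, 2))
    vals[keep] = np.asarray(vec, dtype=float).reshape(-1, 2)
    if boundary_values is not None:
        vals[mesh.outer_nodes] = boundary_values
    return DisplacementField(vals)
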