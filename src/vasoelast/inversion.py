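"""Regularized Gauss-Newton reconstruction of the Young's modulus map.

The elastogram is the minimizer of the Tikhonov objective

    pi(E) = 1/2 ||U(E) - U_m||^2 + alpha/2 ||E||^2

where ``U(E)`` is the plane-strain FEM forward solution under the assumed
luminal pressure (plus tracked Dirichlet data on the outer boundary, when
available) and ``U_m`` the measured displacements.  Each iteration solves
the regularized normal equations

    [J^T J + alpha I] dE = J^T (U_m - U) - alpha E

with the sensitivity matrix J assembled column-wise from the exact
derivative ``dU/dE_k = -K^{-1} (K_k / E_k) U``, reusing the stiffness
factorization across columns; steps are damped by backtracking so the
objective never increases on accepted iterations, and moduli are projected
onto bounds after each update.  All reconstructions start from a
homogeneous 20 kPa trial solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from vasoelast.geometry import TriMesh
from vasoelast.fem import (
    DirichletBC,
    DisplacementField,
    ForwardModel,
    MaterialField,
    PressureLoad,
    interior_displacement_extract,
)


@dataclass
class InversionConfig:
    """Gauss-Newton settings.

    ``alpha`` is dimensionless: it is rescaled internally by
    ``trace(J^T J)/n_params`` at the first iteration, so the same value is
    meaningful across mesh densities and pressures.
    """

    alpha: float = 1e-3
    trial_modulus: float = 20.0          # kPa, homogeneous starting field
    max_iterations: int = 50
    rel_objective_tol: float = 1e-6
    modulus_bounds: tuple[float, float] = (0.1, 1e3)   # kPa
    max_backtracks: int = 25
    rel_step_tol: float = 1e-9
    poisson_ratio: float = 0.495
    #: fit the axial displacement component only — appropriate when U_m
    #: comes from RF tracking, whose lateral estimates are far noisier
    axial_only: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        lo, hi = self.modulus_bounds
        if not lo < self.trial_modulus < hi:
            raise ValueError("trial modulus must lie within bounds")
        if not self.rel_objective_tol > 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class SensitivityMatrix:
    """d(misfit displacement entries)/d(region modulus), one column per region."""

    matrix: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("sensitivity matrix has non-finite entries")
        if self.matrix.shape[1] != len(self.region_names):
            raise ValueError("column count must equal number of parameter regions")


@dataclass
class InversionResult:
    """Reconstruction output with the full optimization trajectory."""

    material: MaterialField
    objective_trajectory: list[float]
    step_norms: list[float]
    status: str                  # "converged" | "max_iter" | "stalled"
    iterations: int
    region_names: list[str] = field(default_factory=list)

    def modulus(self, region: str) -> float:
        return self.material.region_moduli[region]


def _misfit_entries(
    field_vals: DisplacementField, mesh: TriMesh, has_bc: bool, axial_only: bool = False
) -> np.ndarray:
    """Misfit vector: interior nodes when Dirichlet data are imposed
    (boundary entries carry no information then), all nodes otherwise."""
    if has_bc:
        v = interior_displacement_extract(field_vals, mesh)
    else:
        v = field_vals.values.reshape(-1)
    return v[0::2] if axial_only else v


def _misfit_dofs(mesh: TriMesh, has_bc: bool, axial_only: bool = False) -> np.ndarray:
    if has_bc:
        keep = np.setdiff1d(np.arange(mesh.n_nodes), mesh.outer_nodes)
    else:
        keep = np.arange(mesh.n_nodes)
    if axial_only:
        return 2 * keep
    return np.column_stack([2 * keep, 2 * keep + 1]).reshape(-1)


def objective(
    material: MaterialField,
    u_m: DisplacementField,
    mesh: TriMesh,
    load: PressureLoad,
    bc: DirichletBC | None = None,
    alpha: float = 0.0,
    _model: ForwardModel | None = None,
) -> float:
    """Tikhonov data-misfit objective pi(E); always >= 0.

    ``alpha`` here is the raw (already scaled) regularization weight
    multiplying ``||E||^2 / 2`` over the region-modulus vector.
    """
    model = _model or ForwardModel(mesh, material.poisson_ratio, load, bc)
    sol = model.solve({r: float(e) for r, e in material.region_moduli.items()})
    u = model.corner_field(sol)
    r = _misfit_entries(u, mesh, bc is not None) - _misfit_entries(u_m, mesh, bc is not None)
    e_vec = material.modulus_vector(model.region_names)
    return 0.5 * float(r @ r) + 0.5 * alpha * float(e_vec @ e_vec)


def compute_sensitivity(
    material: MaterialField,
    mesh: TriMesh,
    load: PressureLoad,
    bc: DirichletBC | None = None,
    axial_only: bool = False,
    _model: ForwardModel | None = None,
    _sol=None,
) -> SensitivityMatrix:
    """Exact Jacobian of the misfit displacements w.r.t. region moduli.

    Column k is ``-K^{-1} (dK/dE_k) U`` restricted to misfit entries, with
    ``dK/dE_k = K_k / E_k`` the unit-modulus assembly of region k; the
    stiffness factorization is computed once and reused for every column.
    """
    model = _model or ForwardModel(mesh, material.poisson_ratio, load, bc)
    moduli = {r: float(e) for r, e in material.region_moduli.items()}
    sol = _sol or model.solve(moduli)
    dofs = _misfit_dofs(mesh, bc is not None, axial_only)
    cols = []
    for name in model.region_names:
        Kr = model.blocks[name]
        n_elem = int((mesh.region == name).sum())
        if n_elem == 0:
            import warnings

            warnings.warn(f"region {name!r} has no elements; zero sensitivity column")
            cols.append(np.zeros(dofs.size))
            continue
        rhs = -(Kr @ sol.u_full)
        du_full = sol.solve_adjoint(rhs)
        cols.append(du_full[dofs])
    J = np.column_stack(cols)
    return SensitivityMatrix(J, list(model.region_names))


def gauss_newton_step(
    J: SensitivityMatrix | np.ndarray,
    residual: np.ndarray,
    alpha: float,
    modulus: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Solve the regularized normal equations for the modulus update.

    Returns ``dE = [J^T J + alpha I]^{-1} (J^T r - alpha E)`` (the
    ``-alpha E`` term only when ``modulus`` is supplied, making the step
    the exact Gauss-Newton direction of the Tikhonov objective) together
    with a conditioning diagnostic of the normal matrix.
    """
    Jm = J.matrix if isinstance(J, SensitivityMatrix) else np.asarray(J, dtype=float)
    if not np.all(np.isfinite(Jm)):
        raise ValueError("sensitivity matrix must be finite")
    M = Jm.T @ Jm + alpha * np.eye(Jm.shape[1])
    rhs = Jm.T @ np.asarray(residual, dtype=float)
    if modulus is not None:
        rhs = rhs - alpha * np.asarray(modulus, dtype=float)
    cond = float(np.linalg.cond(M))
    try:
        c, low = sla.cho_factor(M)
        step = sla.cho_solve((c, low), rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are numerically singular; increase alpha > 0"
        ) from exc
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal equations are numerically singular; increase alpha > 0"
        ) from exc
    return step, cond


def reconstruct(
    u_m: DisplacementField,
    mesh: TriMesh,
    load: PressureLoad,
    bc: DirichletBC | None = None,
    config: InversionConfig | None = None,
) -> InversionResult:
    """Iterative regularized Gauss-Newton modulus reconstruction.

    Starts from a homogeneous trial field (default 20 kPa) over the mesh's
    parameter regions, iterates damped Gauss-Newton steps with bound
    projection until the relative objective change drops below tolerance
    or the iteration budget is exhausted.  The objective is non-increasing
    across accepted iterations (backtracking halves the step otherwise);
    the full trajectory is recorded in the result.
    """
    config = config or InversionConfig()
    model = ForwardModel(mesh, config.poisson_ratio, load, bc)
    names = model.region_names
    lo, hi = config.modulus_bounds
    E = np.full(len(names), float(config.trial_modulus))
    has_bc = bc is not None
    um_vec = _misfit_entries(u_m, mesh, has_bc, config.axial_only)

    def forward(Evec):
        mod = dict(zip(names, (float(v) for v in Evec)))
        sol = model.solve(mod)
        u = model.corner_field(sol)
        return sol, _misfit_entries(u, mesh, has_bc, config.axial_only)

    def pi_of(Evec, resid, alpha_eff):
        return 0.5 * float(resid @ resid) + 0.5 * alpha_eff * float(Evec @ Evec)

    sol, u_vec = forward(E)
    resid = um_vec - u_vec
    alpha_eff: float | None = None
    trajectory: list[float] = []
    step_norms: list[float] = []
    status = "max_iter"
    it = 0
    for it in range(1, config.max_iterations + 1):
        mat = MaterialField(dict(zip(names, E)), config.poisson_ratio)
        J = compute_sensitivity(
            mat, mesh, load, bc, axial_only=config.axial_only, _model=model, _sol=sol
        )
        if alpha_eff is None:
            scale = np.trace(J.matrix.T @ J.matrix) / max(len(names), 1)
            alpha_eff = config.alpha * float(scale)
            trajectory.append(pi_of(E, resid, alpha_eff))
        step, _cond = gauss_newton_step(J, resid, alpha_eff, modulus=E)
        pi_cur = trajectory[-1]
        t = 1.0
        accepted = False
        last_pi = pi_cur
        for _ in range(config.max_backtracks + 1):
            E_new = np.clip(E + t * step, lo, hi)
            sol_new, u_new = forward(E_new)
            resid_new = um_vec - u_new
            last_pi = pi_of(E_new, resid_new, alpha_eff)
            if last_pi <= pi_cur:
                accepted = True
                break
            t *= 0.5
        tiny_step = np.linalg.norm(np.clip(E + step, lo, hi) - E) <= (
            config.rel_step_tol * max(float(np.linalg.norm(E)), 1e-30)
        )
        if not accepted:
            if tiny_step or abs(last_pi - pi_cur) <= config.rel_objective_tol * max(
                pi_cur, 1e-300
            ):
                status = "converged"
            else:
                status = "stalled"
            break
        step_norms.append(float(np.linalg.norm(E_new - E)))
        E, sol, resid = E_new, sol_new, resid_new
        trajectory.append(last_pi)
        if tiny_step or abs(pi_cur - last_pi) <= config.rel_objective_tol * max(
            pi_cur, 1e-300
        ):
            status = "converged"
            break

    material = MaterialField(dict(zip(names, (float(v) for v in E))), config.poisson_ratio)
    return InversionResult(
        material=material,
        objective_trajectory=trajectory,
        step_norms=step_norms,
        status=status,
        iterations=it,
        region_names=list(names),
    )


def mean_wall_modulus(
    result: InversionResult | MaterialField,
    mesh: TriMesh,
    regions: list[str] | None = None,
) -> float:
    """Element-area-weighted mean Young's modulus over selected regions (kPa)."""
    material = result.material if isinstance(result, InversionResult) else result
    if regions is None:
        regions = mesh.region_names()
    sel = np.isin(mesh.region, regions)
    if not sel.any():
        raise ValueError(f"mask selects no elements (regions={regions})")
    e_elem = material.element_moduli(mesh)[sel]
    w = mesh.element_areas[sel]
    return float((e_elem * w).sum() / w.sum())
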