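"""2D echo tracking: block matching of RF frame pairs.

Displacements are estimated per kernel by locating each 100 um x 25.4 um
RF kernel of the pre-deformation frame inside a search region of the
post-deformation frame via zero-mean normalized cross-correlation, on a
station grid with 80% kernel overlap in both dimensions.  The integer
peak is refined to subpixel precision by a separable parabolic (or,
optionally, cosine) fit.  Tracked grids are interpolated onto the FEM
mesh to form the measured field U_m.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from vasoelast.geometry import TriMesh
from vasoelast.fem import DisplacementField
from vasoelast.rf import RFFrame

_VAR_EPS = 1e-12


class TrackingError(RuntimeError):
    """Raised when tracking cannot produce a usable displacement field."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TrackingConfig:
    """Block-matching geometry and search settings.

    Kernel size and overlap default to the 100 um x 25.4 um / 80% tracking
    geometry; the search range must cover the expected displacement.
    """

    kernel_axial_um: float = 100.0
    kernel_lateral_um: float = 25.4
    overlap_fraction: float = 0.80
    search_axial_samples: int = 10
    search_lateral_beams: int = 2
    #: axial default is a cosine fit at the known RF carrier frequency —
    #: a 3-point parabola on the oscillatory axial correlation carries a
    #: model-mismatch bias that the carrier-matched fit does not
    subpixel_axial: str = "cosine"
    subpixel_lateral: str = "parabolic"
    #: 3x3 median correction of integer peak lags before subpixel
    #: refinement; suppresses one-carrier-period peak hopping on RF data
    median_hop_correction: bool = True
    #: a peak on the search-range boundary means the search did not
    #: bracket the true maximum; such stations are flagged invalid
    reject_edge_peaks: bool = True

    def __post_init__(self) -> None:
        if self.kernel_axial_um <= 0 or self.kernel_lateral_um <= 0:
            raise ValueError("kernel dimensions must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap fraction must be in [0, 1)")
        for m in (self.subpixel_axial, self.subpixel_lateral):
            if m not in ("parabolic", "cosine"):
                raise ValueError(f"unknown subpixel method {m!r}")

    @property
    def step_axial_um(self) -> float:
        return self.kernel_axial_um * (1 - self.overlap_fraction)

    @property
    def step_lateral_um(self) -> float:
        return self.kernel_lateral_um * (1 - self.overlap_fraction)


@dataclass
class DisplacementGrid:
    """Tracked displacements on a regular station grid (um), with the
    peak normalized-correlation value per station (NaN where invalid)."""

    axial_stations_um: np.ndarray
    lateral_stations_um: np.ndarray
    u_axial_um: np.ndarray
    u_lateral_um: np.ndarray
    correlation: np.ndarray
    kernel_samples: tuple[int, int] = (0, 0)  # (axial, lateral), metadata

    def __post_init__(self) -> None:
        shape = (self.axial_stations_um.size, self.lateral_stations_um.size)
        for name in ("u_axial_um", "u_lateral_um", "correlation"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape does not match the station grid")
        finite = self.correlation[np.isfinite(self.correlation)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("correlation values outside [-1, 1]")


def kernel_grid(config: TrackingConfig, geometry) -> tuple[np.ndarray, np.ndarray]:
    """Station centres (um) of the overlapping-kernel grid.

    Station spacing is ``kernel x (1 - overlap)`` per dimension; every
    kernel lies fully inside the frame.  Returns (axial, lateral) centre
    coordinate arrays.
    """
    extent_a = (geometry.n_axial - 1) * geometry.axial_step_um
    extent_l = (geometry.n_lateral - 1) * geometry.beam_pitch_um
    if extent_a < config.kernel_axial_um or extent_l < config.kernel_lateral_um:
        raise TrackingError("frame is smaller than one tracking kernel")
    n_a = int(np.floor((extent_a - config.kernel_axial_um) / config.step_axial_um)) + 1
    n_l = int(np.floor((extent_l - config.kernel_lateral_um) / config.step_lateral_um)) + 1
    first_a = geometry.axial_start_um + config.kernel_axial_um / 2
    first_l = geometry.lateral_start_um + config.kernel_lateral_um / 2
    return (
        first_a + np.arange(n_a) * config.step_axial_um,
        first_l + np.arange(n_l) * config.step_lateral_um,
    )


def _sat(img: np.ndarray) -> np.ndarray:
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(img, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s


def _window_sums(sat: np.ndarray, t: np.ndarray, l: np.ndarray, h: int, w: int) -> np.ndarray:
    return sat[t + h, l + w] - sat[t, l + w] - sat[t + h, l] + sat[t, l]


def _subpixel(
    rm: np.ndarray,
    r0: np.ndarray,
    rp: np.ndarray,
    method: str,
    omega: float | None = None,
) -> np.ndarray:
    """Separable 3-point peak interpolation, clamped to [-0.5, 0.5].

    ``cosine`` is exact for ``rho(tau) = cos(omega (tau - d))``; when the
    lag-domain carrier frequency ``omega`` (radians/sample) is known from
    the system geometry it is used directly, otherwise it is estimated
    from the three samples.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "parabolic":
            denom = rm - 2 * r0 + rp
            delta = np.where(np.abs(denom) > 1e-15, (rm - rp) / (2 * denom), 0.0)
        else:
            if omega is None:
                w = np.arccos(np.clip((rm + rp) / (2 * r0), -1.0, 1.0))
            else:
                w = np.full_like(np.asarray(r0, dtype=float), omega)
            ok = (np.abs(r0) > 1e-15) & (w > 1e-6)
            w_safe = np.where(ok, w, 1.0)
            delta = np.where(
                ok, np.arctan2(rp - rm, 2 * r0 * np.sin(w_safe)) / w_safe, 0.0
            )
    return np.clip(np.nan_to_num(delta), -0.5, 0.5)


def _median_correct(
    pk: np.ndarray, rho: np.ndarray, grid_shape: tuple[int, int], axis: int
) -> np.ndarray:
    """Snap outlier integer peak lags to the 3x3 neighbourhood median.

    A station whose integer lag differs from the local median by more
    than one sample is re-anchored at the median lag (displacement-field
    continuity), provided that lag was actually evaluated there.
    """
    n_lag = rho.shape[1 + axis]
    field = pk.reshape(grid_shape).astype(float)
    stack = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            stack.append(
                np.pad(field, 1, mode="edge")[
                    1 + di : 1 + di + grid_shape[0], 1 + dj : 1 + dj + grid_shape[1]
                ]
            )
    med = np.median(np.stack(stack), axis=0).reshape(-1)
    pk_new = pk.copy()
    outlier = np.abs(pk - med) > 1
    snapped = np.clip(np.round(med[outlier]).astype(int), 0, n_lag - 1)
    pk_new[outlier] = snapped
    return pk_new


def block_match(pre: RFFrame, post: RFFrame, config: TrackingConfig) -> DisplacementGrid:
    """Estimate the displacement grid between two congruent RF frames.

    Per station: displacement = argmax of zero-mean normalized
    cross-correlation over the integer search range, refined by a
    separable 3-point subpixel fit; the peak correlation is stored.
    Stations whose pre-frame kernel has zero variance are flagged invalid
    (NaN displacement and correlation).
    """
    if pre.samples.shape != post.samples.shape:
        raise TrackingError("frames are not congruent in geometry")
    g = pre.geometry
    dz, dx = g.axial_step_um, g.beam_pitch_um
    ka = max(2, _round_half_up(config.kernel_axial_um / dz))
    kl = max(1, _round_half_up(config.kernel_lateral_um / dx))
    z_st, x_st = kernel_grid(config, g)

    iz = np.round((z_st - g.axial_start_um) / dz).astype(int)
    ix = np.round((x_st - g.lateral_start_um) / dx).astype(int)
    tz = np.clip(iz - ka // 2, 0, g.n_axial - ka)
    tx = np.clip(ix - kl // 2, 0, g.n_lateral - kl)
    TZ, TX = np.meshgrid(tz, tx, indexing="ij")
    n_st = TZ.size
    tzf, txf = TZ.reshape(-1), TX.reshape(-1)

    A, L = config.search_axial_samples, config.search_lateral_beams
    lags_a = np.arange(-A, A + 1)
    lags_l = np.arange(-L, L + 1)

    P, Q = pre.samples, post.samples
    N = ka * kl
    sat_p, sat_p2 = _sat(P), _sat(P * P)
    sat_q, sat_q2 = _sat(Q), _sat(Q * Q)
    sum_p = _window_sums(sat_p, tzf, txf, ka, kl)
    var_p = _window_sums(sat_p2, tzf, txf, ka, kl) - sum_p**2 / N
    flat = var_p <= _VAR_EPS * np.maximum(np.abs(sum_p**2 / N), 1.0)

    rho = np.full((n_st, lags_a.size, lags_l.size), -2.0)
    for ia, da in enumerate(lags_a):
        # cross-product image of pre against post shifted by (da, dl)
        for il, dl in enumerate(lags_l):
            i0, i1 = max(0, -da), min(g.n_axial, g.n_axial - da)
            j0, j1 = max(0, -dl), min(g.n_lateral, g.n_lateral - dl)
            if i1 - i0 < ka or j1 - j0 < kl:
                continue
            prod = np.zeros_like(P)
            prod[i0:i1, j0:j1] = P[i0:i1, j0:j1] * Q[i0 + da : i1 + da, j0 + dl : j1 + dl]
            sat_pq = _sat(prod)
            ok = (
                (tzf + da >= 0)
                & (tzf + ka + da <= g.n_axial)
                & (txf + dl >= 0)
                & (txf + kl + dl <= g.n_lateral)
            )
            tq = np.clip(tzf + da, 0, g.n_axial - ka)
            lq = np.clip(txf + dl, 0, g.n_lateral - kl)
            sum_q = _window_sums(sat_q, tq, lq, ka, kl)
            var_q = _window_sums(sat_q2, tq, lq, ka, kl) - sum_q**2 / N
            num = _window_sums(sat_pq, tzf, txf, ka, kl) - sum_p * sum_q / N
            with np.errstate(invalid="ignore", divide="ignore"):
                r = num / np.sqrt(np.maximum(var_p * var_q, _VAR_EPS**2))
            good = ok & (var_q > _VAR_EPS)
            rho[good, ia, il] = np.clip(r[good], -1.0, 1.0)

    flat_idx = rho.reshape(n_st, -1).argmax(axis=1)
    pk_a, pk_l = np.unravel_index(flat_idx, (lags_a.size, lags_l.size))
    grid_shape = (z_st.size, x_st.size)
    if config.median_hop_correction and min(grid_shape) >= 3:
        pk_a = _median_correct(pk_a, rho, grid_shape, axis=0)
        pk_l = _median_correct(pk_l, rho, grid_shape, axis=1)
    peak_rho = rho[np.arange(n_st), pk_a, pk_l]

    st = np.arange(n_st)
    interior_a = (pk_a > 0) & (pk_a < lags_a.size - 1)
    interior_l = (pk_l > 0) & (pk_l < lags_l.size - 1)
    da_sub = np.zeros(n_st)
    dl_sub = np.zeros(n_st)
    ia_m = np.where(interior_a, pk_a - 1, pk_a)
    ia_p = np.where(interior_a, pk_a + 1, pk_a)
    il_m = np.where(interior_l, pk_l - 1, pk_l)
    il_p = np.where(interior_l, pk_l + 1, pk_l)
    rm_a, rp_a = rho[st, ia_m, pk_l], rho[st, ia_p, pk_l]
    rm_l, rp_l = rho[st, pk_a, il_m], rho[st, pk_a, il_p]
    # a perfect-match peak (rho = 1) is exact at the integer lag already;
    # interpolating around it would only re-introduce fit bias
    perfect = peak_rho >= 1.0 - 1e-9
    neigh_ok_a = interior_a & (rm_a > -2) & (rp_a > -2) & ~perfect
    neigh_ok_l = interior_l & (rm_l > -2) & (rp_l > -2) & ~perfect
    omega_ax = 2 * np.pi * dz / g.carrier_period_um  # carrier in rad/sample
    da_sub[neigh_ok_a] = _subpixel(
        rm_a[neigh_ok_a],
        peak_rho[neigh_ok_a],
        rp_a[neigh_ok_a],
        config.subpixel_axial,
        omega=omega_ax if config.subpixel_axial == "cosine" else None,
    )
    dl_sub[neigh_ok_l] = _subpixel(
        rm_l[neigh_ok_l], peak_rho[neigh_ok_l], rp_l[neigh_ok_l], config.subpixel_lateral
    )

    u_a = (lags_a[pk_a] + da_sub) * dz
    u_l = (lags_l[pk_l] + dl_sub) * dx
    invalid = flat | (peak_rho <= -2)
    u_a[invalid] = np.nan
    u_l[invalid] = np.nan
    if config.reject_edge_peaks:
        # per component: the other component's estimate is still usable
        if lags_a.size > 1:
            u_a[(pk_a == 0) | (pk_a == lags_a.size - 1)] = np.nan
        if lags_l.size > 1:
            u_l[(pk_l == 0) | (pk_l == lags_l.size - 1)] = np.nan
    peak_rho = peak_rho.astype(float)
    peak_rho[invalid] = np.nan

    shape = (z_st.size, x_st.size)
    return DisplacementGrid(
        axial_stations_um=z_st,
        lateral_stations_um=x_st,
        u_axial_um=u_a.reshape(shape),
        u_lateral_um=u_l.reshape(shape),
        correlation=peak_rho.reshape(shape),
        kernel_samples=(ka, kl),
    )


def grid_to_nodes(
    grid: DisplacementGrid,
    mesh: TriMesh,
    min_correlation: float = 0.75,
    max_masked_fraction: float = 0.20,
) -> DisplacementField:
    """Bilinear interpolation of the tracked grid onto mesh nodes.

    Only stations with correlation >= ``min_correlation`` contribute.
    Nodes without a complete set of valid surrounding stations are masked
    and filled from the nearest valid station; if more than
    ``max_masked_fraction`` of nodes are masked a hard error is raised.
    Mesh coordinates are mm, the grid is um; output is mm, flagged
    "measured".
    """
    valid = np.isfinite(grid.correlation) & (grid.correlation >= min_correlation)
    if not valid.any():
        raise TrackingError("no station passes the correlation threshold")
    ua = np.where(valid, grid.u_axial_um, np.nan)
    ul = np.where(valid, grid.u_lateral_um, np.nan)
    pts = mesh.nodes * 1e3  # mm -> um, same physical frame as the grid
    interp_a = RegularGridInterpolator(
        (grid.axial_stations_um, grid.lateral_stations_um), ua,
        method="linear", bounds_error=False, fill_value=np.nan,
    )
    interp_l = RegularGridInterpolator(
        (grid.axial_stations_um, grid.lateral_stations_um), ul,
        method="linear", bounds_error=False, fill_value=np.nan,
    )
    va = interp_a(pts)
    vl = interp_l(pts)
    mask_a = ~np.isfinite(va)
    mask_l = ~np.isfinite(vl)
    # the axial component carries the carrier-resolved information; the
    # coverage guarantee is enforced on it, lateral gaps are filled
    frac = mask_a.mean()
    if frac > max_masked_fraction:
        raise TrackingError(
            f"{frac:.0%} of mesh nodes lack valid surrounding stations "
            f"(limit {max_masked_fraction:.0%})"
        )
    zz, xx = np.meshgrid(
        grid.axial_stations_um, grid.lateral_stations_um, indexing="ij"
    )
    for comp, vals, mask in ((ua, va, mask_a), (ul, vl, mask_l)):
        if not mask.any():
            continue
        ok = np.isfinite(comp)
        if not ok.any():
            raise TrackingError("no valid stations for one displacement component")
        tree = cKDTree(np.column_stack([zz[ok], xx[ok]]))
        _, nearest = tree.query(pts[mask])
        vals[mask] = comp[ok][nearest]
    values_mm = np.column_stack([va, vl]) * 1e-3
    return DisplacementField(values_mm, provenance="measured", mask=mask_a | mask_l)
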