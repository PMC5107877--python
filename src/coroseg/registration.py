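"""Multi-atlas heart extraction by two-stage intensity-based registration.

Stage one aligns each atlas to the patient with an affine transform that
minimizes the mean squared intensity difference over image samples redrawn
randomly at every iteration, using a fixed budget of gradient-descent steps.
Stage two refines the alignment with a cubic B-spline free-form deformation
initialized from the affine result; it ascends a *localized* mutual
information measure: each iteration picks one voxel at random and builds the
joint histogram from samples inside a 50 mm cube around it.  Atlas heart
labels are propagated through the final transforms by nearest-neighbour
resampling and fused by strict majority voting.

All gradients are analytic: trilinear-interpolation derivatives for the
moving image, a Parzen (cubic-kernel) smoothed joint histogram for the MI
derivative with respect to moving intensities, and the separable cubic
B-spline basis for the derivative with respect to control-point
displacements.  A Gaussian pyramid (coarse-to-fine, iteration budget split
evenly across levels) accelerates both stages.  Every random draw flows
through the options' seed, so registration is deterministic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import (BinaryMask3D, GeometryError, Grid, GridPoint,
                      OptimizationError, ParameterError, PipelineError,
                      Volume3D, indices_to_world, require_same_grid,
                      world_to_indices)

log = logging.getLogger(__name__)

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Transform types
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """World-space affine map ``T(x) = M (x - c) + c + t`` (x, t, c in mm)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        self.center = np.asarray(self.center, float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ParameterError("affine matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, float))


@dataclass
class BSplineTransform:
    """Affine bulk transform plus a cubic B-spline displacement field.

    ``coefficients`` has shape ``(3, ncz, ncy, ncx)``: per-control-point
    displacement in mm along the world (x, y, z) axes (leading axis), on a
    control lattice indexed (z, y, x).  The lattice covers the fixed-image
    domain plus the cubic support margin.
    """

    control_grid_spacing: float
    coefficients: np.ndarray
    bulk: AffineTransform
    grid_origin: np.ndarray  # world (x, y, z) mm of control point (0, 0, 0)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        self.grid_origin = np.asarray(self.grid_origin, float).reshape(3)
        if self.coefficients.ndim != 4 or self.coefficients.shape[0] != 3:
            raise ParameterError("coefficients must have shape (3, ncz, ncy, ncx)")

    @property
    def n_control(self) -> Tuple[int, int, int]:
        return self.coefficients.shape[1:]

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return _bspline_displacement(self.coefficients, self.grid_origin,
                                     self.control_grid_spacing, points)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.bulk.apply(points) + self.displacement(points)


@dataclass
class RegistrationOptions:
    n_affine_iterations: int = 256
    n_bspline_iterations: int = 600
    n_samples_per_iteration: int = 2048
    pyramid_levels: int = 3
    #: the B-spline stage skips the coarsest pyramid levels: its control
    #: spacing already regularizes, and very coarse levels destabilize the
    #: histogram gradient
    bspline_pyramid_levels: int = 2
    bspline_neighborhood_mm: float = 50.0
    n_histogram_bins: int = 32
    control_spacing_mm: float = 16.0
    step_sizes: Tuple[float, float] = (2.0, 1.0)  # (affine, bspline) mm
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_affine_iterations", "n_bspline_iterations",
                     "n_samples_per_iteration", "pyramid_levels",
                     "n_histogram_bins"):
            if getattr(self, name) < (0 if "bspline_iter" in name else 1):
                raise ParameterError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Interpolation with analytic gradient
# ---------------------------------------------------------------------------

def _trilinear(data: np.ndarray, coords: np.ndarray
               ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trilinear interpolation at continuous (k, j, i) coords.

    Returns ``(values, grad_kji, valid)`` where ``grad_kji`` is the analytic
    derivative with respect to each voxel coordinate and ``valid`` flags
    in-domain points; values/grads are zero for invalid points.
    """
    nz, ny, nx = data.shape
    c = np.asarray(coords, float)
    valid = ((c[:, 0] >= 0) & (c[:, 0] <= nz - 1) &
             (c[:, 1] >= 0) & (c[:, 1] <= ny - 1) &
             (c[:, 2] >= 0) & (c[:, 2] <= nx - 1))
    cc = np.clip(c, 0, [nz - 1, ny - 1, nx - 1])
    base = np.minimum(np.floor(cc).astype(int), [nz - 2, ny - 2, nx - 2])
    base = np.maximum(base, 0)
    t = cc - base
    tz, ty, tx = t[:, 0], t[:, 1], t[:, 2]
    k, j, i = base[:, 0], base[:, 1], base[:, 2]

    C = np.empty((2, 2, 2, c.shape[0]))
    for a in (0, 1):
        for b in (0, 1):
            for d in (0, 1):
                C[a, b, d] = data[k + a, j + b, i + d]
    wz = np.stack([1 - tz, tz]); wy = np.stack([1 - ty, ty]); wx = np.stack([1 - tx, tx])
    dz = np.stack([-np.ones_like(tz), np.ones_like(tz)])

    val = np.zeros(c.shape[0])
    gk = np.zeros_like(val); gj = np.zeros_like(val); gi = np.zeros_like(val)
    for a in (0, 1):
        for b in (0, 1):
            for d in (0, 1):
                cell = C[a, b, d]
                val += wz[a] * wy[b] * wx[d] * cell
                gk += dz[a] * wy[b] * wx[d] * cell
                gj += wz[a] * dz[b] * wx[d] * cell
                gi += wz[a] * wy[b] * dz[d] * cell
    grad = np.stack([gk, gj, gi], axis=1)
    val = np.where(valid, val, 0.0)
    grad[~valid] = 0.0
    return val, grad, valid


def _sample_moving(moving: Volume3D, points_world: np.ndarray):
    """Interpolate the moving image at world points; world-axis gradient (x,y,z)."""
    coords = world_to_indices(moving.grid, points_world)
    val, grad_kji, valid = _trilinear(np.asarray(moving.data, float), coords)
    sz, sy, sx = moving.spacing
    grad_world = np.stack([grad_kji[:, 2] / sx, grad_kji[:, 1] / sy,
                           grad_kji[:, 0] / sz], axis=1)
    return val, grad_world, valid


# ---------------------------------------------------------------------------
# SSD cost (affine stage)
# ---------------------------------------------------------------------------

def _as_index_array(sample_points) -> np.ndarray:
    if isinstance(sample_points, np.ndarray):
        return sample_points.reshape(-1, 3).astype(int)
    return np.array([p.index if isinstance(p, GridPoint) else tuple(p)
                     for p in sample_points], dtype=int).reshape(-1, 3)


def ssd_cost(fixed: Volume3D, moving: Volume3D, t: AffineTransform,
             sample_points) -> float:
    """Mean squared intensity difference over retained (in-domain) samples.

    The moving image is interpolated trilinearly at the transformed sample
    positions; samples mapping outside the moving domain are dropped from
    the average.
    """
    idx = _as_index_array(sample_points)
    cost, _, _, n_valid = _ssd_cost_grad(fixed, moving, t.matrix, t.translation,
                                         t.center, idx, need_grad=False)
    if n_valid == 0:
        raise OptimizationError("all samples map outside the moving domain; "
                                "SSD cost undefined")
    return cost


def _ssd_cost_grad(fixed: Volume3D, moving: Volume3D, M: np.ndarray,
                   t: np.ndarray, center: np.ndarray, idx: np.ndarray,
                   need_grad: bool = True):
    fvals = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    xw = indices_to_world(fixed.grid, idx)
    y = (xw - center) @ M.T + center + t
    mval, gw, valid = _sample_moving(moving, y)
    n = int(valid.sum())
    if n == 0:
        return np.nan, None, None, 0
    r = mval[valid] - fvals[valid]
    cost = float(np.mean(r ** 2))
    if not need_grad:
        return cost, None, None, n
    g = gw[valid]
    rel = (xw - center)[valid]
    g_t = 2.0 / n * (r[:, None] * g).sum(axis=0)
    g_M = 2.0 / n * np.einsum("s,sa,sb->ab", r, g, rel)
    return cost, g_M, g_t, n


# ---------------------------------------------------------------------------
# Gaussian pyramid
# ---------------------------------------------------------------------------

def gaussian_pyramid(vol: Volume3D, levels: int) -> List[Volume3D]:
    """Level 0 is the original; each next level is smoothed and 2x
    downsampled, spacing doubled.  Truncated with a warning once any axis
    would fall below 8 voxels."""
    if levels < 1:
        raise ParameterError("levels must be >= 1")
    out = [vol]
    for _ in range(levels - 1):
        prev = out[-1]
        new_shape = tuple((s + 1) // 2 for s in prev.shape)
        if min(new_shape) < 8:
            warnings.warn(f"pyramid truncated at {len(out)} levels "
                          f"(next shape {new_shape} below 8 voxels per axis)")
            break
        smoothed = ndimage.gaussian_filter(np.asarray(prev.data, float), 1.0)
        data = smoothed[::2, ::2, ::2]
        sz, sy, sx = prev.spacing
        grid = Grid(data.shape, (2 * sz, 2 * sy, 2 * sx), prev.origin)
        out.append(Volume3D(data, grid))
    return out


# ---------------------------------------------------------------------------
# Affine registration
# ---------------------------------------------------------------------------

def _split_iterations(total: int, levels: int) -> List[int]:
    base = total // levels
    split = [base] * levels
    split[-1] += total - base * levels  # remainder to the finest level
    return split


def affine_register(fixed: Volume3D, moving: Volume3D,
                    opts: RegistrationOptions = None) -> AffineTransform:
    """Exactly ``opts.n_affine_iterations`` gradient-descent steps on the SSD
    cost with fresh random samples per iteration, coarse-to-fine."""
    opts = opts or RegistrationOptions()
    rng = np.random.default_rng(opts.rng_seed)
    fpyr = gaussian_pyramid(fixed, opts.pyramid_levels)
    mpyr = gaussian_pyramid(moving, opts.pyramid_levels)
    levels = min(len(fpyr), len(mpyr))
    lo, hi = fixed.grid.world_extent()
    center = 0.5 * (lo + hi)
    L = 0.5 * float(max(hi - lo))  # characteristic half-extent, mm

    M = np.eye(3)
    t = np.zeros(3)
    iters = _split_iterations(opts.n_affine_iterations, levels)
    it_global = 0
    for lvl in range(levels - 1, -1, -1):
        f, m = fpyr[lvl], mpyr[lvl]
        step = opts.step_sizes[0] * (2.0 ** lvl)
        nz, ny, nx = f.shape
        for _ in range(iters[levels - 1 - lvl]):
            it_global += 1
            idx = np.stack([rng.integers(0, nz, opts.n_samples_per_iteration),
                            rng.integers(0, ny, opts.n_samples_per_iteration),
                            rng.integers(0, nx, opts.n_samples_per_iteration)],
                           axis=1)
            cost, g_M, g_t, n = _ssd_cost_grad(f, m, M, t, center, idx)
            if n == 0 or not np.isfinite(cost):
                raise OptimizationError(
                    f"affine registration diverged at iteration {it_global} "
                    f"(cost={cost})")
            u_M = g_M / (L * L)
            u_t = g_t
            delta = L * np.abs(u_M).max() + np.abs(u_t).max()
            if delta <= 0:
                continue
            scale = step / delta
            accepted = False
            for _ in range(5):
                M_try = M - scale * u_M
                t_try = t - scale * u_t
                if abs(np.linalg.det(M_try)) <= 1e-12:
                    scale *= 0.5
                    continue
                c_try, _, _, n_try = _ssd_cost_grad(f, m, M_try, t_try, center,
                                                    idx, need_grad=False)
                if n_try > 0 and np.isfinite(c_try) and c_try <= cost:
                    M, t = M_try, t_try
                    accepted = True
                    break
                scale *= 0.5
            step = min(step * 1.1, opts.step_sizes[0] * (2.0 ** lvl) * 2) \
                if accepted else step * 0.5
            step = max(step, 1e-4)
    return AffineTransform(M, t, center)


# ---------------------------------------------------------------------------
# Localized mutual information (B-spline stage)
# ---------------------------------------------------------------------------

def _percentile_range(values: np.ndarray) -> Tuple[float, float]:
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1.0
    return float(lo), float(hi)


def _cube_indices(grid: Grid, center_idx, half_mm: float):
    """Index ranges (inclusive-exclusive) of the world cube around a voxel."""
    sz, sy, sx = grid.spacing
    nz, ny, nx = grid.shape
    k, j, i = center_idx
    rk, rj, ri = (max(1, int(round(half_mm / s))) for s in (sz, sy, sx))
    return ((max(0, k - rk), min(nz, k + rk + 1)),
            (max(0, j - rj), min(ny, j + rj + 1)),
            (max(0, i - ri), min(nx, i + ri + 1)))


def localized_mi(fixed: Volume3D, moving: Volume3D, t, center: GridPoint,
                 opts: RegistrationOptions = None) -> float:
    """Mutual information (bits) of the joint intensity histogram built from
    the center voxel plus all voxels of a ``bspline_neighborhood_mm`` cube
    around it, transformed through ``t``.

    Returns 0.0 with a warning when either marginal occupies fewer than two
    bins.  Nonnegative and bounded by min of the marginal entropies.
    """
    opts = opts or RegistrationOptions()
    (k0, k1), (j0, j1), (i0, i1) = _cube_indices(
        fixed.grid, center.index, opts.bspline_neighborhood_mm / 2.0)
    kk, jj, ii = np.meshgrid(np.arange(k0, k1), np.arange(j0, j1),
                             np.arange(i0, i1), indexing="ij")
    idx = np.stack([kk.ravel(), jj.ravel(), ii.ravel()], axis=1)
    fvals = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    xw = indices_to_world(fixed.grid, idx)
    mval, _, valid = _sample_moving(moving, t.apply(xw))
    fvals, mval = fvals[valid], mval[valid]
    if fvals.size == 0:
        warnings.warn("localized MI: no in-domain samples; returning 0")
        return 0.0

    nb = opts.n_histogram_bins
    flo, fhi = _percentile_range(fvals)
    mlo, mhi = _percentile_range(mval)
    fi = np.clip(((fvals - flo) / (fhi - flo) * nb).astype(int), 0, nb - 1)
    mi_ = np.clip(((mval - mlo) / (mhi - mlo) * nb).astype(int), 0, nb - 1)
    joint = np.zeros((nb, nb))
    np.add.at(joint, (fi, mi_), 1.0)
    joint /= joint.sum()
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    if np.count_nonzero(pf) < 2 or np.count_nonzero(pm) < 2:
        warnings.warn("localized MI: fewer than 2 occupied bins on a "
                      "marginal; returning 0")
        return 0.0
    nz_ = joint > 0
    return float(np.sum(joint[nz_] * np.log2(
        joint[nz_] / (pf[:, None] * pm[None, :])[nz_])))


def _bspline_weights(t: np.ndarray):
    """Cubic B-spline basis weights/derivatives for fractional offsets t in [0,1)."""
    t2, t3 = t * t, t * t * t
    w = np.stack([(1 - t) ** 3 / 6.0,
                  (3 * t3 - 6 * t2 + 4) / 6.0,
                  (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
                  t3 / 6.0])
    dw = np.stack([-(1 - t) ** 2 / 2.0,
                   (9 * t2 - 12 * t) / 6.0,
                   (-9 * t2 + 6 * t + 3) / 6.0,
                   t2 / 2.0])
    return w, dw


def _bspline_support(points_world: np.ndarray, grid_origin: np.ndarray,
                     cs: float, ncontrol: Tuple[int, int, int]):
    """Base control indices (per world axis x,y,z) and basis weights."""
    u = (np.asarray(points_world, float) - grid_origin) / cs  # (N,3) xyz
    base = np.floor(u).astype(int)
    ncx, ncy, ncz = ncontrol[2], ncontrol[1], ncontrol[0]
    base[:, 0] = np.clip(base[:, 0], 1, ncx - 3)
    base[:, 1] = np.clip(base[:, 1], 1, ncy - 3)
    base[:, 2] = np.clip(base[:, 2], 1, ncz - 3)
    frac = np.clip(u - base, 0.0, 1.0)
    wx, _ = _bspline_weights(frac[:, 0])
    wy, _ = _bspline_weights(frac[:, 1])
    wz, _ = _bspline_weights(frac[:, 2])
    return base, wx, wy, wz


def _bspline_displacement(coeffs: np.ndarray, grid_origin: np.ndarray,
                          cs: float, points_world: np.ndarray) -> np.ndarray:
    pts = np.asarray(points_world, float).reshape(-1, 3)
    base, wx, wy, wz = _bspline_support(pts, grid_origin, cs, coeffs.shape[1:])
    ncz, ncy, ncx = coeffs.shape[1:]
    flat = coeffs.reshape(3, -1)
    disp = np.zeros((pts.shape[0], 3))
    for a in range(4):
        iz = base[:, 2] - 1 + a
        for b in range(4):
            iy = base[:, 1] - 1 + b
            wzy = wz[a] * wy[b]
            for c in range(4):
                ix = base[:, 0] - 1 + c
                w = wzy * wx[c]
                fi = (iz * ncy + iy) * ncx + ix
                disp += (flat[:, fi] * w).T
    out_shape = np.asarray(points_world, float).shape
    return disp.reshape(out_shape)


def _make_control_grid(fixed_grid: Grid, cs: float):
    lo, hi = fixed_grid.world_extent()
    origin = lo - cs
    n = tuple(int(math.ceil((h - l) / cs)) + 4 for l, h in zip(lo, hi))
    # n is per world axis (x, y, z); coefficients are stored (z, y, x)
    return origin, (n[2], n[1], n[0])


def _mattes_mi_and_dmi(fvals, mval, f_range, m_range, nb):
    """MI (bits) of a Parzen-smoothed joint histogram and dMI/d(moving value)."""
    flo, fhi = f_range
    mlo, mhi = m_range
    wfix = (fhi - flo) / nb
    wm = (mhi - mlo) / nb
    fi = np.clip(((fvals - flo) / wfix).astype(int), 0, nb - 1)
    u = np.clip((mval - mlo) / wm, 1.0, nb - 2.0 - 1e-9)
    mb = np.floor(u).astype(int)
    frac = u - mb
    w, dw = _bspline_weights(frac)  # (4, N)

    n = fvals.size
    joint = np.zeros((nb, nb))
    for o in range(4):
        np.add.at(joint, (fi, mb - 1 + o), w[o])
    joint /= n
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    nzj = joint > 1e-12
    mi = float(np.sum(joint[nzj] * np.log2(
        joint[nzj] / np.maximum(pf[:, None] * pm[None, :], 1e-300)[nzj])))

    # dMI/du_s = 1/(N ln2) sum_o dw_o * ln(p(f_s, j_o) / pM(j_o))
    logterm = np.zeros((nb, nb))
    logterm[nzj] = np.log(joint[nzj] / np.maximum(pm[None, :], 1e-300)
                          .repeat(nb, axis=0)[nzj])
    dmi_du = np.zeros(n)
    for o in range(4):
        dmi_du += dw[o] * logterm[fi, mb - 1 + o]
    dmi_dm = dmi_du / (n * _LN2 * wm)
    return mi, dmi_dm


def bspline_register(fixed: Volume3D, moving: Volume3D,
                     init: AffineTransform,
                     opts: RegistrationOptions = None) -> BSplineTransform:
    """Stochastic ascent of localized MI over B-spline control displacements.

    Each iteration selects one voxel at random, draws the remaining samples
    inside a ``bspline_neighborhood_mm`` cube around it, and takes one
    backtracking gradient-ascent step on the control-point coefficients.
    With zero iterations the affine initialization is returned embedded in an
    identity spline.
    """
    opts = opts or RegistrationOptions()
    rng = np.random.default_rng(opts.rng_seed + 1)
    origin, nctrl = _make_control_grid(fixed.grid, opts.control_spacing_mm)
    coeffs = np.zeros((3, *nctrl))
    tr = BSplineTransform(opts.control_spacing_mm, coeffs, init, origin)
    if opts.n_bspline_iterations == 0:
        return tr

    fpyr = gaussian_pyramid(fixed, min(opts.pyramid_levels,
                                       opts.bspline_pyramid_levels))
    mpyr = gaussian_pyramid(moving, min(opts.pyramid_levels,
                                        opts.bspline_pyramid_levels))
    levels = min(len(fpyr), len(mpyr))
    iters = _split_iterations(opts.n_bspline_iterations, levels)
    nb = opts.n_histogram_bins
    cs = opts.control_spacing_mm
    ncz, ncy, ncx = nctrl

    for lvl in range(levels - 1, -1, -1):
        f, m = fpyr[lvl], mpyr[lvl]
        f_range = _percentile_range(np.asarray(f.data, float).ravel())
        m_range = _percentile_range(np.asarray(m.data, float).ravel())
        nz, ny, nx = f.shape
        step = opts.step_sizes[1]
        for _ in range(iters[levels - 1 - lvl]):
            ck = int(rng.integers(0, nz)); cj = int(rng.integers(0, ny))
            ci = int(rng.integers(0, nx))
            (k0, k1), (j0, j1), (i0, i1) = _cube_indices(
                f.grid, (ck, cj, ci), opts.bspline_neighborhood_mm / 2.0)
            ns = opts.n_samples_per_iteration
            idx = np.stack([rng.integers(k0, k1, ns),
                            rng.integers(j0, j1, ns),
                            rng.integers(i0, i1, ns)], axis=1)
            idx[0] = (ck, cj, ci)
            fvals = f.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
            xw = indices_to_world(f.grid, idx)
            bulk = init.apply(xw)

            base, wxb, wyb, wzb = _bspline_support(xw, origin, cs, nctrl)
            disp = _bspline_displacement(coeffs, origin, cs, xw)
            mval, gw, valid = _sample_moving(m, bulk + disp)
            if valid.sum() < 16:
                continue
            fv, mv = fvals[valid], mval[valid]
            mi, dmi_dm = _mattes_mi_and_dmi(fv, mv, f_range, m_range, nb)
            if not np.isfinite(mi):
                raise OptimizationError("B-spline registration: non-finite "
                                        "objective")
            factor = dmi_dm[:, None] * gw[valid]  # (Nv, 3) world axes
            vb = base[valid]
            grad = np.zeros_like(coeffs).reshape(3, -1)
            for a in range(4):
                iz = vb[:, 2] - 1 + a
                for b in range(4):
                    iy = vb[:, 1] - 1 + b
                    wzy = (wzb[a] * wyb[b])[valid]
                    for c in range(4):
                        ix = vb[:, 0] - 1 + c
                        wtot = wzy * wxb[c][valid]
                        fi_ = (iz * ncy + iy) * ncx + ix
                        for ax in range(3):
                            np.add.at(grad[ax], fi_, factor[:, ax] * wtot)
            grad = grad.reshape(coeffs.shape)
            gmax = np.abs(grad).max()
            if gmax <= 0:
                continue
            scale = step / gmax
            accepted = False
            for _ in range(4):
                trial = coeffs + scale * grad
                disp_t = _bspline_displacement(trial, origin, cs, xw)
                mval_t, _, valid_t = _sample_moving(m, bulk + disp_t)
                both = valid & valid_t
                if both.sum() >= 16:
                    mi_t, _ = _mattes_mi_and_dmi(fvals[both], mval_t[both],
                                                 f_range, m_range, nb)
                    if np.isfinite(mi_t) and mi_t >= mi:
                        coeffs = trial
                        accepted = True
                        break
                scale *= 0.5
            step = min(step * 1.1, opts.step_sizes[1] * 2) if accepted \
                else max(step * 0.5, 1e-3)
    return BSplineTransform(cs, coeffs, init, origin)


# ---------------------------------------------------------------------------
# Label propagation and fusion
# ---------------------------------------------------------------------------

def warp_labels(label: BinaryMask3D, t, target_grid: Grid) -> BinaryMask3D:
    """Nearest-neighbour resampling of a label through transform ``t`` onto
    ``target_grid``; out-of-domain voxels become background."""
    world = target_grid.index_grid_world().reshape(-1, 3)
    mapped = t.apply(world)
    coords = world_to_indices(label.grid, mapped)
    vals = ndimage.map_coordinates(label.data.astype(np.uint8), coords.T,
                                   order=0, mode="constant", cval=0)
    return BinaryMask3D(vals.reshape(target_grid.shape) > 0, target_grid)


def majority_vote(labels: Sequence[BinaryMask3D]) -> BinaryMask3D:
    """Voxel is foreground iff strictly more than half the labels mark it."""
    if len(labels) == 0:
        raise ParameterError("majority_vote requires at least one label")
    grid = require_same_grid(*labels)
    votes = np.zeros(grid.shape, np.int32)
    for l in labels:
        votes += l.data
    return BinaryMask3D(votes * 2 > len(labels), grid)


def register_atlas(patient: Volume3D, atlas_image: Volume3D,
                   opts: RegistrationOptions) -> BSplineTransform:
    """Two-stage registration of one atlas (moving) to the patient (fixed)."""
    aff = affine_register(patient, atlas_image, opts)
    return bspline_register(patient, atlas_image, aff, opts)


def segment_heart(patient: Volume3D, atlases, opts: RegistrationOptions = None
                  ) -> BinaryMask3D:
    """Register every atlas to the patient, propagate its heart label, and
    fuse by strict majority voting.

    ``atlases`` is a sequence of ``(Volume3D, BinaryMask3D)`` pairs (or
    objects with ``image``/``label`` attributes).  Atlases whose registration
    fails are excluded with a warning; if all fail, a pipeline error is
    raised.
    """
    opts = opts or RegistrationOptions()
    if len(atlases) == 0:
        raise PipelineError("at least one atlas is required")
    warped: List[BinaryMask3D] = []
    for i, atlas in enumerate(atlases):
        img, lbl = ((atlas.image, atlas.label) if hasattr(atlas, "image")
                    else (atlas[0], atlas[1]))
        o = replace(opts, rng_seed=opts.rng_seed + i)
        try:
            tr = register_atlas(patient, img, o)
            warped.append(warp_labels(lbl, tr, patient.grid))
        except (OptimizationError, GeometryError) as exc:
            warnings.warn(f"atlas {i} excluded: registration failed ({exc})")
    if not warped:
        raise PipelineError("all atlas registrations failed")
    return majority_vote(warped)
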