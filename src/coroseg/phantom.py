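"""Synthetic cardiac CTA phantoms with known gold-standard masks.

The generator emulates the intensity ordering of a contrast-enhanced cardiac
CT: air/lung background far below zero, myocardium below the 120 HU seed
threshold, and contrast-filled vessel lumina well above it.  Vessels are
tubes around polyline centerlines with the ideal bright-line radial profile
``peak * exp(-r^2 / (2 sigma^2))``, truncated at the nominal lumen radius
(no contrast outside the wall); ``sigma`` is set so the wall value is half
the peak, hence intensity >= peak/2 everywhere inside the nominal radius.
A 0.5-voxel Gaussian blur models partial-volume averaging, and optional
Gaussian noise is added last.  All randomness flows through a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import (BinaryMask3D, Grid, ParameterError, Volume3D,
                      indices_to_world)

#: sigma such that exp(-r^2 / (2 sigma^2)) = 1/2 at r = nominal radius
_HALF_PEAK_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Ideal bright line
# ---------------------------------------------------------------------------

def make_line_phantom(shape: Sequence[int], spacing: Sequence[float],
                      sigma_voxels: float, peak: float = 350.0,
                      background: float = 0.0) -> Volume3D:
    """Ideal bright 3D line along the z-axis through the in-plane centre voxel.

    Intensity at ``(x, y, z)`` is ``background + peak * exp(-(x^2+y^2)/(2 sigma^2))``
    with ``x, y`` measured in voxels from the line axis, so the on-axis value
    is exactly ``background + peak``.  The axis passes through voxel
    ``(ny//2, nx//2)`` so that exact on-axis voxels exist.
    """
    if sigma_voxels <= 0:
        raise ParameterError(f"sigma_voxels must be > 0, got {sigma_voxels}")
    grid = Grid(tuple(shape), tuple(spacing))
    nz, ny, nx = grid.shape
    cy, cx = ny // 2, nx // 2
    yy = (np.arange(ny) - cy)[:, None]
    xx = (np.arange(nx) - cx)[None, :]
    r2 = yy ** 2 + xx ** 2
    plane = background + peak * np.exp(-r2 / (2.0 * sigma_voxels ** 2))
    data = np.broadcast_to(plane, (nz, ny, nx)).copy()
    return Volume3D(data, grid)


# ---------------------------------------------------------------------------
# Cardiac phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of the synthetic cardiac phantom.

    ``vessel_centerlines`` are polylines of world (x, y, z) mm points; each
    curve carries a nominal lumen radius in ``vessel_radius_mm`` and an
    optional list of stenoses ``(s0_mm, s1_mm, factor)`` that multiply the
    radius by ``factor`` over the arc-length span ``[s0, s1]``.
    """

    shape: Tuple[int, int, int] = (96, 128, 128)
    spacing: Tuple[float, float, float] = (0.4, 0.33, 0.33)
    vessel_centerlines: List[np.ndarray] = field(default_factory=list)
    vessel_radius_mm: List[float] = field(default_factory=list)
    stenoses: List[List[Tuple[float, float, float]]] = field(default_factory=list)
    vessel_peak_hu: float = 350.0
    myocardium_hu: float = 60.0
    blood_pool_hu: float = 300.0
    lung_hu: float = -800.0
    noise_sd_hu: float = 10.0
    #: smooth intra-tissue HU heterogeneity (sd, correlation length) added to
    #: the heart and pool before blurring.  Real myocardium is not uniform;
    #: this texture is what makes deformable registration of the phantom
    #: identifiable away from tissue boundaries.  Off by default so the
    #: region-growing contracts keep the flat two-level intensity model.
    texture_sd_hu: float = 0.0
    texture_corr_mm: float = 5.0
    rng_seed: int = 0
    heart_center_mm: Optional[Tuple[float, float, float]] = None  # (x, y, z)
    heart_semiaxes_mm: Tuple[float, float, float] = (15.0, 15.0, 13.5)  # (ax, ay, az)
    blood_pool_semiaxes_mm: Tuple[float, float, float] = (5.0, 5.0, 5.0)
    #: world (x, y, z) mm; None places the pool just outside the myocardium
    #: ellipsoid along +y, modelling adjacent contrast-filled blood (atrial /
    #: aortic) that the heart-ROI restriction must exclude.
    blood_pool_center_mm: Optional[Tuple[float, float, float]] = None
    partial_volume_blur_voxels: float = 0.5

    def __post_init__(self):
        if self.vessel_peak_hu <= 120.0 or self.myocardium_hu >= 120.0:
            raise ParameterError(
                "phantom requires vessel_peak_hu > 120 HU > myocardium_hu "
                f"(got peak={self.vessel_peak_hu}, myocardium={self.myocardium_hu})")
        if any(r <= 0 for r in self.vessel_radius_mm):
            raise ParameterError("vessel radii must be strictly positive")
        for curve_sten in self.stenoses:
            for (_, _, f) in curve_sten:
                if not (0.0 <= f < 1.0) and f != 1.0:
                    raise ParameterError(f"stenosis factor must be in [0, 1), got {f}")
        if len(self.vessel_centerlines) != len(self.vessel_radius_mm):
            raise ParameterError("one radius per centerline required")
        while len(self.stenoses) < len(self.vessel_centerlines):
            self.stenoses.append([])

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing)

    def center_mm(self) -> np.ndarray:
        if self.heart_center_mm is not None:
            return np.asarray(self.heart_center_mm, float)
        lo, hi = self.grid.world_extent()
        return 0.5 * (lo + hi)


def default_phantom_spec(noise_sd_hu: float = 10.0, rng_seed: int = 0,
                         shape: Tuple[int, int, int] = (96, 128, 128),
                         spacing: Tuple[float, float, float] = (0.4, 0.33, 0.33),
                         stenoses: Optional[List[List[Tuple[float, float, float]]]] = None,
                         ) -> PhantomSpec:
    """Default phantom: myocardium ellipsoid, central blood pool, two coronary arcs.

    The arcs run on opposite sides of the heart axis at ~10.5 mm radius with
    lumen radii 2.8 and 2.4 mm.  The blood pool sits just outside the
    myocardium ellipsoid (adjacent contrast-filled blood that the heart-ROI
    restriction must exclude), and the arcs keep several millimetres of
    clearance from every other contrast-filled structure so the tubes stay
    disconnected both in intensity and in enhancement response.
    """
    spec = PhantomSpec(shape=shape, spacing=spacing, noise_sd_hu=noise_sd_hu,
                       rng_seed=rng_seed)
    c = spec.center_mm()
    curves, radii = [], []
    for side, (ring, zspan) in enumerate([(10.5, 7.0), (10.5, 6.0)]):
        t = np.linspace(-1.0, 1.0, 41)
        theta = math.pi * side + t * math.radians(55.0)
        x = c[0] + ring * np.cos(theta)
        y = c[1] + ring * np.sin(theta)
        z = c[2] + zspan * t
        curves.append(np.stack([x, y, z], axis=1))
        radii.append(2.8 if side == 0 else 2.4)
    spec.vessel_centerlines = curves
    spec.vessel_radius_mm = radii
    spec.stenoses = list(stenoses) if stenoses is not None else [[], []]
    spec.__post_init__()
    return spec


def _ellipsoid_mask(grid: Grid, center_mm: np.ndarray,
                    semiaxes_xyz_mm: Sequence[float]) -> np.ndarray:
    world = grid.index_grid_world()  # (..., 3) xyz
    ax, ay, az = semiaxes_xyz_mm
    d = (world - center_mm) / np.array([ax, ay, az])
    return (d ** 2).sum(axis=-1) <= 1.0


def _resample_polyline(points: np.ndarray, step_mm: float) -> Tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length steps; returns (samples, arclengths)."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(math.ceil(total / step_mm)) + 1)
    si = np.linspace(0.0, total, n)
    out = np.stack([np.interp(si, s, pts[:, a]) for a in range(3)], axis=1)
    return out, si


def _local_radius(radius_mm: float, arclengths: np.ndarray,
                  stenoses: Sequence[Tuple[float, float, float]]) -> np.ndarray:
    r = np.full_like(arclengths, radius_mm, dtype=float)
    for (s0, s1, f) in stenoses:
        r[(arclengths >= s0) & (arclengths <= s1)] = radius_mm * f
    return r


def make_cardiac_phantom(spec: PhantomSpec
                         ) -> Tuple[Volume3D, BinaryMask3D, BinaryMask3D]:
    """Rasterize a phantom; returns ``(volume, heart_gold, vessel_gold)``.

    ``vessel_gold`` marks voxels within the (possibly stenosed) nominal
    radius of any centerline; ``heart_gold`` is the myocardium ellipsoid
    united with the tubes.  Identical spec + seed give bit-identical output.
    """
    grid = spec.grid
    center = spec.center_mm()
    lo, hi = grid.world_extent()

    heart = _ellipsoid_mask(grid, center, spec.heart_semiaxes_mm)
    if spec.blood_pool_center_mm is not None:
        pool_center = np.asarray(spec.blood_pool_center_mm, float)
    else:
        pool_center = center + np.array(
            [0.0, spec.heart_semiaxes_mm[1] + spec.blood_pool_semiaxes_mm[1] + 1.0,
             0.0])
    pool = _ellipsoid_mask(grid, pool_center, spec.blood_pool_semiaxes_mm)

    vol = np.full(grid.shape, spec.lung_hu, dtype=np.float64)
    vol[heart] = spec.myocardium_hu
    vol[pool] = spec.blood_pool_hu

    vessel_gold = np.zeros(grid.shape, dtype=bool)
    step = 0.25 * min(grid.spacing)
    world = None  # lazy full world grid (only for the tube bounding boxes)
    ax_sq, ay_sq, az_sq = [s ** 2 for s in spec.heart_semiaxes_mm]
    for curve, radius, sten in zip(spec.vessel_centerlines, spec.vessel_radius_mm,
                                   spec.stenoses):
        pts = np.asarray(curve, float)
        d = (pts - center) / np.asarray(spec.heart_semiaxes_mm)
        if np.any((d ** 2).sum(axis=1) > 1.0 + 1e-9):
            raise ParameterError("centerline leaves the myocardium ellipsoid")
        if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
            raise ParameterError("centerline escapes the volume")
        samples, arcs = _resample_polyline(pts, step)
        radii = _local_radius(radius, arcs, sten)
        sigma = radii * _HALF_PEAK_SIGMA

        # bounding box of the tube in voxel indices
        rmax = float(radii.max())
        bmin = samples.min(axis=0) - rmax  # xyz
        bmax = samples.max(axis=0) + rmax
        sz, sy, sx = grid.spacing
        ox, oy, oz = grid.origin
        k0 = max(0, int(math.floor((bmin[2] - oz) / sz)))
        k1 = min(grid.shape[0], int(math.ceil((bmax[2] - oz) / sz)) + 1)
        j0 = max(0, int(math.floor((bmin[1] - oy) / sy)))
        j1 = min(grid.shape[1], int(math.ceil((bmax[1] - oy) / sy)) + 1)
        i0 = max(0, int(math.floor((bmin[0] - ox) / sx)))
        i1 = min(grid.shape[2], int(math.ceil((bmax[0] - ox) / sx)) + 1)

        kk, jj, ii = np.meshgrid(np.arange(k0, k1), np.arange(j0, j1),
                                 np.arange(i0, i1), indexing="ij")
        box_idx = np.stack([kk.ravel(), jj.ravel(), ii.ravel()], axis=1)
        box_world = indices_to_world(grid, box_idx)

        tree = cKDTree(samples)
        dist, nearest = tree.query(box_world, k=1)
        r_loc = radii[nearest]
        inside = dist <= r_loc
        if not np.any(inside):
            continue
        value = spec.vessel_peak_hu * np.exp(
            -dist[inside] ** 2 / (2.0 * sigma[nearest][inside] ** 2))
        sel = tuple(box_idx[inside].T)
        np.maximum.at(vol, sel, value)
        vessel_gold[sel] = True

    heart_gold = heart | vessel_gold

    rng = np.random.default_rng(spec.rng_seed)
    if spec.texture_sd_hu > 0:
        corr_vox = tuple(spec.texture_corr_mm / s for s in grid.spacing)
        tex = ndimage.gaussian_filter(rng.normal(size=grid.shape), corr_vox)
        tex *= spec.texture_sd_hu / max(tex.std(), 1e-12)
        vol = vol + tex * (heart | pool)
    if spec.partial_volume_blur_voxels > 0:
        vol = ndimage.gaussian_filter(vol, spec.partial_volume_blur_voxels)
    if spec.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=vol.shape)

    return (Volume3D(vol, grid), BinaryMask3D(heart_gold, grid),
            BinaryMask3D(vessel_gold, grid))


def make_two_population_phantom(shape: Tuple[int, int, int] = (48, 48, 48),
                                spacing: Tuple[float, float, float] = (0.5, 0.5, 0.5),
                                vessel_hu: float = 300.0,
                                vessel_noise_sd: float = 10.0,
                                myocardium_hu: float = 60.0,
                                tube_radius_mm: float = 2.0,
                                rng_seed: int = 0,
                                ) -> Tuple[Volume3D, BinaryMask3D, BinaryMask3D]:
    """Two discrete intensity populations inside a heart ROI.

    A straight tube of ``vessel_hu`` voxels (independent Gaussian spread
    ``vessel_noise_sd``) crosses a myocardium block held at exactly
    ``myocardium_hu`` — no blur, so the interval statistics of the grown
    vessel region are analytically predictable and the bounds-sweep mutation
    fires at the first ``v`` whose interval reaches the myocardium level.
    Returns ``(volume, heart_roi, vessel_gold)``.
    """
    grid = Grid(shape, spacing)
    nz, ny, nx = shape
    vol = np.full(shape, myocardium_hu, dtype=np.float64)
    heart = np.zeros(shape, dtype=bool)
    heart[2:-2, 2:-2, 2:-2] = True
    vol[~heart] = -800.0

    cy, cx = ny // 2, nx // 2
    yy = (np.arange(ny) - cy)[:, None] * spacing[1]
    xx = (np.arange(nx) - cx)[None, :] * spacing[2]
    tube2d = (yy ** 2 + xx ** 2) <= tube_radius_mm ** 2
    vessel = np.zeros(shape, dtype=bool)
    vessel[2:-2] = tube2d[None, :, :]
    vessel &= heart

    rng = np.random.default_rng(rng_seed)
    vol[vessel] = vessel_hu + rng.normal(0.0, vessel_noise_sd, size=int(vessel.sum()))
    return (Volume3D(vol, grid), BinaryMask3D(heart, grid),
            BinaryMask3D(vessel, grid))


# ---------------------------------------------------------------------------
# Synthetic atlas sets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWarp:
    """Known smooth deformation used to synthesize an atlas from a base phantom.

    Maps atlas world coordinates to base-phantom world coordinates:
    ``psi(x) = A (x - c) + c + t + sum_m amp_m * sin(2 pi freq_m . (x - c) + phase_m)``
    (the sinusoidal term is per world axis).  The atlas image is
    ``atlas(x) = base(psi(x))``, so a perfect patient→atlas registration
    ``T`` of ``base`` (fixed) onto the atlas (moving) satisfies
    ``psi(T(x)) = x``.
    """

    matrix: np.ndarray          # (3, 3)
    translation: np.ndarray     # (3,) mm
    center: np.ndarray          # (3,) mm
    sin_amplitude: np.ndarray   # (n_modes, 3) mm per world axis
    sin_frequency: np.ndarray   # (n_modes, 3) cycles/mm (wave vector per mode)
    sin_phase: np.ndarray       # (n_modes, 3) rad per world axis

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        rel = p - self.center
        out = rel @ self.matrix.T + self.center + self.translation
        for amp, freq, ph in zip(self.sin_amplitude, self.sin_frequency,
                                 self.sin_phase):
            s = rel @ freq  # scalar phase field, (...,)
            out = out + amp * np.sin(2.0 * math.pi * s[..., None] + ph)
        return out


@dataclass
class AtlasSample:
    image: Volume3D
    label: BinaryMask3D
    warp: SyntheticWarp


def _interp_at_world(vol: Volume3D, points_world: np.ndarray, order: int) -> np.ndarray:
    from .volumes import world_to_indices
    coords = world_to_indices(vol.grid, points_world.reshape(-1, 3))
    cval = float(vol.data.min()) if order > 0 else 0.0
    vals = ndimage.map_coordinates(vol.data.astype(float), coords.T, order=order,
                                   mode="constant", cval=cval)
    return vals


def apply_synthetic_warp(volume: Volume3D, label: BinaryMask3D,
                         warp: SyntheticWarp) -> AtlasSample:
    """Resample a volume and its label through a known warp.

    The result satisfies ``atlas(x) = volume(warp(x))`` (trilinear for the
    image, nearest neighbour for the label).
    """
    world = volume.grid.index_grid_world().reshape(-1, 3)
    src = warp.apply(world)
    img = _interp_at_world(volume, src, order=1).reshape(volume.shape)
    lbl = _interp_at_world(Volume3D(label.data.astype(np.float64), label.grid),
                           src, order=0).reshape(volume.shape) > 0.5
    return AtlasSample(Volume3D(img, volume.grid),
                       BinaryMask3D(lbl, volume.grid), warp)


def make_atlas_set(spec: PhantomSpec, n_atlases: int,
                   deform_magnitude_voxels: float,
                   rng_seed: int = 0) -> List[AtlasSample]:
    """Warp the base phantom by known random smooth deformations.

    Each atlas is the base phantom resampled through a random
    :class:`SyntheticWarp` whose total displacement magnitude is on the order
    of ``deform_magnitude_voxels`` (in units of the smallest voxel spacing);
    the heart label is warped identically (nearest neighbour).  The applied
    warps are returned as registration ground truth.
    """
    if n_atlases < 1:
        raise ParameterError("n_atlases must be >= 1")
    base_vol, base_heart, _ = make_cardiac_phantom(spec)
    grid = spec.grid
    center = spec.center_mm()
    lo, hi = grid.world_extent()
    extent = hi - lo
    mag_mm = deform_magnitude_voxels * min(grid.spacing)
    rng = np.random.default_rng(rng_seed)

    out: List[AtlasSample] = []
    for _ in range(n_atlases):
        if mag_mm == 0:
            warp = SyntheticWarp(np.eye(3), np.zeros(3), center,
                                 np.zeros((1, 3)), np.zeros((1, 3)),
                                 np.zeros((1, 3)))
        else:
            # half the budget to the affine part, half to the smooth field
            ang = rng.uniform(-1, 1, 3) * (0.35 * mag_mm / max(extent))  # rad
            cz, cy_, cx_ = np.cos(ang)
            szn, syn, sxn = np.sin(ang)
            rz = np.array([[cz, -szn, 0], [szn, cz, 0], [0, 0, 1]])
            ry = np.array([[cy_, 0, syn], [0, 1, 0], [-syn, 0, cy_]])
            rx = np.array([[1, 0, 0], [0, cx_, -sxn], [0, sxn, cx_]])
            scale = np.diag(1.0 + rng.uniform(-1, 1, 3) * (0.35 * mag_mm / max(extent)))
            matrix = rz @ ry @ rx @ scale
            translation = rng.uniform(-1, 1, 3) * (0.5 * mag_mm)
            n_modes = 2
            amp = rng.uniform(-1, 1, (n_modes, 3))
            amp *= 0.5 * mag_mm / max(1e-12, np.abs(amp).sum(axis=0).max())
            freq = rng.uniform(0.5, 1.0, (n_modes, 3)) / max(extent)
            phase = rng.uniform(0, 2 * math.pi, (n_modes, 3))
            warp = SyntheticWarp(matrix, translation, center, amp, freq, phase)
        out.append(apply_synthetic_warp(base_vol, base_heart, warp))
    return out
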