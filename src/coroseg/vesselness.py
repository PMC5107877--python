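"""Multiscale Hessian line filtering for curvilinear structure enhancement.

At each scale the image is convolved with second derivatives of a Gaussian
(sigma in mm, converted per axis by the voxel spacing) and the response is
normalized by sigma^2 so responses are comparable across scales.  The
per-voxel line measure follows Sato's formulation: with eigenvalues sorted
by magnitude |l1| <= |l2| <= |l3|, a bright tube has l1 ~ 0 and
l2 ~ l3 << 0, and the response is

    |l3| * (l2/l3)^g23 * (1 + l1/|l2|)^g12          if l1 <= 0
    |l3| * (l2/l3)^g23 * (1 - alpha*l1/|l2|)^g12    if 0 < l1 <= |l2|/alpha

and zero whenever l2 >= 0 or l3 >= 0 (dark or non-tubular structure).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import (BinaryMask3D, Grid, ParameterError, PipelineError,
                      Volume3D, require_same_grid)

log = logging.getLogger(__name__)


@dataclass
class HessianField:
    """Six unique second-derivative components per voxel at one scale (mm^-2 units)."""

    ixx: np.ndarray
    iyy: np.ndarray
    izz: np.ndarray
    ixy: np.ndarray
    ixz: np.ndarray
    iyz: np.ndarray
    scale_sigma: float
    grid: Grid

    def trace(self) -> np.ndarray:
        return self.ixx + self.iyy + self.izz


@dataclass
class EigenField:
    """Per-voxel eigenvalues sorted by magnitude: |l1| <= |l2| <= |l3|."""

    l1: np.ndarray
    l2: np.ndarray
    l3: np.ndarray
    grid: Grid


@dataclass
class VesselnessParams:
    """Scales and sharpness exponents of the line measure.

    ``sigmas_mm`` should bracket the expected lumen radii; defaults cover
    0.5–3 mm, the coronary range at sub-millimetre CTA resolution.
    """

    sigmas_mm: Tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)
    gamma23: float = 1.0
    gamma12: float = 1.0
    alpha: float = 0.25

    def __post_init__(self):
        s = tuple(float(x) for x in self.sigmas_mm)
        if any(x <= 0 for x in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ParameterError(
                f"sigmas_mm must be strictly positive and increasing, got {s}")
        self.sigmas_mm = s


def _gaussian_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with exact moment normalization.

    The raw sampled kernels are corrected so that a constant image has an
    exactly zero derivative (sum of weights 0 for order >= 1) and the
    monomials x and x^2/2 have exactly unit first/second derivative —
    otherwise kernel truncation leaves a small DC bias in the Hessian.
    Weights are returned in correlate1d order (output = sum w[i] f[x+i-c]).
    """
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        w = -x / sigma ** 2 * g
        # correlate evaluates sum w[i] f(x+i): response to f = x must be 1
        return w / np.sum(w * x)
    if order == 2:
        w = (x ** 2 / sigma ** 4 - 1.0 / sigma ** 2) * g
        w -= w.mean()                      # annihilate constants exactly
        return w * (2.0 / np.sum(w * x ** 2))  # response to x^2 must be 2
    raise ParameterError(f"unsupported derivative order {order}")


def hessian_at_scale(vol: Volume3D, sigma_mm: float) -> HessianField:
    """Gaussian-derivative Hessian at scale ``sigma_mm``, times sigma^2.

    Derivatives are taken with respect to millimetres: each component is the
    voxel-space Gaussian derivative divided by the appropriate spacing
    product, then multiplied by ``sigma_mm**2`` (gamma-normalization with
    gamma = 2).
    """
    if sigma_mm <= 0:
        raise ParameterError(f"sigma_mm must be > 0, got {sigma_mm}")
    sz, sy, sx = vol.spacing
    if sigma_mm < 0.5 * max(vol.spacing):
        warnings.warn(f"scale sigma={sigma_mm} mm is undersampled for voxel "
                      f"spacing {vol.spacing} mm", stacklevel=2)
    sig_vox = (sigma_mm / sz, sigma_mm / sy, sigma_mm / sx)
    data = np.asarray(vol.data, np.float64)
    norm = sigma_mm ** 2

    def deriv(order_zyx, denom):
        out = data
        for axis, (order, sv) in enumerate(zip(order_zyx, sig_vox)):
            out = ndimage.correlate1d(out, _gaussian_kernel(sv, order),
                                      axis=axis, mode="reflect")
        return out * (norm / denom)

    return HessianField(
        ixx=deriv((0, 0, 2), sx * sx),
        iyy=deriv((0, 2, 0), sy * sy),
        izz=deriv((2, 0, 0), sz * sz),
        ixy=deriv((0, 1, 1), sx * sy),
        ixz=deriv((1, 0, 1), sx * sz),
        iyz=deriv((1, 1, 0), sy * sz),
        scale_sigma=float(sigma_mm),
        grid=vol.grid,
    )


def eigenvalues_sorted(h: HessianField) -> EigenField:
    """Per-voxel symmetric eigendecomposition, magnitude-sorted."""
    comps = [h.ixx, h.iyy, h.izz, h.ixy, h.ixz, h.iyz]
    for name, c in zip("ixx iyy izz ixy ixz iyz".split(), comps):
        if not np.all(np.isfinite(c)):
            bad = np.argwhere(~np.isfinite(c))[0]
            raise ParameterError(
                f"non-finite Hessian component {name} at voxel {tuple(bad)}")
    n = h.ixx.size
    mats = np.empty((n, 3, 3), np.float64)
    mats[:, 0, 0] = h.ixx.ravel()
    mats[:, 1, 1] = h.iyy.ravel()
    mats[:, 2, 2] = h.izz.ravel()
    mats[:, 0, 1] = mats[:, 1, 0] = h.ixy.ravel()
    mats[:, 0, 2] = mats[:, 2, 0] = h.ixz.ravel()
    mats[:, 1, 2] = mats[:, 2, 1] = h.iyz.ravel()
    vals = np.linalg.eigvalsh(mats)  # ascending by value
    order = np.argsort(np.abs(vals), axis=1, kind="stable")
    vals = np.take_along_axis(vals, order, axis=1)
    shp = h.ixx.shape
    return EigenField(vals[:, 0].reshape(shp), vals[:, 1].reshape(shp),
                      vals[:, 2].reshape(shp), h.grid)


def line_measure(e: EigenField, p: VesselnessParams) -> Volume3D:
    """Sato bright-line response from magnitude-sorted eigenvalues (>= 0)."""
    l1, l2, l3 = e.l1, e.l2, e.l3
    resp = np.zeros_like(l3)
    bright = (l2 < 0) & (l3 < 0)
    if np.any(bright):
        b1, b2, b3 = l1[bright], l2[bright], l3[bright]
        base = np.abs(b3) * (b2 / b3) ** p.gamma23
        factor = np.zeros_like(base)
        neg = b1 <= 0
        factor[neg] = (1.0 + b1[neg] / np.abs(b2[neg])) ** p.gamma12
        pos = (b1 > 0) & (b1 <= np.abs(b2) / p.alpha)
        factor[pos] = (1.0 - p.alpha * b1[pos] / np.abs(b2[pos])) ** p.gamma12
        resp[bright] = base * factor
    return Volume3D(resp, e.grid)


def multiscale_vesselness(vol: Volume3D, heart_mask: BinaryMask3D,
                          p: VesselnessParams = None) -> Volume3D:
    """Per-voxel maximum of the normalized line measure over scales, zero
    outside ``heart_mask``."""
    p = p or VesselnessParams()
    require_same_grid(vol, heart_mask)
    if heart_mask.count() == 0:
        raise PipelineError("heart mask is empty; nothing to enhance")
    best = np.zeros(vol.shape, np.float64)
    for sigma in p.sigmas_mm:
        resp = line_measure(eigenvalues_sorted(hessian_at_scale(vol, sigma)), p)
        np.maximum(best, resp.data, out=best)
        log.debug("vesselness scale %.2f mm: max response %.3g", sigma,
                  resp.data.max())
    best[~heart_mask.data] = 0.0
    return Volume3D(best, vol.grid)
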