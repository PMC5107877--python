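"""Statistical region growing with a heuristic bounds sweep.

Growth runs in two phases.  Phase 1 visits the seed points in order; a seed
already absorbed by the running region is skipped (the removal rule).  An
unabsorbed seed contributes the flood fill, over the chosen connectivity, of
voxels whose intensity lies in the confidence interval

    I = [m - v*d, m + v*d]

where m and d are the mean and population standard deviation over the seed
voxel plus its 26-neighbourhood.  Phase 2 then re-estimates m and d over the
*entire* current region, rebuilds the interval, and expands the region to
closure — repeating for a fixed number of refinement iterations or until a
pass adds nothing.

The bounds multiplier v is chosen by a sweep: grow at v0, v0+step, ...
recording the segmented voxel count N_i; an abrupt jump ("mutation") in N_i
marks the v at which the interval engulfs the myocardium, and the previous
grid value is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Literal, Tuple

import numpy as np
from scipy import ndimage

from .seeds import SeedSet
from .volumes import (BinaryMask3D, ParameterError, PipelineError, Volume3D,
                      require_same_grid)

log = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class GrowthParams:
    v: float = 1.0
    n_refinement_iterations: int = 5
    connectivity: int = 26
    min_std_hu: float = 1.0  # variance floor so uniform plateaus still grow

    def __post_init__(self):
        if self.v <= 0:
            raise ParameterError(f"v must be > 0, got {self.v}")
        if self.n_refinement_iterations < 0:
            raise ParameterError("n_refinement_iterations must be >= 0")
        if self.connectivity not in _STRUCTURES:
            raise ParameterError(
                f"connectivity must be one of {sorted(_STRUCTURES)}, "
                f"got {self.connectivity}")


@dataclass(frozen=True)
class IntensityInterval:
    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ParameterError(f"interval low {self.low} > high {self.high}")

    def contains(self, values: np.ndarray) -> np.ndarray:
        return (values >= self.low) & (values <= self.high)


@dataclass
class VSweepParams:
    v0: float = 1.0
    step: float = 0.1
    mutation_abs: float = 1e8          # absolute jump threshold, voxels
    mutation_frac: float = 0.5         # fraction of heart-ROI voxels
    mode: Literal["absolute", "relative"] = "relative"
    max_v: float = 5.0

    def __post_init__(self):
        if self.step <= 0 or self.mutation_abs <= 0 or self.mutation_frac <= 0:
            raise ParameterError("sweep step and mutation thresholds must be > 0")
        if self.mode not in ("absolute", "relative"):
            raise ParameterError(f"unknown sweep mode {self.mode!r}")


@dataclass
class VSweepResult:
    trace: List[Tuple[float, int]]
    selected_v: float
    terminated_by: Literal["mutation", "max_v"]
    selected_mask: BinaryMask3D


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def seed_statistics(vol: Volume3D, seed, connectivity: int = 26,
                    min_std_hu: float = 1.0) -> Tuple[float, float]:
    """Mean and population standard deviation over the seed voxel plus its
    neighbourhood (clipped at volume borders), std floored at ``min_std_hu``.

    The neighbourhood is the full 3x3x3 block for connectivity 26 and the
    corresponding subsets for 18/6.
    """
    index = seed.index if hasattr(seed, "index") else tuple(seed)
    if not vol.grid.contains_index(index):
        raise ParameterError(f"seed {index} out of bounds")
    k, j, i = index
    nz, ny, nx = vol.shape
    block = vol.data[max(0, k - 1):min(nz, k + 2),
                     max(0, j - 1):min(ny, j + 2),
                     max(0, i - 1):min(nx, i + 2)]
    if connectivity != 26:
        st = _STRUCTURES[connectivity]
        sl = st[max(0, 1 - k):, max(0, 1 - j):, max(0, 1 - i):]
        sl = sl[:block.shape[0], :block.shape[1], :block.shape[2]]
        values = block[sl]
    else:
        values = block.ravel()
    mean = float(np.mean(values))
    std = float(np.std(values))  # population std
    return mean, max(std, min_std_hu)


def confidence_interval(mean: float, std: float, v: float) -> IntensityInterval:
    """``[m - v*d, m + v*d]``."""
    if std < 0:
        raise ParameterError("std must be >= 0")
    if v <= 0:
        raise ParameterError("v must be > 0")
    return IntensityInterval(mean - v * std, mean + v * std)


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------

def _flood_component(eligible: np.ndarray, start_mask: np.ndarray,
                     structure: np.ndarray) -> np.ndarray:
    """Voxels of ``eligible | start_mask`` reachable from ``start_mask``
    (region voxels are always traversable)."""
    field_ = eligible | start_mask
    labels, n = ndimage.label(field_, structure=structure)
    if n == 0:
        return start_mask.copy()
    hit = np.unique(labels[start_mask])
    hit = hit[hit > 0]
    keep = np.isin(labels, hit)
    return keep & field_


def grow_from_seeds(vol: Volume3D, heart_mask: BinaryMask3D, seeds: SeedSet,
                    p: GrowthParams = None) -> BinaryMask3D:
    """Two-phase seeded statistical region growing confined to ``heart_mask``."""
    p = p or GrowthParams()
    grid = require_same_grid(vol, heart_mask)
    if len(seeds) == 0:
        raise PipelineError("empty seed set")
    structure = _STRUCTURES[p.connectivity]
    data = vol.data
    roi = heart_mask.data

    region = np.zeros(grid.shape, dtype=bool)

    # Phase 1: per-seed flood fill with seed-neighbourhood statistics.
    for s in seeds.seeds:
        k, j, i = s.index
        if region[k, j, i]:
            continue  # seed absorbed -> removed from the set
        # statistics always over the full 26-neighbourhood; p.connectivity
        # only governs the flood fill
        mean, std = seed_statistics(vol, s, 26, p.min_std_hu)
        iv = confidence_interval(mean, std, p.v)
        eligible = roi & iv.contains(data)
        start = np.zeros(grid.shape, dtype=bool)
        start[k, j, i] = True
        if eligible[k, j, i]:
            region |= _flood_component(eligible, start, structure)
        else:
            region[k, j, i] = True  # seed itself always belongs

    # Phase 2: refinement with whole-region statistics, expansion to closure.
    for _ in range(p.n_refinement_iterations):
        values = data[region]
        mean = float(np.mean(values))
        std = max(float(np.std(values)), p.min_std_hu)
        iv = confidence_interval(mean, std, p.v)
        eligible = roi & iv.contains(data)
        new_region = _flood_component(eligible, region, structure)
        if new_region.sum() == region.sum():
            break
        region = new_region

    if _touches_boundary(region, roi):
        log.warning("grown region touches the heart-mask boundary "
                    "(possible leakage)")
    return BinaryMask3D(region, grid)


def _touches_boundary(region: np.ndarray, roi: np.ndarray) -> bool:
    shell = roi & ~ndimage.binary_erosion(roi, border_value=0)
    return bool(np.any(region & shell))


def count_segmented(mask: BinaryMask3D) -> int:
    """Number of segmented voxels N."""
    return mask.count()


def v_sweep(vol: Volume3D, heart_mask: BinaryMask3D, seeds: SeedSet,
            sweep: VSweepParams = None,
            growth: GrowthParams = None) -> VSweepResult:
    """Sweep v over v0, v0+step, ... and stop at the mutation jump.

    The selected v is the last grid value *before* the jump; the returned
    mask is the segmentation grown at that v.  If no jump occurs by
    ``max_v`` the sweep terminates there with a warning.
    """
    sweep = sweep or VSweepParams()
    growth = growth or GrowthParams()
    if len(seeds) == 0:
        raise PipelineError("empty seed set")
    threshold = (sweep.mutation_abs if sweep.mode == "absolute"
                 else sweep.mutation_frac * heart_mask.count())

    trace: List[Tuple[float, int]] = []
    masks: List[BinaryMask3D] = []
    i = 0
    while True:
        v = sweep.v0 + i * sweep.step
        if v > sweep.max_v + 1e-9:
            selected = trace[-1][0]
            warnings.warn(f"no mutation detected up to max_v={sweep.max_v}; "
                          f"selecting v={selected:.3g}")
            return VSweepResult(trace, selected, "max_v", masks[-1])
        gp = GrowthParams(v=v, n_refinement_iterations=growth.n_refinement_iterations,
                          connectivity=growth.connectivity,
                          min_std_hu=growth.min_std_hu)
        mask = grow_from_seeds(vol, heart_mask, seeds, gp)
        n = count_segmented(mask)
        log.info("v-sweep: v=%.3g N=%d", v, n)
        if trace and n - trace[-1][1] > threshold:
            if len(trace) == 1:
                warnings.warn("mutation at the very first increment; "
                              "selecting v0")
            trace.append((v, n))
            return VSweepResult(trace, trace[-2][0], "mutation", masks[-1])
        trace.append((v, n))
        masks = [mask]  # keep only the most recent pre-jump mask
        i += 1
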