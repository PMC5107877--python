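"""Automatic seed-point detection: conservative thresholding plus 3D erosion.

Voxels are eligible when their original intensity is at least 120 HU *and*
they carry a positive vessel-enhancement response; a box erosion (default
4 x 4 in-plane, 3 across slices to match the coarser slice spacing) then
removes thin or noisy structures so every survivor lies well inside a
contrast-filled artery.  Even-sized kernel axes anchor at floor(d/2).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .volumes import (BinaryMask3D, Grid, GridPoint, NoSeedsError,
                      ParameterError, Volume3D, require_same_grid,
                      voxel_to_world)


@dataclass
class SeedDetectionParams:
    threshold_hu: float = 120.0
    erosion_kernel: Tuple[int, int, int] = (3, 4, 4)  # (dz, dy, dx)
    vesselness_floor: float = 0.0  # eligibility requires response > floor

    def __post_init__(self):
        k = tuple(int(d) for d in self.erosion_kernel)
        if any(d < 1 for d in k):
            raise ParameterError(f"erosion kernel dims must be >= 1, got {k}")
        self.erosion_kernel = k


@dataclass
class SeedSet:
    """Ordered, duplicate-free voxel indices consumed by region growing."""

    seeds: List[GridPoint]
    source_grid: Grid

    def __post_init__(self):
        idx = [tuple(s.index) for s in self.seeds]
        if len(set(idx)) != len(idx):
            raise ParameterError("duplicate seed indices")
        for i in idx:
            if not self.source_grid.contains_index(i):
                raise ParameterError(f"seed {i} out of bounds")

    def __len__(self):
        return len(self.seeds)

    def indices(self) -> np.ndarray:
        return np.array([s.index for s in self.seeds], dtype=int).reshape(-1, 3)


def threshold_mask(vol: Volume3D, response: Volume3D,
                   p: SeedDetectionParams) -> BinaryMask3D:
    """Voxel is 1 iff ``vol >= threshold_hu`` and ``response > vesselness_floor``."""
    grid = require_same_grid(vol, response)
    mask = (vol.data >= p.threshold_hu) & (response.data > p.vesselness_floor)
    return BinaryMask3D(mask, grid)


def erode(mask: BinaryMask3D, kernel: Tuple[int, int, int]) -> BinaryMask3D:
    """Binary erosion with a full box structuring element.

    A voxel survives iff the box, anchored at floor(d/2) per axis, fits
    entirely inside the mask.  Output is always a subset of the input.
    """
    k = tuple(int(d) for d in kernel)
    if any(d < 1 for d in k):
        raise ParameterError(f"kernel dims must be >= 1, got {k}")
    if k == (1, 1, 1):
        return BinaryMask3D(mask.data.copy(), mask.grid)
    out = ndimage.binary_erosion(mask.data, structure=np.ones(k, bool),
                                 border_value=0)
    return BinaryMask3D(out, mask.grid)


def extract_seeds(mask: BinaryMask3D) -> SeedSet:
    """Every surviving voxel becomes a seed, in raster order (k, then j, then i).

    Raises
    ------
    NoSeedsError
        If the mask is empty — the pipeline cannot proceed without seeds.
    """
    idx = np.argwhere(mask.data)
    if idx.shape[0] == 0:
        raise NoSeedsError("no seeds detected (empty mask after threshold/erosion)")
    seeds = [GridPoint(tuple(int(v) for v in row),
                       voxel_to_world(mask.grid, row)) for row in idx]
    return SeedSet(seeds, mask.grid)


def detect_seeds(vol: Volume3D, response: Volume3D,
                 p: SeedDetectionParams = None) -> SeedSet:
    """threshold → erode → extract, the full detection stage."""
    p = p or SeedDetectionParams()
    return extract_seeds(erode(threshold_mask(vol, response, p),
                               p.erosion_kernel))


# ---------------------------------------------------------------------------
# CSV interchange: header k,j,i,x_mm,y_mm,z_mm — one row per seed
# ---------------------------------------------------------------------------

def save_seeds_csv(seed_set: SeedSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["k", "j", "i", "x_mm", "y_mm", "z_mm"])
        for s in seed_set.seeds:
            world = s.world or voxel_to_world(seed_set.source_grid, s.index)
            w.writerow([*s.index, *(f"{v:.6f}" for v in world)])


def load_seeds_csv(path, grid: Grid) -> SeedSet:
    seeds = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            idx = (int(row["k"]), int(row["j"]), int(row["i"]))
            seeds.append(GridPoint(idx, voxel_to_world(grid, idx)))
    return SeedSet(seeds, grid)
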