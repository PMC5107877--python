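"""End-to-end orchestration: heart → enhancement → seeds → growing.

The pipeline is a pure function of (inputs, configuration, seed) and never
prompts: a missing required input is a startup error.  Each stage's output
can be persisted to an output directory for inspection or reuse.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import yaml

from .growing import (GrowthParams, VSweepParams, VSweepResult, grow_from_seeds,
                      v_sweep)
from .registration import RegistrationOptions, segment_heart
from .seeds import SeedDetectionParams, SeedSet, detect_seeds, save_seeds_csv
from .vesselness import VesselnessParams, multiscale_vesselness
from .volumes import (BinaryMask3D, ParameterError, PipelineError, Volume3D,
                      require_same_grid, save_volume)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameter blocks plus the master seed.

    Every block validates its own invariants on construction, before any
    stage runs.
    """

    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    seeds: SeedDetectionParams = field(default_factory=SeedDetectionParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    sweep: VSweepParams = field(default_factory=VSweepParams)
    rng_seed: int = 17

    def to_yaml(self, path) -> None:
        blocks = {name: asdict(getattr(self, name))
                  for name in ("registration", "vesselness", "seeds",
                               "growth", "sweep")}
        blocks["rng_seed"] = self.rng_seed
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(blocks), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, klass in (("registration", RegistrationOptions),
                            ("vesselness", VesselnessParams),
                            ("seeds", SeedDetectionParams),
                            ("growth", GrowthParams),
                            ("sweep", VSweepParams)):
            if name in raw:
                block = dict(raw[name])
                for key in ("step_sizes", "sigmas_mm", "erosion_kernel"):
                    if key in block and isinstance(block[key], list):
                        block[key] = tuple(block[key])
                kwargs[name] = klass(**block)
        if "rng_seed" in raw:
            kwargs["rng_seed"] = int(raw["rng_seed"])
        return cls(**kwargs)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


@dataclass
class SegmentationResult:
    vessel_mask: BinaryMask3D
    heart_mask: BinaryMask3D
    seeds: SeedSet
    sweep: VSweepResult
    response: Volume3D
    stage_timings: dict


def run_pipeline(volume: Volume3D,
                 atlases: Optional[Sequence] = None,
                 config: Optional[PipelineConfig] = None,
                 heart_mask: Optional[BinaryMask3D] = None,
                 out_dir: Optional[str] = None) -> SegmentationResult:
    """Execute the four stages in order on one patient volume.

    Either ``atlases`` (for multi-atlas heart extraction) or a precomputed
    ``heart_mask`` must be supplied; giving a heart mask skips stage 1 and
    produces results identical to a run whose stage 1 emitted that mask.
    """
    config = config or PipelineConfig()
    if atlases is None and heart_mask is None:
        raise ParameterError("either atlases or a precomputed heart mask "
                             "is required")
    timings = {}

    def _persist(name, obj):
        if out_dir is None:
            return
        os.makedirs(out_dir, exist_ok=True)
        path = os.path.join(out_dir, name)
        if isinstance(obj, BinaryMask3D):
            save_volume(Volume3D(obj.data.astype("uint8"), obj.grid), path)
        elif isinstance(obj, Volume3D):
            save_volume(obj, path)

    t0 = time.perf_counter()
    if heart_mask is None:
        reg = config.registration
        if reg.rng_seed != config.rng_seed:
            from dataclasses import replace
            reg = replace(reg, rng_seed=config.rng_seed)
        heart_mask = segment_heart(volume, atlases, reg)
    else:
        require_same_grid(volume, heart_mask)
        log.info("stage 1 skipped: heart mask supplied")
    timings["heart"] = time.perf_counter() - t0
    _persist("heart_mask.nii.gz", heart_mask)
    log.info("stage 1 done: heart mask %d voxels (%.1fs)",
             heart_mask.count(), timings["heart"])

    t0 = time.perf_counter()
    response = multiscale_vesselness(volume, heart_mask, config.vesselness)
    timings["enhance"] = time.perf_counter() - t0
    _persist("vesselness.nii.gz", response)
    log.info("stage 2 done: max response %.3g (%.1fs)", response.data.max(),
             timings["enhance"])

    t0 = time.perf_counter()
    seed_set = detect_seeds(volume, response, config.seeds)
    timings["seeds"] = time.perf_counter() - t0
    if out_dir is not None:
        save_seeds_csv(seed_set, os.path.join(out_dir, "seeds.csv"))
    log.info("stage 3 done: %d seeds (%.1fs)", len(seed_set), timings["seeds"])

    t0 = time.perf_counter()
    sweep = v_sweep(volume, heart_mask, seed_set, config.sweep, config.growth)
    timings["grow"] = time.perf_counter() - t0
    _persist("vessel_mask.nii.gz", sweep.selected_mask)
    if out_dir is not None:
        with open(os.path.join(out_dir, "sweep_trace.json"), "w") as fh:
            json.dump({"trace": [{"v": v, "n_voxels": n} for v, n in sweep.trace],
                       "selected_v": sweep.selected_v,
                       "terminated_by": sweep.terminated_by}, fh, indent=2)
    log.info("stage 4 done: selected v=%.2f, %d voxels (%.1fs)",
             sweep.selected_v, sweep.selected_mask.count(), timings["grow"])

    if not _subset(sweep.selected_mask, heart_mask):
        raise PipelineError("vessel mask escapes the heart mask")
    return SegmentationResult(sweep.selected_mask, heart_mask, seed_set,
                              sweep, response, timings)


def _subset(a: BinaryMask3D, b: BinaryMask3D) -> bool:
    import numpy as np
    return not np.any(a.data & ~b.data)
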