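# coroseg

Fully automated segmentation of coronary arteries from 3D cardiac CT
angiography (CTA), for researchers who need a transparent, testable
reference implementation of the classic four-stage recipe:

1. **Heart extraction** — multi-atlas segmentation: every atlas is aligned
   to the patient volume by a two-stage registration (affine on the mean
   squared intensity difference, then a cubic B-spline free-form deformation
   ascending a *localized* mutual-information measure), its heart label is
   propagated, and the labels are fused by strict majority voting.
2. **Vessel enhancement** — a 3D multiscale Hessian line filter.  At scale
   σ the image is convolved with Gaussian second derivatives; with the
   eigenvalues of the Hessian sorted by magnitude |λ₁| ≤ |λ₂| ≤ |λ₃|, a
   bright tube satisfies λ₁ ≈ 0, λ₂ ≈ λ₃ ≪ 0 and scores

       R = |λ₃| (λ₂/λ₃)^γ23 (1 + λ₁/|λ₂|)^γ12          (λ₁ ≤ 0)

   (Sato's line measure; zero for dark, planar, or blob-like structure).
   Responses are σ²-normalized and maximized over scales 0.5–3 mm.
3. **Seed detection** — voxels with intensity ≥ 120 HU *and* positive
   enhancement response, eroded by a 4 × 4 × 3 box so every surviving voxel
   lies well inside a contrast-filled artery.  Every survivor is a seed.
4. **Statistical region growing with a heuristic bounds sweep** — each seed
   contributes a 26-connected flood fill of voxels whose intensity lies in
   the confidence interval **I = [m − v·d, m + v·d]**, where m and d are the
   mean and standard deviation over the seed's 26-neighbourhood; the region
   is then refined for 5 iterations with whole-region statistics.  The
   bounds multiplier v is selected automatically: grow at v = 1.0, 1.1, …
   and record the segmented voxel count N(v); the first abrupt jump
   ("mutation") marks the v at which the interval engulfs the myocardium,
   and the preceding grid value is selected.

No step needs manual interaction.  Because clinical CTA with expert
annotations cannot ship with a library, the package includes a seeded
phantom generator (`coroseg.phantom`) that builds CTA-like volumes — lung
background, myocardium ellipsoid, adjacent blood pool, curved
contrast-filled tubes with optional stenoses — together with gold-standard
heart and vessel masks, plus synthetic atlas sets with known deformations.
Everything below runs on those phantoms.

## Worked example

```python
import coroseg as cs

spec = cs.default_phantom_spec(noise_sd_hu=0.0, rng_seed=0)
volume, heart_gold, vessel_gold = cs.make_cardiac_phantom(spec)

cfg = cs.PipelineConfig(rng_seed=17)
result = cs.run_pipeline(volume, config=cfg, heart_mask=heart_gold)

report = cs.evaluate(result.vessel_mask, vessel_gold)
print(f"seeds={len(result.seeds)}  selected v={result.sweep.selected_v:.1f}")
print(f"DICE={report.dice:.4f}  MSD={report.msd_mm:.3f} mm  "
      f"MAXSD={report.maxsd_mm:.3f} mm")
```

prints

```
seeds=13426  selected v=2.7
DICE=0.9952  MSD=0.013 mm  MAXSD=0.400 mm
```

All 13 426 automatically detected seeds fall inside the gold tubes.  The
sweep trace (`result.sweep.trace`) stays flat around ~26 800 voxels until
v = 2.8, where the interval reaches the 60 HU myocardium and the count
jumps tenfold — so v = 2.7 is selected, giving a segmentation that overlaps
the gold tubes at DICE 0.995 with sub-voxel surface error (voxel diagonal
0.62 mm).

The same stages are available from the shell:

```sh
coroseg phantom --out-dir ph --noise-sd 0
coroseg run --input ph/volume.nii.gz --heart-mask ph/heart_gold.nii.gz \
            --out-dir out --seed 17
coroseg eval --seg out/vessel_mask.nii.gz --gold ph/vessel_gold.nii.gz \
             --out report.json
```

(`coroseg heart --atlas-dir …` replaces `--heart-mask` when atlas
image/label pairs are available.)

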