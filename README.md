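# pssmap

Probabilistic sweet-spot mapping for deep brain stimulation (DBS)
stimulation-test data.

During DBS surgery for tremor, stimulation is tested at many positions
along the implantation tracts, and each test is scored on a discrete
improvement scale (0/25/50/75/100 %). Simulating the electric field (EF)
of every test and thresholding it at 0.2 V/mm gives a volume of tissue
activated (VTA) labelled with its improvement score; stacking many
labelled VTAs on a common grid lets one ask, voxel by voxel, *does
stimulating this voxel produce good improvement?* The voxels that pass
are the **probabilistic sweet spot (PSS)** — a candidate stimulation
target. The answer, however, depends heavily on the statistical criterion
used. `pssmap` implements the full comparison pipeline:

- **Voxel-wise maps** — for each voxel with n ≥ 3 observations:
  one-sided one-sample *t*-test and Wilcoxon signed-rank test of
  H₁: improvement ≥ 75 % (exact, tie-aware, Pratt zeros); a directional
  Bayesian test reporting BF₁₀ = [P(μ≥75|x)/P(μ<75|x)] / [P(μ≥75)/P(μ<75)]
  under an encompassing Normal(75, 25) prior; and a per-voxel linear
  mixed model improvement ~ EF with patient random effects (select
  slope > 0, p < 0.05).
- **Type-I-error corrections** for the t and Wilcoxon maps:
  Benjamini–Hochberg FDR, and a voxel-wise nonparametric permutation
  correction (labels shuffled across records, corrected p = fraction of
  permuted p-values ≤ the true p; corrected p ≥ 0.05 discards the voxel).
- **Extraction** — significant voxels (p < 0.05 strict, BF₁₀ ≥ 10
  inclusive) → frequency masks (discard voxels activated in < 25 % of
  patients or by < 10 % of the maximum VTA count) → removal of connected
  components under 8 voxels (1 mm³).
- **Evaluation** — volumes, Dice overlaps, centroids;
  leave-one-patient-out correlation between VTA–PSS overlap and
  improvement (Spearman, 95th-percentile trimming); consistency of the
  fold-wise PSS (volume CV = 100·std/mean, pairwise Dice, centroid
  distances normalized by the larger equivalent-sphere diameter); ANOVA/
  Tukey or Kruskal–Wallis comparison between methods.
- **Synthetic cohorts** — a first-class generator emulating the
  intra-operative protocol (2 tracts 2 mm apart, 14 mm span in 1 mm
  steps, 0.2 mA amplitude ramp, motor-threshold recording, 23 patients,
  ~15 ± 6 stimulations each) driven by a latent ellipsoidal effective
  region, so every stage is testable without clinical data.

It is aimed at researchers developing or auditing probabilistic
stimulation mapping workflows, who need reference implementations with
exact conventions, oracle-tested statistics and reproducible synthetic
benchmarks.

## Worked example

```python
import numpy as np
import pssmap as pm

# strong-signal synthetic cohort with a known 2.5 mm spherical target
cohort, gt_mask = pm.generate_cohort(
    pm.strong_signal_config(seed=1), pm.recovery_ground_truth())
stack = pm.build_stack(cohort, threshold=0.2)
cfg = pm.RunConfig(seed=1)

for spec in (pm.MethodSpec("t", "perm"),      # TPerm
             pm.MethodSpec("wilcoxon", "perm"),  # WPerm
             pm.MethodSpec("bayes")):          # B
    pss = pm.compute_pss(stack, spec, cfg)
    print(f"{spec.label:5s} volume={pss.volume_mm3:6.1f} mm^3  "
          f"dice_vs_truth={pm.dice(pss.mask, gt_mask):.3f}  "
          f"centroid_err={np.linalg.norm(pm.centroid_mm(pss.mask, cohort.grid) - pm.centroid_mm(gt_mask, cohort.grid)):.2f} mm")
```

prints

```
TPerm volume= 146.8 mm^3  dice_vs_truth=0.559  centroid_err=0.10 mm
WPerm volume= 148.5 mm^3  dice_vs_truth=0.568  centroid_err=0.09 mm
B     volume= 155.0 mm^3  dice_vs_truth=0.569  centroid_err=0.08 mm
```

Each line is one extracted sweet spot: all three methods recover a
~150 mm³ cluster containing the 65 mm³ latent target (Dice ≈ 0.56 — the
PSS is always somewhat larger than the truth, a halo the width of the
high-scoring VTAs), with centroids within 0.1 mm of the true centre. The
same run on a no-effect cohort (`pm.null_ground_truth(level=25)`) yields
empty sweet spots.

The same pipeline is available from the shell:

```bash
pssmap generate --seed 1 --out cohort/
pssmap run      --cohort cohort/ --seed 1 --out results/
pssmap loocv    --cohort cohort/ --seed 1 --out results/
pssmap sensitivity --cohort cohort/ --seed 1 --out results/
pssmap perm-stability --cohort cohort/ --counts 100,200,300 --seed 1 --out results/
```

Cohorts are a CSV table plus one NIfTI EF volume per stimulation and a
JSON sidecar; all outputs (PSS masks, reports, resolved configs) are
NIfTI + JSON.

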