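# Methods

`pssmap` computes probabilistic sweet spots (PSS) from stimulation-test
data: given many electric-field (EF) simulations, each labelled with the
tremor-improvement score its stimulation produced, it finds the voxels
whose improvement distribution supports "good or excellent" benefit, and
evaluates how robustly different statistical criteria find them. This note
records the models, conventions and numerical choices behind each stage,
and what the synthetic study conditions do and do not show.

## Data model

All volumes in an analysis live on one rectilinear grid (default 48³
voxels of 0.5 mm, a 24 mm cube centred on the surgical target); voxel
indices are 0-based, world coordinates in mm via the NIfTI affine, and a
voxel is wholly in or out of any mask. One cohort holds one hemisphere.
A stimulation record is the motor threshold of one tested position: the
lowest current amplitude (mA) at which the position's best improvement
score was observed, with that score in percent on the discrete clinical
scale {0, 25, 50, 75, 100}. The volume of tissue activated (VTA) is the
EF-norm field thresholded at 0.2 V/mm; the comparison is inclusive
(values *lower than* the threshold are discarded, so equality is kept).

## Voxel stack

EF volumes are stacked along a fourth dimension: each voxel collects one
(EF, improvement, patient) observation per record whose EF reaches the
threshold there. Two frequency maps support masking — `n_map` (number of
covering stimulations) and `npat_map` (number of distinct covering
patients). An auxiliary `wimp_map` (mean improvement weighted by
EF/amplitude, penalizing coverage bought with high currents) is computed
and exported but takes no part in masking, which uses raw counts only:
the masking rules are phrased in numbers of patients and of VTAs, and
counts are the only reading consistent with that.

## Statistical maps

All four methods test voxels against the clinical threshold of 75 %
("good") improvement, with a minimum of `min_n = 3` observations per
voxel; voxels below that are marked invalid rather than given p = 1, so
multiplicity corrections do not count them. A variance cannot be
meaningfully supported by two points.

**t map.** One-sided one-sample t-test of H1: mean ≥ 75. Zero-variance
samples are common on a discrete scale and carry real evidence, so they
follow a fixed convention: p = 0 if the sample mean exceeds 75, p = 1
otherwise.

**Wilcoxon map.** One-sided signed-rank test, zeros handled by the Pratt
rule (zeros are ranked with the rest, then dropped), tied |differences|
get midranks. For up to 25 non-zero differences the null distribution is
enumerated exactly by convolution over the rank multiset; beyond that a
normal approximation with tie-aware variance and continuity correction is
used. Exactness buys reproducibility; its price is conservativeness — on
a 5-level scale the achievable p-values are sparse, and small voxels
(n ≤ 8 with many zeros) often cannot reach p < 0.05 at all. This is why
the Wilcoxon map's empirical rejection rate at the null boundary is ~2 %
rather than the nominal 5 % (see *Study conditions* below); the t map,
whose statistic varies continuously, sits at ~4.6 %.

**Bayesian map.** A directional Bayes factor: BF₁₀ = posterior odds of
μ ≥ 75 versus μ < 75, divided by the prior odds, under an encompassing
prior shared by both hypotheses. The location prior is Normal(75, 25) —
centred on the tested threshold so that a sample symmetric about 75 gives
BF₁₀ = 1 exactly (and the prior-odds term is 1), with a scale of one
rating-scale step; the response scale σ carries a half-Cauchy(25) prior,
floored at 1 rating point because the observations are discrete (an
unbounded σ → 0 spike would otherwise make all-equal samples degenerate).
The default backend is deterministic 2-D quadrature (321 μ-nodes placed
symmetrically about 75 with a node at 75 whose weight splits evenly
between the half-lines, 41 log-spaced σ-nodes), so Bayesian maps need no
seed. A seeded ensemble-MCMC backend (emcee; 24 walkers, 1500 steps, 500
burn-in) serves as a cross-check. Because μ | σ is conjugate-normal under
the normal location prior, the backend Rao-Blackwellizes the directional
probability — the exact conditional tail probability is averaged over the
σ chain — which resolves tail masses a raw μ-sample count cannot;
non-normal priors fall back to counting μ samples with ½-count smoothing.
The two backends agree within 10 % on log BF over moderate evidence
(|log BF| ≲ 4.5). Voxels with BF₁₀ ≥ 10 (inclusive) count as sweet-spot
evidence. A prior-sensitivity helper recomputes BF₁₀ under normal, Cauchy
and Student-t priors and reports the maximal pairwise BF ratio per
sample.

**Mixed-model map.** Per voxel, improvement ~ intercept + slope·EF with
per-patient random intercepts and slopes (REML, lbfgs); on convergence
failure the model falls back to random intercepts only, then to ordinary
least squares, with the ladder recorded in the map metadata. The
statistic is the two-sided p of the fixed slope; selection additionally
requires slope > 0. Whether the original selection rule used a one- or
two-sided p is not documented; two-sided plus the sign rule is the
stricter reading. Mixed models are fitted only on candidate voxels that
could survive the frequency masks — at ~50 ms per voxel a whole-grid fit
is minutes-to-hours, and masked voxels cannot enter the PSS anyway.

## Type-I-error corrections (t and Wilcoxon maps only)

**BH-FDR** over the valid voxels only, at q = 0.05; `corrected_p` holds
the monotone BH-adjusted p-values and significance follows the step-up
rule exactly.

**Voxel-wise permutation correction.** Improvement labels are permuted
across records (default 200 replicates) while the EF geometry stays
fixed; the map is recomputed per replicate, and a voxel's corrected p is
the fraction of permuted p-values at or below its true p — exactly
count/n, matching the boundary rule that corrected p ≥ 0.05 is discarded
(a (count+1)/(n+1) variant is available behind a flag). The correction
*removes* voxels from the thresholded map: a voxel is retained only if
its uncorrected p < 0.05 *and* its corrected p < 0.05. This matters:
corrected p-values are rank-based and therefore near-uniform even at
voxels whose absolute evidence is hopeless, so without the intersection a
no-effect cohort would keep ~1–2 % of voxels. The default permutation
scheme is a single global shuffle over all records per replicate, which
realizes exchange both between and within leads; a lead-stratified mode
(shuffling within each lead only) is behind a flag. One RNG stream per
run; the seed is recorded in the map metadata.

## Sweet-spot extraction

Fixed order: significance threshold → frequency masks → cluster filter.
P-value maps threshold at p < 0.05 (strict), BF maps at BF₁₀ ≥ 10
(inclusive), mixed-model maps at p < 0.05 with positive slope. The
frequency masks discard voxels activated in less than 25 % of patients or
covered by fewer VTAs than 10 % of the maximum stimulation count — both
strict-less on exact fractions, no rounding of patient counts. Connected
components smaller than 8 voxels (1 mm³ at 0.5 mm resolution; the voxel
equivalent is derived from the grid for other resolutions) are removed,
with 26-connectivity by default (6/18 available and recorded in
provenance). The order matters and is asserted by a fixture in which a
9-voxel cluster loses 2 voxels to masking and must then fall to the
cluster rule. An empty sweet spot is a legal outcome — FDR-corrected
variants routinely reject nothing — and every extraction logs stage-wise
voxel counts so such outcomes are auditable.

## Evaluation

Volumes are voxel counts times voxel volume; overlap is the Dice
coefficient (0 when both masks are empty); centroids are means of voxel-
centre world coordinates. Leave-one-patient-out cross-validation builds
the sweet spot from n−1 patients and pairs each left-out VTA's Dice
overlap with its improvement score; pairs pool over folds, pairs at or
above the pooled 95th percentile of overlap are trimmed (computed on the
pooled distribution, not per fold), and Spearman's ρ is taken on the
rest. Folds with an empty sweet spot contribute zero-overlap pairs by
default so that methods failing on many folds are visibly penalized; a
drop-fold mode exists. Consistency of the fold-wise sweet spots is
summarized by the volume coefficient of variation (100·std/mean, sample
std with n−1 — the convention is recorded in the result), all pairwise
Dice values, and pairwise centroid distances normalized by the larger
*equivalent-sphere* diameter (6V/π)^(1/3) of the pair — robust for ragged
voxel clusters; a maximum-extent (Feret) diameter mode is behind a flag.
Between-method comparison checks normality (Shapiro–Wilk) and
homoscedasticity (Levene) at 0.05, runs one-way ANOVA with Tukey post-hoc
when both hold and the ANOVA is significant, otherwise Kruskal–Wallis
with no default post-hoc (the omission is noted in the result).

## Synthetic study conditions

The generator emulates the intra-operative protocol: 23 patients, two
parallel tracts 2 mm apart (central tract through the target), 15
positions per tract over 14 mm in 1 mm steps (depths −10 to +4 mm), an
amplitude ramp in 0.2 mA steps, and ~15 ± 6 explored positions per
patient. The EF of a stimulation is an idealized inverse-square point
source EF = g·I/max(r², r_min²) with r_min half a voxel diagonal and
g = 0.8 calibrated so that 1 mA gives a 2 mm VTA radius at the 0.2 V/mm
threshold — enough realism for amplitude-monotone, sensibly sized VTAs,
nothing more. Improvement is driven by a latent ellipsoidal effective
region: latent = 25 + 75·coverage + patient effect + noise, where
coverage is the covered fraction of the ellipsoid, the patient effect is
drawn once per patient (SD 10) and noise once per position (SD 15); the
latent value is clamped to [0, 100] and snapped to the nearest rating
level, ties up (62.5 → 75). The ramp is simulated through the coverage
curve; since the latent response is non-decreasing in amplitude, the best
score sits at the top of the ramp and the motor threshold is the lowest
amplitude whose snapped score equals it. When the snapped profile is flat
along the whole ramp there is no best-improvement event to anchor a
threshold, and the recorded amplitude is drawn uniformly from the tested
ramp instead — without this, every ineffective position would degenerate
to 0.2 mA and contribute an unrealistically tiny VTA.

Defaults were calibrated once so the full-scale cohort reproduces the
emulated protocol's moments (mean improvement ≈ 55–65 %, SD ≈ 30–34, ~330
records): ellipsoid centre (1.0, 1.5, −3.0) mm, semi-axes 2.5 mm,
amplitude cap 5.0 mA. Two further presets define the study conditions
used by the tests and the acceptance script:

- **Boundary null** (`null_config` + `null_ground_truth()`): improvement
  independent of position, centred exactly at the 75 % testing threshold,
  patient effect 0 and noise SD 12 — at that spread the snapped response
  occupies {50, 75, 100} symmetrically (larger spreads leak mass to the
  25-level whose +125 mirror is clamped at 100, biasing the mean below
  the boundary). This is where a one-sided test's nominal level applies.
  Single-cohort rejection fractions are dominated by the shared-label
  fluctuation of ~330 records, so the level is estimated as a mean over
  30 seeds.
- **No-effect null** (`null_ground_truth(level=25)`): everyone stays at
  background; used for the end-to-end false-positive check (the
  permutation-corrected, masked, clustered sweet spot should be empty).
- **Strong signal** (`strong_signal_config` + `recovery_ground_truth()`):
  patient SD 5, noise SD 5, amplitude cap 3.0 mA (the ramp protocol's
  stated top), ellipsoid centre (1.0, 0.0, −3.0) — used for recovery and
  concordance runs. Recovered sweet spots are still systematically larger
  than the latent ellipsoid (a halo the width of the high-scoring VTAs'
  reach), which bounds attainable Dice at roughly 0.5–0.6.

What the synthetic conditions do **not** emulate: tissue heterogeneity
and anisotropy, electrode geometry, rater variability structure, side
effects, registration error, or any estimate of the clinical
data-generating process — the response model is a stand-in with the
statistical features the mapping methods assume (effect gradient, patient
clustering, discreteness). Passing tests demonstrate correctness and
calibration of the *statistics* under those features, not clinical
validity of any particular sweet spot.

## Known limitations

- The exact Wilcoxon map is conservative on the discrete scale (see
  above); its boundary-null rejection rate is ~2 %, not 5 %. This is a
  property of exact rank tests under heavy ties, not an implementation
  artifact — the brute-force enumeration oracle agrees to 1e-12.
- Whole-grid mixed-model maps are expensive (~50 ms/voxel); they are
  restricted to mask-surviving candidates.
- The MCMC Bayes backend with a non-normal prior falls back to counting
  μ samples and cannot resolve |log BF| beyond the chain's minority-tail
  resolution; the quadrature backend is the reference throughout.
- LOOCV Spearman correlations on desk-scale cohorts carry wide
  uncertainty; the pooled trimming rule can exclude all pairs when the
  overlap distribution is nearly constant, in which case trimming is
  skipped and noted.

## Problem sizes

Default analyses run on the full 48³ grid with ~330 records and 200
permutations. Unit tests use 6-patient cohorts on 32³ grids with short
tracts; the type-I study averages 30 boundary-null cohorts; recovery and
concordance use full-scale strong-signal cohorts. These sizes were chosen
to keep every property measurable at desk scale while the statistics
remain in their asymptotically relevant regimes.
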