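"""Synthetic stimulation-test cohorts with a known ground-truth sweet spot.

The generator emulates an intra-operative exploration protocol: per patient
a semi-electrode with two parallel tracts (2 mm apart) tests positions over
a 14 mm span in 1 mm steps; at each position the current is ramped in
0.2 mA increments and the motor threshold — the lowest amplitude attaining
the position's best improvement score — is kept as the single record.

The electric field of a stimulation is an idealized inverse-square point
source with a near-field clamp, calibrated so a 1 mA pulse produces a VTA
radius of ~2 mm at the 0.2 V/mm activation threshold. Tremor improvement is
driven by how much of a latent ellipsoidal "true" sweet spot the VTA
covers, plus a patient-level random intercept and per-position noise, then
snapped to the discrete clinical rating scale {0, 25, 50, 75, 100}.

Nothing here is an estimate of any clinical data-generating process; the
response model is a stand-in with just enough structure (effect gradient,
patient clustering, discreteness) to exercise the mapping statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort_io import (
    Cohort,
    CohortValidationError,
    EFVolume,
    StimulationRecord,
    VoxelGrid,
)

__all__ = [
    "GroundTruth",
    "SimConfig",
    "SCALE_LEVELS",
    "snap_to_scale",
    "ef_point_source",
    "vta_coverage",
    "improvement_response",
    "generate_cohort",
    "default_ground_truth",
    "null_ground_truth",
    "recovery_ground_truth",
    "strong_signal_config",
    "null_config",
]

#: The discrete clinical rating scale (percent improvement).
SCALE_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)

#: EF activation threshold in V/mm used to binarize EF volumes into VTAs.
DEFAULT_EF_THRESHOLD = 0.2


@dataclass(frozen=True)
class GroundTruth:
    """Latent ellipsoidal effective region driving the synthetic response.

    ``max_effect`` is the expected improvement (%) at full VTA coverage of
    the ellipsoid, ``background_effect`` the expectation at zero coverage.
    Setting them equal yields a null cohort whose improvement is
    independent of stimulation position.
    """

    center_mm: tuple[float, float, float] = (1.0, 1.5, -3.0)
    semi_axes_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    max_effect: float = 100.0
    background_effect: float = 25.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise CohortValidationError("ground-truth semi-axes must be positive")
        if self.background_effect > self.max_effect:
            raise CohortValidationError("background_effect must not exceed max_effect")

    @property
    def is_null(self) -> bool:
        return self.max_effect == self.background_effect

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        """Binary voxel mask of the ellipsoid on ``grid``."""
        xyz = grid.voxel_centers_mm()
        c = np.asarray(self.center_mm)
        a = np.asarray(self.semi_axes_mm)
        return np.sum(((xyz - c) / a) ** 2, axis=-1) <= 1.0


def default_ground_truth() -> GroundTruth:
    """Ellipsoid centred between the two tracts, mid-exploration depth."""
    return GroundTruth()


def null_ground_truth(level: float = 75.0) -> GroundTruth:
    """Flat response field: expected improvement ``level`` everywhere.

    ``level`` defaults to the 75 % testing threshold so the one-sided maps
    are evaluated at the boundary of their null hypothesis, where the
    nominal type-I error rate applies.
    """
    return GroundTruth(max_effect=level, background_effect=level)


@dataclass(frozen=True)
class SimConfig:
    """Protocol geometry, EF calibration and response-noise parameters.

    Defaults mirror the emulated protocol: 23 patients, 15 +/- 6
    stimulations each on 2 tracts 2 mm apart spanning 14 mm in 1 mm steps
    (depths -10..+4 mm relative to target), amplitudes ramped in 0.2 mA
    steps up to 5.0 mA, on a 48^3 grid of 0.5 mm voxels.
    """

    n_patients: int = 23
    stims_per_patient_mean: float = 15.0
    stims_per_patient_sd: float = 6.0
    tract_span_mm: float = 14.0
    tract_step_mm: float = 1.0
    tract_offset_mm: float = 2.0
    depth_min_mm: float = -10.0
    depth_max_mm: float = 4.0
    amplitude_step_mA: float = 0.2
    amplitude_max_mA: float = 5.0
    ef_gain: float = 0.8  # V/mm at 1 mm from a 1 mA source => EF(2 mm, 1 mA) = 0.2
    ef_threshold: float = DEFAULT_EF_THRESHOLD
    patient_sd: float = 10.0
    noise_sd: float = 15.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise CohortValidationError("n_patients must be positive")
        if self.stims_per_patient_mean <= 0 or self.stims_per_patient_sd < 0:
            raise CohortValidationError("stimulations-per-patient parameters must be positive")
        if self.amplitude_step_mA <= 0 or self.amplitude_max_mA < self.amplitude_step_mA:
            raise CohortValidationError("invalid amplitude ramp")
        if self.depth_max_mm - self.depth_min_mm != self.tract_span_mm:
            raise CohortValidationError("depth range must match tract span")

    def make_grid(self) -> VoxelGrid:
        return VoxelGrid.centered(self.grid_shape, self.voxel_size_mm)

    @property
    def depths_mm(self) -> np.ndarray:
        n = int(round(self.tract_span_mm / self.tract_step_mm)) + 1
        return self.depth_min_mm + self.tract_step_mm * np.arange(n)

    @property
    def amplitudes_mA(self) -> np.ndarray:
        n = int(round(self.amplitude_max_mA / self.amplitude_step_mA))
        return self.amplitude_step_mA * np.arange(1, n + 1)

    def tract_positions(self) -> list[tuple[str, float, np.ndarray]]:
        """All (tract_id, depth, xyz-mm) stimulation positions of one lead.

        The central tract runs through the target (x = 0); the parallel
        tract is offset laterally by ``tract_offset_mm``.
        """
        out = []
        for tract, x in (("central", 0.0), ("parallel", self.tract_offset_mm)):
            for depth in self.depths_mm:
                out.append((tract, float(depth), np.array([x, 0.0, float(depth)])))
        return out


def null_config(seed: int, **overrides) -> SimConfig:
    """Configuration for type-I-error runs: no patient effect, so voxel
    samples are i.i.d. draws of the flat response.

    ``noise_sd`` defaults to 12 here: at that spread the snapped response
    at the 75 % boundary occupies {50, 75, 100} almost exclusively, so the
    discrete distribution is symmetric about the tested threshold (larger
    spreads leak mass into the 25-level whose +125 mirror is clamped to
    100, biasing the mean below the boundary)."""
    overrides.setdefault("patient_sd", 0.0)
    overrides.setdefault("noise_sd", 12.0)
    return SimConfig(seed=seed, **overrides)


def strong_signal_config(seed: int, **overrides) -> SimConfig:
    """Low-noise configuration for parameter-recovery runs.

    The amplitude ramp is capped at 3 mA (the ramp protocol's stated top)
    so motor-threshold VTAs stay compact around the effective region.
    """
    overrides.setdefault("patient_sd", 5.0)
    overrides.setdefault("noise_sd", 5.0)
    overrides.setdefault("amplitude_max_mA", 3.0)
    return SimConfig(seed=seed, **overrides)


def recovery_ground_truth() -> GroundTruth:
    """Ground truth for recovery runs: a 2.5 mm-radius sphere centred
    between the tracts at mid-exploration depth, 1 mm lateral of each."""
    return GroundTruth(center_mm=(1.0, 0.0, -3.0), semi_axes_mm=(2.5, 2.5, 2.5))


def snap_to_scale(value, levels=SCALE_LEVELS):
    """Clamp to [0, 100] and snap to the nearest rating level, ties up.

    With the default 25-point levels the breakpoints are at the midpoints:
    62.4 -> 50, 62.5 -> 75 (tie rounds up), 63 -> 75.
    """
    step = levels[1] - levels[0]
    value = np.clip(np.asarray(value, dtype=float), levels[0], levels[-1])
    snapped = np.floor(value / step + 0.5) * step
    return np.clip(snapped, levels[0], levels[-1])


def ef_point_source(source_mm, amplitude_mA: float, grid: VoxelGrid,
                    ef_gain: float = 0.8) -> np.ndarray:
    """Idealized EF-norm field of a point source: gain * I / max(r^2, r_min^2).

    ``r`` is the mm distance from the voxel centre to the source and
    ``r_min`` half the voxel diagonal (near-field clamp). Deterministic.
    """
    if amplitude_mA < 0:
        raise CohortValidationError("amplitude_mA must be >= 0")
    source = np.asarray(source_mm, dtype=float)
    if not grid.contains_mm(source):
        raise CohortValidationError(f"source {source.tolist()} lies outside the grid")
    r2 = np.sum((grid.voxel_centers_mm() - source) ** 2, axis=-1)
    r_min = 0.5 * np.linalg.norm(grid.voxel_size_mm)
    return ef_gain * amplitude_mA / np.maximum(r2, r_min**2)


def vta_coverage(vta_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Fraction of the ground-truth region covered by the VTA."""
    n_gt = int(gt_mask.sum())
    if n_gt == 0:
        return 0.0
    return float(np.logical_and(vta_mask, gt_mask).sum() / n_gt)


def improvement_response(vta_mask: np.ndarray, gt: GroundTruth, gt_mask: np.ndarray,
                         patient_effect: float, rng: np.random.Generator | None = None,
                         noise_sd: float = 0.0) -> float:
    """Discrete improvement score of one stimulation.

    latent = background + (max - background) * coverage + patient_effect + noise,
    clamped to [0, 100] and snapped to the nearest rating level (ties up).
    """
    cov = vta_coverage(vta_mask, gt_mask)
    noise = float(rng.normal(0.0, noise_sd)) if rng is not None and noise_sd > 0 else 0.0
    latent = (gt.background_effect
              + (gt.max_effect - gt.background_effect) * cov
              + patient_effect + noise)
    return float(snap_to_scale(latent))


def _activation_amplitudes(source_mm: np.ndarray, gt_xyz: np.ndarray,
                           cfg: SimConfig, r_min: float) -> np.ndarray:
    """Per ground-truth voxel, the smallest amplitude whose VTA reaches it.

    With EF = gain * I / max(r^2, r_min^2), a voxel at distance r activates
    once I >= threshold * max(r^2, r_min^2) / gain. Sorted ascending, so
    coverage(I) is a searchsorted lookup.
    """
    r2 = np.sum((gt_xyz - source_mm) ** 2, axis=-1)
    amps = cfg.ef_threshold * np.maximum(r2, r_min**2) / cfg.ef_gain
    return np.sort(amps)


def generate_cohort(cfg: SimConfig, gt: GroundTruth | None = None,
                    ) -> tuple[Cohort, np.ndarray]:
    """Generate a cohort and the ground-truth mask, reproducibly from cfg.seed.

    Per patient a random subset of the 2 x 15 lead positions is explored
    (subset size ~ Normal(mean, sd), clipped to [3, all]). At each position
    the amplitude ramp is simulated through the coverage curve: the latent
    response is non-decreasing in amplitude, the best score is attained at
    the top of the ramp and the motor threshold is the lowest amplitude
    whose snapped score equals it. Only that record (and its EF volume) is
    kept — one record per explored position.
    """
    if cfg.seed is None:
        raise CohortValidationError("SimConfig.seed is mandatory for generation")
    gt = gt or default_ground_truth()
    grid = cfg.make_grid()
    rng = np.random.default_rng(cfg.seed)

    gt_mask = gt.mask(grid)
    gt_xyz = grid.voxel_centers_mm()[gt_mask]
    if gt_xyz.size == 0:
        raise CohortValidationError("ground-truth ellipsoid contains no voxels on this grid")
    r_min = 0.5 * np.linalg.norm(grid.voxel_size_mm)
    positions = cfg.tract_positions()
    act_amps = [_activation_amplitudes(p[2], gt_xyz, cfg, r_min) for p in positions]
    amps = cfg.amplitudes_mA
    effect_span = gt.max_effect - gt.background_effect
    n_gt = len(gt_xyz)

    records: list[StimulationRecord] = []
    volumes: dict[str, EFVolume] = {}
    for p_idx in range(cfg.n_patients):
        patient_id = f"P{p_idx:02d}"
        patient_effect = rng.normal(0.0, cfg.patient_sd) if cfg.patient_sd > 0 else 0.0
        n_stims = int(round(rng.normal(cfg.stims_per_patient_mean, cfg.stims_per_patient_sd)))
        n_stims = int(np.clip(n_stims, 3, len(positions)))
        explored = np.sort(rng.choice(len(positions), size=n_stims, replace=False))
        for pos_idx in explored:
            tract, depth, source = positions[pos_idx]
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            coverage = np.searchsorted(act_amps[pos_idx], amps, side="right") / n_gt
            latent = gt.background_effect + effect_span * coverage + patient_effect + noise
            scores = snap_to_scale(latent)
            best = scores[-1]  # scores are non-decreasing along the ramp
            if scores[0] == best:
                # Flat score profile: no best-improvement event anchors the
                # motor threshold, so the recorded amplitude is an arbitrary
                # point of the tested ramp.
                thr_idx = int(rng.integers(len(amps)))
            else:
                thr_idx = int(np.argmax(scores >= best))
            amplitude = round(
                round(amps[thr_idx] / cfg.amplitude_step_mA) * cfg.amplitude_step_mA, 6)
            ref = f"{patient_id}_{tract}_d{depth:+05.1f}"
            ef = ef_point_source(source, amplitude, grid, cfg.ef_gain).astype(np.float32)
            records.append(StimulationRecord(
                patient_id=patient_id,
                lead_id=f"{patient_id}_lead",
                tract_id=tract,
                depth_mm=depth,
                amplitude_mA=amplitude,
                improvement_pct=float(best),
                ef_volume_ref=ref,
            ))
            volumes[ref] = EFVolume(grid=grid, values=ef, record_ref=ref)

    meta = {
        "generator": "pssmap.synthetic",
        "seed": cfg.seed,
        "ground_truth": {
            "center_mm": list(gt.center_mm),
            "semi_axes_mm": list(gt.semi_axes_mm),
            "max_effect": gt.max_effect,
            "background_effect": gt.background_effect,
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
    }
    cohort = Cohort(grid=grid, records=records, ef_volumes=volumes, meta=meta).validate()
    return cohort, gt_mask
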