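"""Evaluation of extracted sweet spots.

Volumetrics (volume, Dice overlap, centroids), leave-one-patient-out
cross-validated overlap-improvement correlation, geometric consistency of
the cross-validation sweet spots (volume coefficient of variation, pairwise
Dice, normalized pairwise centroid distances), and the between-method
statistical comparison (ANOVA + Tukey when its assumptions hold, otherwise
Kruskal-Wallis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort_io import Cohort, CohortValidationError, GridMismatchError, VoxelGrid
from .sweetspot import SweetSpot
from .voxel_stack import vta_from_ef

__all__ = [
    "dice",
    "centroid_mm",
    "volume_mm3",
    "volume_cv",
    "equivalent_sphere_diameter_mm",
    "LOOCVResult",
    "loocv_overlap_correlation",
    "ConsistencyResult",
    "consistency_metrics",
    "MethodComparisonResult",
    "compare_methods",
]

logger = logging.getLogger(__name__)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def centroid_mm(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Mean world coordinate (mm) of the voxel centres in a non-empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise CohortValidationError("centroid of an empty mask is undefined")
    ijk = np.argwhere(mask).astype(float)
    xyz = ijk @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return xyz.mean(axis=0)


def volume_mm3(mask: np.ndarray, grid: VoxelGrid) -> float:
    """Mask volume: voxel count times voxel volume."""
    return float(np.asarray(mask, dtype=bool).sum()) * grid.voxel_volume_mm3


def volume_cv(volumes: Sequence[float]) -> float:
    """Volume coefficient of variation in percent: 100 * std / mean.

    Sample standard deviation (n-1 denominator).
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise CohortValidationError("volume CV needs at least 2 volumes")
    mean = v.mean()
    if mean <= 0:
        raise CohortValidationError("volume CV is undefined for mean <= 0")
    return float(100.0 * v.std(ddof=1) / mean)


def equivalent_sphere_diameter_mm(volume: float) -> float:
    """Diameter of the sphere with the given volume: (6V/pi)^(1/3)."""
    return float((6.0 * volume / np.pi) ** (1.0 / 3.0))


def _feret_diameter_mm(mask: np.ndarray, grid: VoxelGrid) -> float:
    xyz = np.argwhere(mask).astype(float) @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    if len(xyz) > 400:  # subsample for tractability; Feret mode is a flag
        sel = np.linspace(0, len(xyz) - 1, 400).astype(int)
        xyz = xyz[sel]
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    return float(d.max())


# ---------------------------------------------------------------------------
# Leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LOOCVResult:
    """Pooled overlap-improvement pairs and their Spearman correlation."""

    folds: list[str]
    fold_pss: list[SweetSpot]
    empty_folds: list[str]
    overlaps: np.ndarray
    improvements: np.ndarray
    trim_pct: float | None
    trim_threshold: float | None
    n_used: int
    spearman_rho: float
    spearman_p: float


def loocv_overlap_correlation(cohort: Cohort,
                              pss_builder: Callable[[Cohort], SweetSpot],
                              trim_pct: float | None = 95.0,
                              threshold: float = 0.2,
                              drop_empty_folds: bool = False) -> LOOCVResult:
    """Spearman correlation between VTA-PSS overlap and improvement, LOOCV.

    One fold per patient: the sweet spot is built from the other patients'
    records, then every left-out VTA is paired (Dice overlap vs its
    improvement score). Pairs are pooled over folds; pairs at or above the
    pooled ``trim_pct`` percentile of the overlap distribution are excluded
    to blunt the influence of a few high-overlap points. Folds with an
    empty sweet spot contribute zero-overlap pairs unless
    ``drop_empty_folds`` is set.
    """
    cohort.validate()
    patients = cohort.patients
    if len(patients) < 3:
        raise CohortValidationError("LOOCV needs at least 3 patients")

    fold_pss: list[SweetSpot] = []
    empty_folds: list[str] = []
    overlaps, improvements = [], []
    for left_out in patients:
        train = cohort.subset_patients([p for p in patients if p != left_out])
        pss = pss_builder(train)
        fold_pss.append(pss)
        if pss.n_voxels == 0:
            empty_folds.append(left_out)
            if drop_empty_folds:
                continue
        for rec in cohort.records:
            if rec.patient_id != left_out:
                continue
            vta = vta_from_ef(cohort.ef_volumes[rec.ef_volume_ref].values,
                              cohort.grid, rec.ef_volume_ref, threshold)
            overlaps.append(dice(vta.mask, pss.mask))
            improvements.append(rec.improvement_pct)

    overlaps = np.asarray(overlaps)
    improvements = np.asarray(improvements)
    trim_threshold = None
    keep = np.ones(overlaps.size, dtype=bool)
    if trim_pct is not None and overlaps.size:
        trim_threshold = float(np.percentile(overlaps, trim_pct))
        keep = overlaps < trim_threshold
        if not keep.any():  # degenerate all-equal distribution
            keep = np.ones(overlaps.size, dtype=bool)

    x, y = overlaps[keep], improvements[keep]
    if x.size >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = float("nan"), float("nan")
    logger.info("loocv: %d folds (%d empty), %d/%d pairs used, rho=%.3f",
                len(patients), len(empty_folds), int(keep.sum()), overlaps.size, rho)
    return LOOCVResult(
        folds=list(patients), fold_pss=fold_pss, empty_folds=empty_folds,
        overlaps=overlaps, improvements=improvements,
        trim_pct=trim_pct, trim_threshold=trim_threshold,
        n_used=int(keep.sum()), spearman_rho=float(rho), spearman_p=float(p),
    )


# ---------------------------------------------------------------------------
# Consistency metrics
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    """Geometric variability of a set of sweet spots (e.g. LOOCV folds)."""

    n_input: int
    n_used: int
    volume_cv_pct: float
    pairwise_dice: list[float]
    pairwise_norm_centroid_dist_pct: list[float]
    diameter_definition: str = "equivalent_sphere"


def consistency_metrics(pss_list: Sequence[SweetSpot],
                        diameter: str = "equivalent_sphere") -> ConsistencyResult:
    """Volume CV, pairwise Dice, and pairwise centroid distances normalized
    by the larger diameter of each pair (percent).

    The diameter is that of the equal-volume sphere by default
    (``diameter="feret"`` switches to the maximum point-pair extent).
    Empty sweet spots are excluded with a warning.
    """
    used = [p for p in pss_list if p.n_voxels > 0]
    if len(used) < len(pss_list):
        logger.warning("consistency_metrics: excluded %d empty PSS",
                       len(pss_list) - len(used))
    if len(used) < 2:
        raise CohortValidationError("consistency metrics need >= 2 non-empty PSS")
    volumes = [p.volume_mm3 for p in used]
    centroids = [centroid_mm(p.mask, p.grid) for p in used]
    if diameter == "equivalent_sphere":
        diams = [equivalent_sphere_diameter_mm(v) for v in volumes]
    elif diameter == "feret":
        diams = [_feret_diameter_mm(p.mask, p.grid) for p in used]
    else:
        raise TypeError(f"unknown diameter definition {diameter!r}")
    pair_dice, pair_dist = [], []
    for i in range(len(used)):
        for j in range(i + 1, len(used)):
            pair_dice.append(dice(used[i].mask, used[j].mask))
            d = float(np.linalg.norm(centroids[i] - centroids[j]))
            pair_dist.append(100.0 * d / max(diams[i], diams[j]))
    return ConsistencyResult(
        n_input=len(pss_list), n_used=len(used),
        volume_cv_pct=volume_cv(volumes),
        pairwise_dice=pair_dice,
        pairwise_norm_centroid_dist_pct=pair_dist,
        diameter_definition=diameter,
    )


# ---------------------------------------------------------------------------
# Between-method comparison
# ---------------------------------------------------------------------------

@dataclass
class MethodComparisonResult:
    """Decision trail of the between-method test on a consistency metric."""

    test_used: str  # "anova" | "kruskal" | "none"
    statistic: float
    p_value: float
    assumptions: dict
    posthoc: "object | None"  # pandas.DataFrame for Tukey, else None
    note: str = ""


def compare_methods(metric_samples: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> MethodComparisonResult:
    """Compare per-method metric distributions.

    Normality of residuals (Shapiro-Wilk) and homoscedasticity (Levene) are
    checked at 0.05; if both hold, one-way ANOVA with Tukey post-hoc when
    significant, otherwise Kruskal-Wallis (no default post-hoc).
    """
    names = list(metric_samples)
    groups = [np.asarray(metric_samples[k], dtype=float) for k in names]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise CohortValidationError("need >= 2 methods with >= 2 values each")

    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return MethodComparisonResult(
            test_used="none", statistic=float("nan"), p_value=float("nan"),
            assumptions={}, posthoc=None,
            note="all values identical across methods; no difference to test")

    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) == 0:
        shapiro_p = 1.0
    else:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
    try:
        levene_p = float(stats.levene(*groups).pvalue)
    except Exception:
        levene_p = 0.0
    assumptions = {"shapiro_p": shapiro_p, "levene_p": levene_p,
                   "normal": shapiro_p >= alpha, "homoscedastic": levene_p >= alpha}

    if assumptions["normal"] and assumptions["homoscedastic"]:
        f_stat, p = stats.f_oneway(*groups)
        posthoc = None
        if p < alpha:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            import pandas as pd

            labels = np.concatenate([[k] * g.size for k, g in zip(names, groups)])
            tk = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        return MethodComparisonResult(
            test_used="anova", statistic=float(f_stat), p_value=float(p),
            assumptions=assumptions, posthoc=posthoc)
    h_stat, p = stats.kruskal(*groups)
    return MethodComparisonResult(
        test_used="kruskal", statistic=float(h_stat), p_value=float(p),
        assumptions=assumptions, posthoc=None,
        note="ANOVA assumptions not met; Kruskal-Wallis used, no post-hoc by default")
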