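"""Probabilistic sweet-spot extraction from a thresholded statistic map.

The pipeline order is fixed: significance thresholding, then frequency
masking (voxels stimulated in too few patients or by too few VTAs are
discarded), then cluster-size filtering of the surviving connected
components. An empty sweet spot is a legal outcome — FDR-corrected maps
routinely reject nothing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label

from .cohort_io import CohortValidationError, GridMismatchError, VoxelGrid
from .correction import CorrectedMap
from .psm import PSMap
from .voxel_stack import VoxelStack

__all__ = [
    "PSSParams",
    "SweetSpot",
    "significant_voxels",
    "apply_frequency_masks",
    "filter_clusters",
    "extract_pss",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class PSSParams:
    """Thresholds of the extraction pipeline (defaults as used throughout).

    ``pat_frac``: voxels activated in less than this fraction of patients
    are discarded; ``nmap_frac``: voxels covered by fewer VTAs than this
    fraction of the maximum stimulation count are discarded (both strict-
    less); ``min_cluster``: connected components smaller than this many
    voxels are removed.
    """

    alpha: float = 0.05
    bf_threshold: float = 10.0
    pat_frac: float = 0.25
    nmap_frac: float = 0.10
    min_cluster: int = 8
    connectivity: int = 26


@dataclass
class SweetSpot:
    """Binary PSS mask with full extraction provenance."""

    grid: VoxelGrid
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3


def significant_voxels(m: PSMap | CorrectedMap, alpha: float = 0.05,
                       bf_threshold: float = 10.0) -> np.ndarray:
    """Binary field of voxels passing the method's significance rule.

    p-value maps: p < alpha (strict); corrected maps: their stored
    rejection rule (permutation: corrected p < alpha, BH: step-up rule);
    BF maps: BF10 >= threshold (inclusive); mixed-model maps: p < alpha
    AND slope > 0.
    """
    if isinstance(m, CorrectedMap):
        return m.significant.copy()
    if isinstance(m, PSMap):
        out = np.zeros(m.grid.shape, dtype=bool)
        v = m.valid_mask
        if m.kind == "p":
            out[v] = m.stat[v] < alpha
        elif m.kind == "bf":
            out[v] = m.stat[v] >= bf_threshold
        elif m.kind == "lmm":
            if m.slope is None:
                raise TypeError("LMM map carries no slope field")
            out[v] = (m.stat[v] < alpha) & (m.slope[v] > 0)
        else:  # pragma: no cover - PSMap constructor forbids this
            raise TypeError(f"unknown statistic kind {m.kind!r}")
        return out
    raise TypeError(f"cannot threshold object of type {type(m).__name__}")


def apply_frequency_masks(sig: np.ndarray, stack: VoxelStack,
                          n_patients: int | None = None,
                          pat_frac: float = 0.25, nmap_frac: float = 0.10) -> np.ndarray:
    """Discard voxels activated in < ``pat_frac`` of patients or covered by
    fewer VTAs than ``nmap_frac`` of the maximum stimulation count.

    Both comparisons are strict-less on exact fractions (a voxel exactly at
    the 25 % or 10 % bound is kept).
    """
    if not (0 < pat_frac < 1 and 0 < nmap_frac < 1):
        raise CohortValidationError("mask fractions must lie in (0, 1)")
    sig = np.asarray(sig, dtype=bool)
    if sig.shape != stack.grid.shape:
        raise GridMismatchError(f"field shape {sig.shape} != grid {stack.grid.shape}")
    n_patients = n_patients if n_patients is not None else stack.n_patients
    nmap_max = int(stack.n_map.max()) if stack.n_map.size else 0
    keep = (stack.npat_map / n_patients >= pat_frac) & (stack.n_map >= nmap_frac * nmap_max)
    return sig & keep


def filter_clusters(mask: np.ndarray, min_cluster: int = 8,
                    connectivity: int = 26) -> np.ndarray:
    """Remove connected components with fewer than ``min_cluster`` voxels."""
    if min_cluster < 1:
        raise CohortValidationError("min_cluster must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise CohortValidationError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or min_cluster == 1:
        return mask.copy()
    labels = cc_label(mask, connectivity=_CONNECTIVITY[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return np.isin(labels, np.flatnonzero(sizes >= min_cluster))


def _cohort_hash(stack: VoxelStack) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(stack.record_improvement).tobytes())
    h.update(np.asarray(stack.record_patient).tobytes())
    h.update(stack.n_map.tobytes())
    return h.hexdigest()[:16]


def extract_pss(m: PSMap | CorrectedMap, stack: VoxelStack,
                params: PSSParams | None = None) -> SweetSpot:
    """significance threshold -> frequency masks -> cluster filter.

    Stage-wise voxel counts are logged so an all-voxels-rejected outcome is
    auditable; the provenance records method, correction, thresholds and
    the input data fingerprint.
    """
    params = params or PSSParams()
    if m.grid != stack.grid:
        raise GridMismatchError("statistic map and stack are on different grids")
    sig = significant_voxels(m, alpha=params.alpha, bf_threshold=params.bf_threshold)
    masked = apply_frequency_masks(sig, stack, pat_frac=params.pat_frac,
                                   nmap_frac=params.nmap_frac)
    final = filter_clusters(masked, min_cluster=params.min_cluster,
                            connectivity=params.connectivity)
    meta = m.meta if isinstance(m, (PSMap, CorrectedMap)) else {}
    logger.info("extract_pss[%s/%s]: significant=%d masked=%d clustered=%d",
                meta.get("method", "?"), meta.get("correction", "none"),
                int(sig.sum()), int(masked.sum()), int(final.sum()))
    provenance = {
        "method": meta.get("method"),
        "correction": meta.get("correction", "none"),
        "map_meta": {k: v for k, v in meta.items() if not isinstance(v, np.ndarray)},
        "params": vars(params),
        "counts": {"significant": int(sig.sum()), "after_masks": int(masked.sum()),
                   "after_clusters": int(final.sum())},
        "min_cluster_mm3": params.min_cluster * stack.grid.voxel_volume_mm3,
        "cohort_hash": _cohort_hash(stack),
    }
    return SweetSpot(grid=stack.grid, mask=final, provenance=provenance)
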