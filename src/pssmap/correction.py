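"""Type-I-error corrections for the t and Wilcoxon maps.

Two corrections are provided: Benjamini-Hochberg FDR over the valid voxels
of a p-value map, and a voxel-wise nonparametric permutation correction in
which improvement labels are shuffled across records (EF geometry fixed),
the chosen test is recomputed per permutation, and each voxel's corrected
p-value is the fraction of permuted p-values at or below its true one.
Voxels with corrected p >= 0.05 are discarded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortValidationError, VoxelGrid
from .psm import PSMap, _prepare, _t_pvalues, _w_pvalues
from .voxel_stack import VoxelStack

__all__ = [
    "CorrectedMap",
    "fdr_bh",
    "permutation_correct",
    "permutation_count_stability",
    "PermutationStabilityReport",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrectedMap:
    """A corrected p-value map plus its rejection rule.

    ``kind`` is ``"fdr"`` (``corrected_p`` holds BH-adjusted p-values,
    significance follows the BH step-up rule) or ``"perm"``
    (``corrected_p`` = fraction of permuted p-values <= true p). The
    correction removes voxels from the uncorrected significant set: a
    ``perm`` voxel is significant iff its uncorrected p < alpha AND its
    corrected p < alpha (corrected p >= 0.05 is discarded, strict <).
    """

    grid: VoxelGrid
    kind: str
    corrected_p: np.ndarray
    valid_mask: np.ndarray
    significant: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def method(self) -> str:
        return self.meta.get("method", self.kind)


def fdr_bh(pmap: PSMap, q: float = 0.05) -> CorrectedMap:
    """Benjamini-Hochberg step-up correction over the valid voxels only.

    A voxel is significant iff its p-value is at or below p(k) where
    k = max{i : p(i) <= i q / m}; ``corrected_p`` carries the BH-adjusted
    p-values (monotone min over m p(j)/j).
    """
    if pmap.kind != "p":
        raise TypeError(f"FDR applies to p-value maps, got kind {pmap.kind!r}")
    valid = pmap.valid_mask
    p = pmap.stat[valid]
    adj = np.full(pmap.grid.n_voxels, np.nan).reshape(pmap.grid.shape)
    sig = np.zeros(pmap.grid.shape, dtype=bool)
    if p.size:
        reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        adj[valid] = p_adj
        sig[valid] = reject
    return CorrectedMap(
        grid=pmap.grid, kind="fdr", corrected_p=adj, valid_mask=valid.copy(),
        significant=sig,
        meta={**pmap.meta, "correction": "fdr", "q": q},
    )


def _permute_labels(rng: np.random.Generator, labels: np.ndarray,
                    lead_of_record: np.ndarray | None) -> np.ndarray:
    if lead_of_record is None:
        return labels[rng.permutation(labels.size)]
    out = labels.copy()
    for lead in np.unique(lead_of_record):
        idx = np.flatnonzero(lead_of_record == lead)
        out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def permutation_correct(stack: VoxelStack, test: str = "t", n_perm: int = 200,
                        seed: int | None = None, mu0: float = 75.0, min_n: int = 3,
                        alpha: float = 0.05, stratify_by_lead: bool = False,
                        add_one: bool = False) -> CorrectedMap:
    """Voxel-wise nonparametric permutation correction of a t or Wilcoxon map.

    Improvement labels are shuffled ``n_perm`` times across all records
    (both within and between leads; ``stratify_by_lead`` restricts the
    exchange to within each lead). The corrected p-value of a voxel is the
    fraction of permuted maps whose p at that voxel is <= the true p
    (``add_one`` switches to the (count+1)/(n_perm+1) convention).
    """
    if n_perm < 1:
        raise CohortValidationError("n_perm must be >= 1")
    if seed is None:
        raise CohortValidationError("permutation correction requires a seed")
    if test not in ("t", "wilcoxon"):
        raise TypeError(f"test must be 't' or 'wilcoxon', got {test!r}")

    prep = _prepare(stack, min_n)
    labels = stack.record_improvement
    cache: dict = {}
    if test == "t":
        p_true = _t_pvalues(prep, labels, mu0)
    else:
        p_true = _w_pvalues(prep, labels, mu0, cache)

    lead_of_record = stack.record_lead if stratify_by_lead else None

    rng = np.random.default_rng(seed)
    count = np.zeros(prep.voxels.size, dtype=np.int64)
    for b in range(n_perm):
        perm = _permute_labels(rng, labels, lead_of_record)
        if test == "t":
            p_b = _t_pvalues(prep, perm, mu0)
        else:
            p_b = _w_pvalues(prep, perm, mu0, cache)
        count += p_b <= p_true
    if add_one:
        corr = (count + 1) / (n_perm + 1)
    else:
        corr = count / n_perm

    grid = stack.grid
    cp = np.full(grid.n_voxels, np.nan)
    cp[prep.voxels] = corr
    cp = cp.reshape(grid.shape)
    valid = np.zeros(grid.n_voxels, dtype=bool)
    valid[prep.voxels] = True
    valid = valid.reshape(grid.shape)
    # the correction discards voxels from the thresholded map: keep voxels
    # significant before correction whose corrected p also stays < alpha
    uncorr = np.zeros(grid.n_voxels, dtype=bool)
    uncorr[prep.voxels] = p_true < alpha
    sig = np.zeros(grid.shape, dtype=bool)
    sig[valid] = (cp[valid] < alpha) & uncorr.reshape(grid.shape)[valid]
    logger.info("permutation_correct(%s, n_perm=%d): %d/%d voxels significant",
                test, n_perm, int(sig.sum()), int(valid.sum()))
    return CorrectedMap(
        grid=grid, kind="perm", corrected_p=cp, valid_mask=valid, significant=sig,
        meta={"method": test, "correction": "perm", "n_perm": n_perm, "seed": seed,
              "alpha": alpha, "mu0": mu0, "min_n": min_n,
              "stratify_by_lead": stratify_by_lead, "add_one": add_one},
    )


@dataclass
class PermutationStabilityReport:
    """PSS stability across permutation counts."""

    counts: list[int]
    surviving_voxels: list[int]
    masks: list[np.ndarray]
    pairwise_dice: dict[tuple[int, int], float]
    pairwise_centroid_dist_mm: dict[tuple[int, int], float]


def permutation_count_stability(stack: VoxelStack, test: str, counts: list[int],
                                seed: int, pss_params=None, mu0: float = 75.0,
                                min_n: int = 3) -> PermutationStabilityReport:
    """Recompute the permutation-corrected PSS for several permutation
    counts and compare the resulting masks (surviving-voxel counts,
    pairwise Dice, pairwise centroid distances).

    Each count uses a seed derived from (seed, count) so identical counts
    reproduce identical permutations.
    """
    from .evaluation import centroid_mm, dice
    from .sweetspot import PSSParams, extract_pss

    if not counts:
        raise CohortValidationError("counts must be non-empty")
    pss_params = pss_params or PSSParams()
    masks, nvox = [], []
    for c in counts:
        sub_seed = int(np.random.SeedSequence([seed, int(c)]).generate_state(1)[0] % (2**31))
        cm = permutation_correct(stack, test=test, n_perm=int(c), seed=sub_seed,
                                 mu0=mu0, min_n=min_n)
        pss = extract_pss(cm, stack, pss_params)
        masks.append(pss.mask)
        nvox.append(int(pss.mask.sum()))
    pair_dice, pair_dist = {}, {}
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            key = (counts[i], counts[j])
            pair_dice[key] = dice(masks[i], masks[j])
            if masks[i].any() and masks[j].any():
                ci = centroid_mm(masks[i], stack.grid)
                cj = centroid_mm(masks[j], stack.grid)
                pair_dist[key] = float(np.linalg.norm(ci - cj))
            else:
                pair_dist[key] = float("nan")
    return PermutationStabilityReport(
        counts=list(counts), surviving_voxels=nvox, masks=masks,
        pairwise_dice=pair_dice, pairwise_centroid_dist_mm=pair_dist,
    )
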