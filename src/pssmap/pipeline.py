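"""End-to-end orchestration: cohort -> stack -> map -> correction -> PSS.

The six standard analysis variants are the four statistical methods with
their admissible corrections: t and Wilcoxon maps corrected by FDR or
voxel-wise permutations (TFDR, WFDR, TPerm, WPerm), and the Bayesian and
mixed-model maps uncorrected (B, LMM).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort_io import Cohort, CohortValidationError, save_volume
from .correction import fdr_bh, permutation_correct
from .evaluation import centroid_mm, dice
from .psm import PriorSpec, bmap, lmm_map, tmap, wmap
from .sweetspot import PSSParams, SweetSpot, apply_frequency_masks, extract_pss
from .voxel_stack import VoxelStack, build_stack

__all__ = ["MethodSpec", "RunConfig", "RunResult", "STANDARD_VARIANTS",
           "compute_pss", "run_analysis", "make_pss_builder"]

logger = logging.getLogger(__name__)

_METHODS = ("t", "wilcoxon", "bayes", "lmm")
_CORRECTIONS = ("none", "fdr", "perm")


@dataclass(frozen=True)
class MethodSpec:
    """One statistical method plus its type-I-error correction."""

    method: str
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise CohortValidationError(f"unknown method {self.method!r}")
        if self.correction not in _CORRECTIONS:
            raise CohortValidationError(f"unknown correction {self.correction!r}")
        if self.method in ("bayes", "lmm") and self.correction != "none":
            raise CohortValidationError(
                f"{self.method} accepts correction 'none' only "
                "(corrections apply to the t and Wilcoxon maps)")

    @property
    def label(self) -> str:
        base = {"t": "T", "wilcoxon": "W", "bayes": "B", "lmm": "LMM"}[self.method]
        suffix = {"none": "", "fdr": "FDR", "perm": "Perm"}[self.correction]
        return base + suffix


#: The six variants compared throughout: TFDR, WFDR, TPerm, WPerm, B, LMM.
STANDARD_VARIANTS = (
    MethodSpec("t", "fdr"), MethodSpec("wilcoxon", "fdr"),
    MethodSpec("t", "perm"), MethodSpec("wilcoxon", "perm"),
    MethodSpec("bayes"), MethodSpec("lmm"),
)


@dataclass
class RunConfig:
    """Resolved analysis configuration with the standard defaults."""

    methods: tuple[MethodSpec, ...] = STANDARD_VARIANTS
    mu0: float = 75.0
    ef_threshold: float = 0.2
    min_n: int = 3
    min_patients_lmm: int = 3
    n_perm: int = 200
    fdr_q: float = 0.05
    pss: PSSParams = field(default_factory=PSSParams)
    prior: PriorSpec = field(default_factory=PriorSpec)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "methods": [dataclasses.asdict(m) for m in self.methods],
            "mu0": self.mu0, "ef_threshold": self.ef_threshold,
            "min_n": self.min_n, "min_patients_lmm": self.min_patients_lmm,
            "n_perm": self.n_perm, "fdr_q": self.fdr_q,
            "pss": dataclasses.asdict(self.pss),
            "prior": dataclasses.asdict(self.prior),
            "seed": self.seed,
        }


def _perm_seed(base: int | None, spec: MethodSpec) -> int:
    if base is None:
        raise CohortValidationError("permutation correction requires RunConfig.seed")
    tag = {"t": 1, "wilcoxon": 2}[spec.method]
    return int(np.random.SeedSequence([int(base), tag]).generate_state(1)[0] % (2**31))


def compute_pss(stack: VoxelStack, spec: MethodSpec, cfg: RunConfig) -> SweetSpot:
    """Run one method x correction variant on a prepared stack."""
    if spec.method == "t":
        m = tmap(stack, mu0=cfg.mu0, min_n=cfg.min_n)
    elif spec.method == "wilcoxon":
        m = wmap(stack, mu0=cfg.mu0, min_n=cfg.min_n)
    elif spec.method == "bayes":
        m = bmap(stack, mu0=cfg.mu0, prior=cfg.prior, min_n=cfg.min_n)
    else:  # lmm: fit only where the frequency masks can keep voxels
        candidates = apply_frequency_masks(
            np.ones(stack.grid.shape, dtype=bool), stack,
            pat_frac=cfg.pss.pat_frac, nmap_frac=cfg.pss.nmap_frac)
        m = lmm_map(stack, candidate_mask=candidates,
                    min_patients=cfg.min_patients_lmm)

    if spec.correction == "fdr":
        m = fdr_bh(m, q=cfg.fdr_q)
    elif spec.correction == "perm":
        m = permutation_correct(stack, test=spec.method, n_perm=cfg.n_perm,
                                seed=_perm_seed(cfg.seed, spec),
                                mu0=cfg.mu0, min_n=cfg.min_n,
                                alpha=cfg.pss.alpha)
    pss = extract_pss(m, stack, cfg.pss)
    pss.provenance["variant"] = spec.label
    pss.provenance["run_seed"] = cfg.seed
    return pss


def make_pss_builder(spec: MethodSpec, cfg: RunConfig):
    """A ``cohort -> SweetSpot`` callable for cross-validation folds."""

    def build(cohort: Cohort) -> SweetSpot:
        stack = build_stack(cohort, threshold=cfg.ef_threshold)
        return compute_pss(stack, spec, cfg)

    return build


@dataclass
class RunResult:
    """Sweet spots of all requested variants plus their volumetrics."""

    sweet_spots: dict[str, SweetSpot]
    volumes_mm3: dict[str, float]
    centroids_mm: dict[str, list[float] | None]
    pairwise_dice: dict[str, float]
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "volumes_mm3": self.volumes_mm3,
            "centroids_mm": self.centroids_mm,
            "pairwise_dice": self.pairwise_dice,
            "stage_counts": {k: s.provenance["counts"]
                             for k, s in self.sweet_spots.items()},
            "config": self.config,
        }


def run_analysis(cohort: Cohort, cfg: RunConfig) -> RunResult:
    """Compute every requested PSS variant on a cohort and compare them."""
    stack = build_stack(cohort, threshold=cfg.ef_threshold)
    spots: dict[str, SweetSpot] = {}
    for spec in cfg.methods:
        logger.info("running variant %s", spec.label)
        spots[spec.label] = compute_pss(stack, spec, cfg)
    volumes = {k: s.volume_mm3 for k, s in spots.items()}
    centroids = {
        k: (centroid_mm(s.mask, s.grid).tolist() if s.n_voxels else None)
        for k, s in spots.items()
    }
    labels = list(spots)
    pair_dice = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            pair_dice[f"{a}|{b}"] = dice(spots[a].mask, spots[b].mask)
    return RunResult(sweet_spots=spots, volumes_mm3=volumes,
                     centroids_mm=centroids, pairwise_dice=pair_dice,
                     config=cfg.to_dict())


def save_run(result: RunResult, out_dir) -> Path:
    """Write each PSS as NIfTI + JSON provenance, plus the run report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label, pss in result.sweet_spots.items():
        save_volume(pss.mask, pss.grid, out_dir / f"pss_{label}.nii.gz")
        (out_dir / f"pss_{label}.json").write_text(
            json.dumps(pss.provenance, indent=2, default=str))
    (out_dir / "report.json").write_text(
        json.dumps(result.to_json_dict(), indent=2, default=str))
    return out_dir
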