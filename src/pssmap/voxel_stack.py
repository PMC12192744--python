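"""Per-voxel observation stack, VTA thresholding and frequency maps.

EF volumes labelled with improvement scores are stacked along a fourth
dimension: each voxel collects one (EF, improvement, patient) observation
per stimulation whose EF at that voxel reaches the 0.2 V/mm activation
threshold. The stack is stored as flat parallel arrays (observation ->
voxel index / record index) so that voxel-wise statistics and label
permutations can be computed with vectorized group-by reductions without
re-reading any volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import Cohort, CohortValidationError, GridMismatchError, VoxelGrid

__all__ = ["VTAMask", "VoxelStack", "vta_from_ef", "build_stack"]


@dataclass
class VTAMask:
    """Binary volume of tissue activated: EF >= threshold (inclusive)."""

    grid: VoxelGrid
    mask: np.ndarray
    record_ref: str
    threshold_used: float = 0.2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GridMismatchError(
                f"VTA {self.record_ref!r}: mask shape {self.mask.shape} != grid {self.grid.shape}"
            )
        if self.threshold_used <= 0:
            raise CohortValidationError("VTA threshold must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def vta_from_ef(ef_values: np.ndarray, grid: VoxelGrid, record_ref: str = "",
                threshold: float = 0.2) -> VTAMask:
    """Threshold an EF-norm field into a VTA. Values below the threshold are
    discarded, i.e. the comparison is inclusive at equality."""
    if threshold <= 0:
        raise CohortValidationError("threshold must be > 0")
    return VTAMask(grid=grid, mask=np.asarray(ef_values) >= threshold,
                   record_ref=record_ref, threshold_used=threshold)


@dataclass
class VoxelStack:
    """Flat per-voxel observation store plus derived frequency maps.

    Observation arrays (all length = total number of (voxel, record)
    incidences):

    - ``obs_voxel``   flat voxel index of the observation
    - ``obs_record``  index into ``record_refs`` / record-level arrays
    - ``obs_ef``      EF norm at the voxel (>= threshold by construction)

    Record-level arrays (length = number of records): ``record_improvement``,
    ``record_patient``, ``record_amplitude``. Observation improvements are
    looked up through ``obs_record`` so that permuting improvement labels at
    the record level re-labels every observation consistently.

    Derived maps: ``n_map`` (stimulations covering each voxel), ``npat_map``
    (distinct patients covering each voxel) and ``wimp_map`` (auxiliary
    EF/amplitude-weighted mean improvement; not used for masking).
    """

    grid: VoxelGrid
    threshold: float
    obs_voxel: np.ndarray
    obs_record: np.ndarray
    obs_ef: np.ndarray
    record_refs: list[str]
    record_improvement: np.ndarray
    record_patient: np.ndarray
    record_amplitude: np.ndarray
    record_lead: np.ndarray
    patients: list[str]
    n_map: np.ndarray = field(repr=False, default=None)
    npat_map: np.ndarray = field(repr=False, default=None)
    wimp_map: np.ndarray = field(repr=False, default=None)

    @property
    def n_records(self) -> int:
        return len(self.record_refs)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def obs_improvement(self) -> np.ndarray:
        return self.record_improvement[self.obs_record]

    @property
    def obs_patient(self) -> np.ndarray:
        return self.record_patient[self.obs_record]

    def observations(self, voxel) -> list[tuple[float, float, str, str]]:
        """(ef, improvement, patient_id, record_ref) tuples at one voxel
        (voxel given as an (i, j, k) index triple or a flat index)."""
        flat = int(np.ravel_multi_index(voxel, self.grid.shape)) if np.ndim(voxel) else int(voxel)
        sel = np.flatnonzero(self.obs_voxel == flat)
        return [
            (float(self.obs_ef[i]),
             float(self.record_improvement[self.obs_record[i]]),
             self.patients[self.record_patient[self.obs_record[i]]],
             self.record_refs[self.obs_record[i]])
            for i in sel
        ]


def build_stack(cohort: Cohort, threshold: float = 0.2) -> VoxelStack:
    """Stack a cohort's EF volumes into a :class:`VoxelStack`.

    Each voxel's observation sequence holds one entry per record whose EF
    at that voxel is >= ``threshold``. The auxiliary ``wimp_map`` is the
    weighted mean improvement with weights EF / amplitude, penalizing
    coverage attained only through high currents.
    """
    cohort.validate()
    grid = cohort.grid
    patients = cohort.patients
    patient_index = {p: i for i, p in enumerate(patients)}

    vox_parts, rec_parts, ef_parts = [], [], []
    record_refs, rec_imp, rec_pat, rec_amp, rec_lead = [], [], [], [], []
    lead_index: dict[str, int] = {}
    for r_idx, rec in enumerate(cohort.records):
        values = np.asarray(cohort.ef_volumes[rec.ef_volume_ref].values)
        flat = np.flatnonzero(values.ravel() >= threshold)
        vox_parts.append(flat)
        rec_parts.append(np.full(flat.size, r_idx, dtype=np.int32))
        ef_parts.append(values.ravel()[flat].astype(np.float64))
        record_refs.append(rec.ef_volume_ref)
        rec_imp.append(rec.improvement_pct)
        rec_pat.append(patient_index[rec.patient_id])
        rec_amp.append(rec.amplitude_mA)
        rec_lead.append(lead_index.setdefault(rec.lead_id, len(lead_index)))

    obs_voxel = np.concatenate(vox_parts) if vox_parts else np.empty(0, dtype=np.int64)
    obs_record = np.concatenate(rec_parts) if rec_parts else np.empty(0, dtype=np.int32)
    obs_ef = np.concatenate(ef_parts) if ef_parts else np.empty(0)

    n_vox = grid.n_voxels
    n_map = np.bincount(obs_voxel, minlength=n_vox).reshape(grid.shape)

    rec_pat_arr = np.asarray(rec_pat, dtype=np.int32)
    pair = obs_voxel * len(patients) + rec_pat_arr[obs_record]
    npat_map = np.bincount(np.unique(pair) // len(patients), minlength=n_vox).reshape(grid.shape)

    rec_imp_arr = np.asarray(rec_imp)
    rec_amp_arr = np.asarray(rec_amp)
    w = obs_ef / rec_amp_arr[obs_record]
    wsum = np.bincount(obs_voxel, weights=w, minlength=n_vox)
    wimp = np.bincount(obs_voxel, weights=w * rec_imp_arr[obs_record], minlength=n_vox)
    with np.errstate(invalid="ignore"):
        wimp_map = np.where(wsum > 0, wimp / np.where(wsum > 0, wsum, 1.0), np.nan)
    wimp_map = wimp_map.reshape(grid.shape)

    # order-independence: sort observations by (voxel, record)
    order = np.lexsort((obs_record, obs_voxel))
    return VoxelStack(
        grid=grid,
        threshold=threshold,
        obs_voxel=obs_voxel[order],
        obs_record=obs_record[order],
        obs_ef=obs_ef[order],
        record_refs=record_refs,
        record_improvement=rec_imp_arr,
        record_patient=rec_pat_arr,
        record_amplitude=rec_amp_arr,
        record_lead=np.asarray(rec_lead, dtype=np.int32),
        patients=patients,
        n_map=n_map,
        npat_map=npat_map,
        wimp_map=wimp_map,
    )
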