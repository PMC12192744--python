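"""Cohort data model and NIfTI/CSV readers and writers.

A cohort bundles one hemisphere's intra-operative stimulation tests: a
tabular record per stimulation (patient, tract, depth, current amplitude,
tremor-improvement rating) and, for each record, a simulated electric-field
(EF) norm volume resampled onto a common isotropic grid. All volumes in one
analysis share an identical grid; voxel indices are 0-based and world
coordinates in mm are obtained through the grid affine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "CohortValidationError",
    "GridMismatchError",
    "VolumeLoadError",
    "VoxelGrid",
    "StimulationRecord",
    "EFVolume",
    "Cohort",
    "TABLE_COLUMNS",
    "load_cohort",
    "save_cohort",
    "load_volume",
    "save_volume",
]

TABLE_COLUMNS = (
    "patient_id",
    "lead_id",
    "tract_id",
    "depth_mm",
    "amplitude_mA",
    "improvement_pct",
    "ef_volume_ref",
)

TRACT_IDS = ("central", "parallel")


class CohortError(Exception):
    """Base class for cohort I/O and validation failures."""


class CohortValidationError(CohortError):
    """A record or cohort violates an invariant (range, cross-reference...)."""


class GridMismatchError(CohortError):
    """Two volumes (or a volume and a field) do not share the same grid."""


class VolumeLoadError(CohortError):
    """A referenced volume file is missing or unreadable."""


@dataclass(frozen=True)
class VoxelGrid:
    """A rectilinear voxel grid with a voxel-index -> mm affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    affine
        4x4 homogeneous mapping from 0-based voxel index to mm world
        coordinates. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise CohortValidationError(f"grid shape must be a positive triple, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise CohortValidationError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise CohortValidationError("affine is not invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise CohortValidationError("voxel size must be strictly positive")

    @classmethod
    def centered(cls, shape=(48, 48, 48), voxel_size_mm=0.5, center_mm=(0.0, 0.0, 0.0)) -> "VoxelGrid":
        """Isotropic axis-aligned grid whose centre voxel sits at ``center_mm``."""
        shape = tuple(int(s) for s in shape)
        vs = float(voxel_size_mm)
        affine = np.diag([vs, vs, vs, 1.0])
        center = np.asarray(center_mm, dtype=float)
        affine[:3, 3] = center - vs * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return tuple(float(v) for v in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains_mm(self, point_mm) -> bool:
        """Whether a world point falls inside the voxel-index bounding box."""
        inv = np.linalg.inv(self.affine)
        p = np.asarray(point_mm, dtype=float)
        ijk = inv[:3, :3] @ p + inv[:3, 3]
        return bool(np.all(ijk >= -0.5) and np.all(ijk <= np.asarray(self.shape) - 0.5))

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=1e-6)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.round(6).tobytes()))


def _check_grid(grid_a: VoxelGrid, grid_b: VoxelGrid, what: str) -> None:
    if grid_a != grid_b:
        raise GridMismatchError(
            f"{what}: grids differ (shape {grid_a.shape} vs {grid_b.shape})"
        )


@dataclass(frozen=True)
class StimulationRecord:
    """One intra-operative stimulation test at its motor threshold.

    ``improvement_pct`` is the tremor-improvement rating in percent on the
    discrete clinical scale {0, 25, 50, 75, 100} (intermediate scores are
    permitted); ``amplitude_mA`` is the lowest current at which that best
    score was observed at the position.
    """

    patient_id: str
    lead_id: str
    tract_id: str
    depth_mm: float
    amplitude_mA: float
    improvement_pct: float
    ef_volume_ref: str

    def __post_init__(self) -> None:
        if self.tract_id not in TRACT_IDS:
            raise CohortValidationError(
                f"record {self.ef_volume_ref!r}: tract_id must be one of {TRACT_IDS}, got {self.tract_id!r}"
            )
        if not np.isfinite(self.amplitude_mA) or self.amplitude_mA <= 0:
            raise CohortValidationError(
                f"record {self.ef_volume_ref!r}: amplitude_mA must be > 0, got {self.amplitude_mA}"
            )
        if not np.isfinite(self.improvement_pct) or not 0.0 <= self.improvement_pct <= 100.0:
            raise CohortValidationError(
                f"record {self.ef_volume_ref!r}: improvement_pct must lie in [0, 100], got {self.improvement_pct}"
            )


@dataclass
class EFVolume:
    """Scalar field of EF norm (V/mm) for one stimulation."""

    grid: VoxelGrid
    values: np.ndarray
    record_ref: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"EF volume {self.record_ref!r}: values shape {self.values.shape} "
                f"does not match grid {self.grid.shape}"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise CohortValidationError(
                f"EF volume {self.record_ref!r}: values must be finite and >= 0"
            )


@dataclass
class Cohort:
    """One hemisphere's stimulation records plus their EF volumes."""

    grid: VoxelGrid
    records: list[StimulationRecord]
    ef_volumes: dict[str, EFVolume]
    meta: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> "Cohort":
        if not self.records:
            raise CohortValidationError("cohort has no records")
        refs = [r.ef_volume_ref for r in self.records]
        if len(set(refs)) != len(refs):
            dup = sorted({r for r in refs if refs.count(r) > 1})
            raise CohortValidationError(f"duplicate ef_volume_ref(s): {dup}")
        for r in self.records:
            vol = self.ef_volumes.get(r.ef_volume_ref)
            if vol is None:
                raise CohortValidationError(
                    f"record {r.ef_volume_ref!r} (patient {r.patient_id}) has no EF volume"
                )
            _check_grid(self.grid, vol.grid, f"EF volume {r.ef_volume_ref!r}")
        if self.n_patients < 2:
            raise CohortValidationError(
                f"cohort must contain >= 2 patients, got {self.n_patients}"
            )
        return self

    def subset_patients(self, keep: Iterable[str]) -> "Cohort":
        """Cohort restricted to the given patients (volumes shared, not copied)."""
        keep = set(keep)
        records = [r for r in self.records if r.patient_id in keep]
        vols = {r.ef_volume_ref: self.ef_volumes[r.ef_volume_ref] for r in records}
        return Cohort(grid=self.grid, records=records, ef_volumes=vols, meta=dict(self.meta))


# ---------------------------------------------------------------------------
# Volumetric I/O (NIfTI-1)
# ---------------------------------------------------------------------------

def save_volume(values: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a scalar or binary field as a NIfTI-1 file with the grid affine.

    Binary masks are stored as uint8 so the round trip is exact; scalar
    fields keep their floating dtype.
    """
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"field shape {values.shape} does not match grid {grid.shape}"
        )
    if values.dtype == bool:
        values = values.astype(np.uint8)
    elif values.dtype not in (np.uint8, np.int16, np.int32, np.float32, np.float64):
        values = values.astype(np.float64)
    img = nib.Nifti1Image(values, grid.affine)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a NIfTI volume; returns the data array and its grid."""
    path = Path(path)
    if not path.exists():
        raise VolumeLoadError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeLoadError(f"could not read volume {path}: {exc}") from exc
    grid = VoxelGrid(shape=data.shape, affine=np.asarray(img.affine))
    return data, grid


# ---------------------------------------------------------------------------
# Cohort I/O (CSV table + NIfTI volumes + JSON sidecar)
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as ``table.csv`` + ``volumes/<ref>.nii.gz`` + ``cohort.json``."""
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    rows = [dataclasses.asdict(r) for r in cohort.records]
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(out_dir / "table.csv", index=False)
    for ref, vol in cohort.ef_volumes.items():
        save_volume(np.asarray(vol.values, dtype=np.float32), cohort.grid, vol_dir / f"{ref}.nii.gz")
    sidecar = {
        "grid": {
            "shape": list(cohort.grid.shape),
            "voxel_size_mm": list(cohort.grid.voxel_size_mm),
            "affine": cohort.grid.affine.tolist(),
        },
        "n_patients": cohort.n_patients,
        "n_records": len(cohort.records),
        **cohort.meta,
    }
    (out_dir / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_cohort(volume_dir, table) -> Cohort:
    """Load and validate a cohort from a volume directory and a CSV table.

    ``volume_dir`` may be the cohort directory written by :func:`save_cohort`
    (containing ``volumes/``) or the volume directory itself.
    """
    volume_dir = Path(volume_dir)
    if (volume_dir / "volumes").is_dir():
        base_dir, volume_dir = volume_dir, volume_dir / "volumes"
    else:
        base_dir = volume_dir.parent
    table = Path(table)
    df = pd.read_csv(table)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"table {table} is missing columns {missing}")

    records = []
    for row in df.itertuples(index=False):
        if not np.isfinite(row.improvement_pct):
            raise CohortValidationError(
                f"record {row.ef_volume_ref!r}: improvement_pct is not finite"
            )
        records.append(
            StimulationRecord(
                patient_id=str(row.patient_id),
                lead_id=str(row.lead_id),
                tract_id=str(row.tract_id),
                depth_mm=float(row.depth_mm),
                amplitude_mA=float(row.amplitude_mA),
                improvement_pct=float(row.improvement_pct),
                ef_volume_ref=str(row.ef_volume_ref),
            )
        )

    grid: VoxelGrid | None = None
    volumes: dict[str, EFVolume] = {}
    for rec in records:
        path = volume_dir / f"{rec.ef_volume_ref}.nii.gz"
        if not path.exists():
            path = volume_dir / f"{rec.ef_volume_ref}.nii"
        if not path.exists():
            raise VolumeLoadError(
                f"record {rec.ef_volume_ref!r} (patient {rec.patient_id}): "
                f"volume file not found under {volume_dir}"
            )
        data, vgrid = load_volume(path)
        if grid is None:
            grid = vgrid
        else:
            _check_grid(grid, vgrid, f"EF volume {rec.ef_volume_ref!r}")
        volumes[rec.ef_volume_ref] = EFVolume(grid=vgrid, values=data, record_ref=rec.ef_volume_ref)

    meta = {}
    sidecar = base_dir / "cohort.json"
    if sidecar.exists():
        meta = {k: v for k, v in json.loads(sidecar.read_text()).items()
                if k not in ("grid", "n_patients", "n_records")}
    assert grid is not None
    return Cohort(grid=grid, records=records, ef_volumes=volumes, meta=meta).validate()
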