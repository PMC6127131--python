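"""Volumetric PET I/O: NIfTI images and masks, frame timing, cohort tables.

Frame timing is deliberately *not* read from NIfTI headers — dynamic-PET
timing in NIfTI exports is unreliable — but supplied as a sidecar table
(CSV with columns ``start_min``, ``duration_min``).  Voxel values are
activity concentration in kBq/mL unless declared otherwise at load time.
All downstream stages require identical grids (shape, spacing, affine);
nothing in this package resamples silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicPETVolume",
    "SUVVolume",
    "VOIMask",
    "SubjectRecord",
    "GridMismatchError",
    "default_schedule",
    "read_schedule",
    "write_schedule",
    "read_dynamic",
    "read_mask",
    "write_volume",
    "read_cohort",
    "write_cohort",
]

#: unit conversion factors to kBq/mL
_ACTIVITY_UNITS = {"kBq/mL": 1.0, "Bq/mL": 1e-3, "MBq/mL": 1e3}


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timing of a dynamic scan, in minutes post-injection.

    Frames must be contiguous, non-overlapping and of positive duration.
    """

    start: np.ndarray  # minutes
    duration: np.ndarray  # minutes

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape or start.size == 0:
            raise ValueError("start and duration must be equal-length 1-D arrays")
        if np.any(duration <= 0):
            raise ValueError("all frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = start + duration
        if not np.allclose(ends[:-1], start[1:], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid_times(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return self.start + self.duration / 2.0

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])

    def frame_containing(self, t: float) -> int:
        """Index of the frame whose [start, end) interval contains ``t``.

        The final frame is closed on the right so ``t == end of scan`` is
        assigned to the last frame.
        """
        if t < self.start[0] or t > self.end[-1]:
            raise ValueError(f"time {t} min outside acquisition window")
        idx = int(np.searchsorted(self.end, t, side="right"))
        return min(idx, len(self) - 1)


def default_schedule() -> FrameSchedule:
    """The 16-frame 0-50 min schedule: 5 x 1 min, 5 x 3 min, 6 x 5 min."""
    duration = np.array([1.0] * 5 + [3.0] * 5 + [5.0] * 6)
    start = np.concatenate([[0.0], np.cumsum(duration)[:-1]])
    return FrameSchedule(start, duration)


def read_schedule(path: str | Path) -> FrameSchedule:
    df = pd.read_csv(path)
    if not {"start_min", "duration_min"} <= set(df.columns):
        raise ValueError(f"{path}: schedule CSV needs columns start_min, duration_min")
    return FrameSchedule(df["start_min"].to_numpy(), df["duration_min"].to_numpy())


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame({"start_min": schedule.start, "duration_min": schedule.duration}).to_csv(
        path, index=False
    )


def _check_grid(spacing_a, spacing_b, shape_a, shape_b, what: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(f"{what}: shape {tuple(shape_a)} != {tuple(shape_b)}")
    if not np.allclose(spacing_a, spacing_b, rtol=1e-5):
        raise GridMismatchError(f"{what}: spacing {spacing_a} != {spacing_b}")


@dataclass
class DynamicPETVolume:
    """4-D activity data, frame-major: ``voxels[frame, x, y, z]``.

    ``voxels`` is activity concentration (kBq/mL) unless ``suv_scaled``;
    ``spacing`` is mm per spatial axis; ``affine`` maps voxel indices to
    physical mm coordinates (kept for faithful NIfTI round-trips).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    schedule: FrameSchedule
    affine: np.ndarray | None = None
    suv_scaled: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("dynamic volume must be 4-D (frame, x, y, z)")
        if self.voxels.shape[0] != len(self.schedule):
            raise ValueError(
                f"{self.voxels.shape[0]} frames but schedule has {len(self.schedule)}"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive mm values")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("activity values must be finite")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]


@dataclass
class SUVVolume:
    """3-D SUV image (dimensionless g/mL) on a fixed grid."""

    voxels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("SUV volume must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive mm values")
        if np.any(self.voxels < 0) or not np.all(np.isfinite(self.voxels)):
            raise ValueError("SUV must be finite and non-negative")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class VOIMask:
    """Boolean volume-of-interest mask on the same grid as the image it indexes."""

    voxels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive mm values")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0

    def require_nonempty(self, what: str = "mask") -> None:
        if self.is_empty:
            raise ValueError(f"{what} is empty")

    def check_same_grid(self, other) -> None:
        _check_grid(
            self.spacing,
            other.spacing,
            self.voxels.shape,
            other.voxels.shape if other.voxels.ndim == 3 else other.voxels.shape[1:],
            "mask vs image",
        )


@dataclass
class SubjectRecord:
    """Cohort bookkeeping for one subject (label 1 = IDH-mutant)."""

    subject_id: str
    image: str | list[str]
    injected_activity_mbq: float
    body_weight_kg: float
    label: int
    mask: str | None = None
    reference_center_mm: tuple[float, float, float] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (IDH-wt) or 1 (IDH-mut)")
        if self.injected_activity_mbq <= 0 or self.body_weight_kg <= 0:
            raise ValueError("injected activity and body weight must be positive")


# ---------------------------------------------------------------------------
# NIfTI reading / writing


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing, np.asarray(img.affine)


def read_dynamic(
    paths: str | Path | Sequence[str | Path],
    schedule: FrameSchedule,
    units: str = "kBq/mL",
) -> DynamicPETVolume:
    """Read a dynamic series from one 4-D NIfTI or a list of 3-D frame files.

    Grids of all frames must be identical; the frame count must match the
    schedule.  ``units`` declares the stored activity unit; anything other
    than kBq/mL is rescaled at load.
    """
    if units not in _ACTIVITY_UNITS:
        raise ValueError(f"unknown activity unit {units!r}")
    scale = _ACTIVITY_UNITS[units]

    if isinstance(paths, (str, Path)):
        data, spacing, affine = _load_nifti(paths)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{paths}: expected 3-D or 4-D image, got {data.ndim}-D")
        frames = np.moveaxis(data, -1, 0)
    else:
        vols = []
        spacing = affine = None
        ref_shape = None
        for i, p in enumerate(paths):
            data, sp, aff = _load_nifti(p)
            if data.ndim != 3:
                raise ValueError(f"{p}: frame files must be 3-D")
            if spacing is None:
                spacing, affine, ref_shape = sp, aff, data.shape
            else:
                try:
                    _check_grid(spacing, sp, ref_shape, data.shape, "frame grid")
                except GridMismatchError as e:
                    raise GridMismatchError(f"frame {i} ({p}): {e}") from None
                if not np.allclose(affine, aff, atol=1e-5):
                    raise GridMismatchError(f"frame {i} ({p}): affine differs")
            vols.append(data)
        frames = np.stack(vols, axis=0)

    if frames.shape[0] != len(schedule):
        raise ValueError(
            f"{frames.shape[0]} frames read but schedule defines {len(schedule)}"
        )
    return DynamicPETVolume(frames * scale, spacing, schedule, affine=affine)


def read_mask(path: str | Path, reference_grid: SUVVolume | DynamicPETVolume) -> VOIMask:
    """Read a mask (nonzero -> True) and verify it shares the reference grid."""
    data, spacing, affine = _load_nifti(path)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    ref_shape = (
        reference_grid.voxels.shape
        if reference_grid.voxels.ndim == 3
        else reference_grid.voxels.shape[1:]
    )
    _check_grid(spacing, reference_grid.spacing, data.shape, ref_shape, f"mask {path}")
    return VOIMask(data != 0, spacing, affine=affine)


def write_volume(obj: DynamicPETVolume | SUVVolume | VOIMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1; round-trips voxels, spacing, affine."""
    if isinstance(obj, DynamicPETVolume):
        data = np.moveaxis(obj.voxels, 0, -1)
    elif isinstance(obj, VOIMask):
        data = obj.voxels.astype(np.uint8)
    else:
        data = obj.voxels
    img = nib.Nifti1Image(np.asarray(data), obj.affine)
    img.header.set_zooms((*obj.spacing, *([1.0] if data.ndim == 4 else [])))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables

_COHORT_COLS = ["subject_id", "image", "mask", "injected_activity_MBq", "body_weight_kg", "label"]


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = {"subject_id", "image", "injected_activity_MBq", "body_weight_kg", "label"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        image = row["image"]
        if isinstance(image, str) and ";" in image:
            image = image.split(";")
        mask = row.get("mask")
        if isinstance(mask, float) and np.isnan(mask):
            mask = None
        center = None
        if "ref_x_mm" in df.columns and np.isfinite(row["ref_x_mm"]):
            center = (row["ref_x_mm"], row["ref_y_mm"], row["ref_z_mm"])
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                image=image,
                mask=mask,
                injected_activity_mbq=float(row["injected_activity_MBq"]),
                body_weight_kg=float(row["body_weight_kg"]),
                label=int(row["label"]),
                reference_center_mm=center,
            )
        )
    return records


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        image = ";".join(r.image) if isinstance(r.image, list) else r.image
        row = {
            "subject_id": r.subject_id,
            "image": image,
            "mask": r.mask or "",
            "injected_activity_MBq": r.injected_activity_mbq,
            "body_weight_kg": r.body_weight_kg,
            "label": r.label,
        }
        if r.reference_center_mm is not None:
            row["ref_x_mm"], row["ref_y_mm"], row["ref_z_mm"] = r.reference_center_mm
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
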