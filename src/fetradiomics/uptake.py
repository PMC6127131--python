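"""Standard FET PET uptake parameters.

The clinical reading of an amino-acid PET scan in this pipeline rests on a
handful of conventional quantities:

* a summed 20-40 min post-injection SUV image,
* the mean SUV of a 30 mm spherical reference VOI in normal-appearing brain,
* the biological tumor volume (BTV) from 3-D auto-contouring at a
  tumor-to-brain ratio (TBR) of 1.6 or more,
* TBR_mean and TBR_max of the tumor VOI,
* the tumor time-activity curve (TAC) with its time-to-peak (TTP) and the
  slope of a linear fit to the late (20-50 min) phase, in SUV/h.

Decreasing late-phase curves (negative slope, early TTP) are the pattern
typical of IDH-wildtype gliomas; slowly increasing curves of IDH-mutant
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import DynamicPETVolume, SUVVolume, VOIMask

__all__ = [
    "TimeActivityCurve",
    "StandardParams",
    "InclusionResult",
    "suv_scale",
    "sum_window",
    "reference_voi",
    "auto_contour",
    "tumor_tbr",
    "extract_tac",
    "compute_ttp",
    "compute_slope",
    "check_inclusion",
    "compute_standard_params",
]

#: 26-connectivity structuring element for 3-D component labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)

TBR_THRESHOLD = 1.6
MIN_BTV_VOXELS = 100
SUM_WINDOW = (20.0, 40.0)
SLOPE_WINDOW = (20.0, 50.0)
REF_DIAMETER_MM = 30.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean tumor SUV per frame, indexed by frame mid-times (minutes)."""

    mid_times: np.ndarray
    mean_suv: np.ndarray

    def __post_init__(self):
        mt = np.asarray(self.mid_times, dtype=float)
        ms = np.asarray(self.mean_suv, dtype=float)
        object.__setattr__(self, "mid_times", mt)
        object.__setattr__(self, "mean_suv", ms)
        if mt.shape != ms.shape or mt.ndim != 1 or mt.size == 0:
            raise ValueError("mid_times and mean_suv must be equal-length 1-D arrays")
        if np.any(np.diff(mt) <= 0):
            raise ValueError("mid-times must be strictly increasing")


@dataclass(frozen=True)
class StandardParams:
    """The four standard parameters plus the biological tumor volume."""

    tbr_mean: float
    tbr_max: float
    ttp_min: float
    slope_suv_per_h: float
    btv_voxels: int
    btv_ml: float


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the cohort inclusion filters on one subject.

    ``reason`` is ``None`` when included, ``"no_pathological_uptake"`` when
    no voxel reaches the TBR threshold (criterion v), or ``"btv_too_small"``
    when the contoured lesion has <= ``MIN_BTV_VOXELS`` voxels (criterion vi).
    """

    included: bool
    reason: str | None
    btv_voxels: int


def suv_scale(
    dyn: DynamicPETVolume, injected_activity_mbq: float, body_weight_kg: float
) -> DynamicPETVolume:
    """Normalise activity concentration to SUV.

    SUV divides tissue radioactivity (kBq/mL) by the injected radioactivity
    per gram of body weight; with activity in MBq and weight in kg the
    voxelwise factor reduces to ``weight_kg / activity_MBq``.
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    factor = body_weight_kg / injected_activity_mbq
    return DynamicPETVolume(
        dyn.voxels * factor,
        dyn.spacing,
        dyn.schedule,
        affine=dyn.affine,
        suv_scaled=True,
    )


def sum_window(dyn: DynamicPETVolume, t0: float = 20.0, t1: float = 40.0) -> SUVVolume:
    """Duration-weighted mean image over the frames overlapping [t0, t1] min.

    Each frame is weighted by the length of its overlap with the window;
    with the standard schedule and the default 20-40 min window this is the
    plain mean of the four 5-min frames.
    """
    if t1 <= t0:
        raise ValueError("window must satisfy t0 < t1")
    sched = dyn.schedule
    overlap = np.minimum(sched.end, t1) - np.maximum(sched.start, t0)
    weights = np.clip(overlap, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError(f"no frame overlaps window [{t0}, {t1}] min")
    weights = weights / weights.sum()
    summed = np.tensordot(weights, dyn.voxels, axes=(0, 0))
    return SUVVolume(np.clip(summed, 0.0, None), dyn.spacing, affine=dyn.affine)


def _voxel_centers_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return axes


def reference_voi(
    suv: SUVVolume, center_mm: tuple[float, float, float], diameter_mm: float = REF_DIAMETER_MM
) -> tuple[VOIMask, float]:
    """Spherical reference VOI (default 30 mm diameter, 14.2 mL).

    The mask contains every voxel whose physical centre lies within
    ``diameter/2`` of ``center_mm``; the sphere must lie entirely inside the
    grid because a clipped reference would bias the brain background mean.
    """
    radius = diameter_mm / 2.0
    shape = suv.voxels.shape
    extent = (np.asarray(shape) - 1) * suv.spacing
    center = np.asarray(center_mm, dtype=float)
    if np.any(center - radius < 0) or np.any(center + radius > extent):
        raise ValueError(
            f"reference sphere (centre {center_mm}, r={radius} mm) clipped by grid"
        )
    ax, ay, az = _voxel_centers_mm(shape, suv.spacing)
    d2 = (
        (ax[:, None, None] - center[0]) ** 2
        + (ay[None, :, None] - center[1]) ** 2
        + (az[None, None, :] - center[2]) ** 2
    )
    mask = VOIMask(d2 <= radius**2, suv.spacing, affine=suv.affine)
    mask.require_nonempty("reference VOI")
    return mask, float(suv.voxels[mask.voxels].mean())


def auto_contour(
    suv: SUVVolume,
    ref_mean: float,
    threshold: float = TBR_THRESHOLD,
    seed_point: tuple[int, int, int] | None = None,
) -> VOIMask:
    """3-D auto-contour of the biological tumor volume at TBR >= threshold.

    Thresholds the SUV image at ``threshold * ref_mean`` and keeps the
    26-connected component containing ``seed_point`` (voxel indices) when
    given, else the largest component.  An empty mask (no voxel above
    threshold, or seed outside every component) is returned as-is; the
    inclusion filter flags it downstream.
    """
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    above = suv.voxels >= threshold * ref_mean
    if not above.any():
        return VOIMask(above, suv.spacing, affine=suv.affine)
    labels, n = ndimage.label(above, structure=_CONN26)
    if seed_point is not None:
        lab = labels[tuple(seed_point)]
        keep = labels == lab if lab > 0 else np.zeros_like(above)
    else:
        counts = np.bincount(labels.ravel())[1:]
        keep = labels == (int(np.argmax(counts)) + 1)
    return VOIMask(keep, suv.spacing, affine=suv.affine)


def tumor_tbr(suv: SUVVolume, tumor_mask: VOIMask, ref_mean: float) -> tuple[float, float]:
    """TBR_mean and TBR_max: tumor mean / max SUV over the brain reference mean."""
    tumor_mask.require_nonempty("tumor VOI")
    tumor_mask.check_same_grid(suv)
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    vals = suv.voxels[tumor_mask.voxels]
    return float(vals.mean() / ref_mean), float(vals.max() / ref_mean)


def extract_tac(dyn_suv: DynamicPETVolume, tumor_mask: VOIMask) -> TimeActivityCurve:
    """Mean SUV per frame over a fixed tumor mask."""
    tumor_mask.require_nonempty("tumor VOI")
    tumor_mask.check_same_grid(dyn_suv)
    m = tumor_mask.voxels
    means = dyn_suv.voxels[:, m].mean(axis=1)
    return TimeActivityCurve(dyn_suv.schedule.mid_times, means)


def compute_ttp(tac: TimeActivityCurve) -> float:
    """Time-to-peak: mid-time of the frame with maximal mean SUV (minutes).

    Ties resolve to the earliest such frame.
    """
    return float(tac.mid_times[int(np.argmax(tac.mean_suv))])


def compute_slope(
    tac: TimeActivityCurve, window: tuple[float, float] = SLOPE_WINDOW
) -> float:
    """Late-phase slope in SUV/h: OLS fit of mean SUV on mid-time (hours)
    over frames whose mid-time falls inside ``window`` (minutes)."""
    t0, t1 = window
    sel = (tac.mid_times >= t0) & (tac.mid_times <= t1)
    if sel.sum() < 2:
        raise ValueError(f"need >= 2 frames with mid-time in [{t0}, {t1}] min")
    t_h = tac.mid_times[sel] / 60.0
    y = tac.mean_suv[sel]
    slope, _ = np.polyfit(t_h, y, 1)
    return float(slope)


def check_inclusion(btv: VOIMask, min_voxels: int = MIN_BTV_VOXELS) -> InclusionResult:
    """Cohort inclusion filters: pathological uptake exists and BTV > min_voxels."""
    n = btv.n_voxels
    if n == 0:
        return InclusionResult(False, "no_pathological_uptake", 0)
    if n <= min_voxels:
        return InclusionResult(False, "btv_too_small", n)
    return InclusionResult(True, None, n)


def compute_standard_params(
    dyn_suv: DynamicPETVolume,
    ref_center_mm: tuple[float, float, float],
    tumor_mask: VOIMask | None = None,
    sum_win: tuple[float, float] = SUM_WINDOW,
    slope_win: tuple[float, float] = SLOPE_WINDOW,
    tbr_threshold: float = TBR_THRESHOLD,
    ref_diameter_mm: float = REF_DIAMETER_MM,
) -> tuple[StandardParams, SUVVolume, VOIMask, float, InclusionResult]:
    """Full standard-parameter readout for one SUV-scaled dynamic volume.

    Returns (params, summed image, tumor mask, reference mean, inclusion).
    When ``tumor_mask`` is None the BTV is auto-contoured on the summed
    image.  ``params`` is None-equivalent (all-NaN) for excluded subjects.
    """
    summed = sum_window(dyn_suv, *sum_win)
    _, ref_mean = reference_voi(summed, ref_center_mm, ref_diameter_mm)
    if tumor_mask is None:
        tumor_mask = auto_contour(summed, ref_mean, tbr_threshold)
    inclusion = check_inclusion(tumor_mask)
    if not inclusion.included:
        nan = float("nan")
        params = StandardParams(nan, nan, nan, nan, tumor_mask.n_voxels, tumor_mask.volume_ml)
        return params, summed, tumor_mask, ref_mean, inclusion
    tbr_mean, tbr_max = tumor_tbr(summed, tumor_mask, ref_mean)
    tac = extract_tac(dyn_suv, tumor_mask)
    params = StandardParams(
        tbr_mean=tbr_mean,
        tbr_max=tbr_max,
        ttp_min=compute_ttp(tac),
        slope_suv_per_h=compute_slope(tac, slope_win),
        btv_voxels=tumor_mask.n_voxels,
        btv_ml=tumor_mask.volume_ml,
    )
    return params, summed, tumor_mask, ref_mean, inclusion
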