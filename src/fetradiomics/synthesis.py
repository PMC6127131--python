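"""Synthetic dynamic FET-PET cohort generator.

Emulates already-reconstructed dynamic scans of glioma patients on the
16-frame 0-50 min schedule (5 x 1, 5 x 3, 6 x 5 min): an ellipsoidal tumor
with a multiplicative lognormal intratumoral texture field sits in a
homogeneous brain background, each frame scaled by a subject-specific
time-activity-curve shape, blurred by the scanner point-spread function
(about 6 mm FWHM for a stand-alone PET scanner, about 3 mm for a
high-resolution hybrid PET/MR system) and degraded by additive Gaussian
noise.  Injected dose follows the 3 MBq/kg protocol.

The per-class calibration mirrors the observable contrast between
IDH-wildtype and IDH-mutant gliomas: wildtype curves fall in the late
phase (negative slope, early time-to-peak), mutant curves rise; the
wildtype class additionally defaults to a more heterogeneous intratumoral
texture.

TAC construction is calibrated to the *measurement*, not to a kinetic
model: frame values are built so that the ordinary-least-squares slope
over the 20-50 min window equals the drawn slope target exactly, the
duration-weighted 20-40 min mean equals the drawn TBR target exactly, and
the curve maximum falls in the frame containing the drawn time-to-peak
(a slope- and mean-neutral peak perturbation pins the argmax).  A curve
literally following "linear rise, then linear decline" would not have this
closure property: pre-peak rise frames inside the regression window would
contaminate the fitted slope, and a rising late phase would always peak in
the final frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    DynamicPETVolume,
    FrameSchedule,
    SubjectRecord,
    VOIMask,
    default_schedule,
    write_cohort,
    write_schedule,
    write_volume,
)
from .uptake import SLOPE_WINDOW, SUM_WINDOW

__all__ = [
    "ClassTacParams",
    "CohortConfig",
    "GroundTruth",
    "subgroup_i_params",
    "subgroup_ii_params",
    "default_config",
    "sample_tac_shape",
    "render_subject",
    "generate_cohort",
]

DOSE_MBQ_PER_KG = 3.0


@dataclass(frozen=True)
class ClassTacParams:
    """Per-class targets for the observable uptake parameters.

    Means and SDs of TBR_mean (dimensionless), TTP (minutes) and late
    slope (SUV/h); ``heterogeneity`` in [0, 1] is the log-amplitude of the
    multiplicative intratumoral texture field.
    """

    tbr_mean_mu: float
    tbr_mean_sd: float
    ttp_mu: float
    ttp_sd: float
    slope_mu: float
    slope_sd: float
    heterogeneity: float

    def __post_init__(self):
        if min(self.tbr_mean_sd, self.ttp_sd, self.slope_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.heterogeneity <= 1.0:
            raise ValueError("heterogeneity must lie in [0, 1]")


def subgroup_i_params() -> dict[int, ClassTacParams]:
    """Stand-alone-scanner cohort calibration (41 wt / 15 mut)."""
    return {
        0: ClassTacParams(2.2, 0.3, 28.0, 9.6, -0.2, 0.5, heterogeneity=0.35),
        1: ClassTacParams(2.3, 0.5, 39.2, 7.7, 0.2, 0.5, heterogeneity=0.15),
    }


def subgroup_ii_params() -> dict[int, ClassTacParams]:
    """Hybrid PET/MR cohort calibration (17 wt / 11 mut)."""
    return {
        0: ClassTacParams(2.3, 0.5, 28.7, 12.2, -0.4, 0.6, heterogeneity=0.35),
        1: ClassTacParams(1.9, 0.2, 34.8, 6.5, 0.3, 0.3, heterogeneity=0.15),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to render one labelled cohort reproducibly."""

    n_wt: int = 41
    n_mut: int = 15
    schedule: FrameSchedule = field(default_factory=default_schedule)
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_suv: float = 1.0
    bg_variation_sd: float = 0.02
    tumor_radius_range_mm: tuple[float, float] = (8.0, 14.0)
    tumor_center_frac: tuple[float, float, float] = (0.28, 0.5, 0.5)
    ref_center_frac: tuple[float, float, float] = (0.72, 0.5, 0.5)
    psf_fwhm_mm: float = 6.0
    noise_sd: float = 0.05
    core_radius_fraction: float = 0.0
    core_uptake_multiplier: float = 1.0
    seed: int = 0
    class_params: dict[int, ClassTacParams] = field(default_factory=subgroup_i_params)

    def __post_init__(self):
        if self.n_wt < 1 or self.n_mut < 1:
            raise ValueError("need at least one subject per class")
        if self.psf_fwhm_mm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be non-negative")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing_mm)
        if self.tumor_radius_range_mm[1] * 2 > extent.min():
            raise ValueError("tumor radius range too large for the grid")

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    @property
    def tumor_center_mm(self) -> np.ndarray:
        return self.extent_mm * np.asarray(self.tumor_center_frac)

    @property
    def ref_center_mm(self) -> np.ndarray:
        return self.extent_mm * np.asarray(self.ref_center_frac)


def default_config(**overrides) -> CohortConfig:
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


@dataclass
class GroundTruth:
    """What the generator actually put into one subject's volume."""

    subject_id: str
    label: int
    tbr_mean_target: float
    ttp_drawn_min: float
    ttp_frame_mid_min: float
    slope_target_suv_h: float
    heterogeneity: float
    n_tumor_voxels: int
    tumor_mask: VOIMask | None = None
    tbr_curve: np.ndarray | None = None


# ---------------------------------------------------------------------------
# TAC construction


def _sum_window_weights(schedule: FrameSchedule, t0: float, t1: float) -> np.ndarray:
    overlap = np.clip(np.minimum(schedule.end, t1) - np.maximum(schedule.start, t0), 0, None)
    return overlap / overlap.sum()


def _peak_bump(t_w, w_w, k_local, y, margin):
    """Slope-, intercept- and mean-neutral perturbation of the window frame
    values making frame ``k_local`` the strict maximum by ``margin``.

    Returns the perturbation vector, or None if the projection direction
    cannot separate the peak (never the case for the standard schedule).
    """
    n = t_w.size
    C = np.vstack([np.ones(n), t_w, w_w])
    e = np.zeros(n)
    e[k_local] = 1.0
    # project e onto the null space of C
    u = e - C.T @ np.linalg.solve(C @ C.T, C @ e)
    gaps = y - y[k_local] + margin  # amount frame j must end up below the peak
    beta_req = 0.0
    for j in range(n):
        if j == k_local:
            continue
        du = u[k_local] - u[j]
        if du > 1e-12:
            beta_req = max(beta_req, gaps[j] / du)
        elif gaps[j] > 0:
            return None
    return beta_req * u


def sample_tac_shape(
    params: ClassTacParams,
    rng: np.random.Generator,
    schedule: FrameSchedule | None = None,
    background_suv: float = 1.0,
    max_retries: int = 10,
) -> tuple[np.ndarray, dict]:
    """Draw one subject's per-frame tumor TBR curve.

    Returns ``(tbr_per_frame, targets)``; the curve satisfies, exactly and
    by construction, the three closure properties described in the module
    docstring.  Draws producing a non-positive curve are redrawn a bounded
    number of times before raising.
    """
    schedule = schedule or default_schedule()
    mids = schedule.mid_times
    w_all = _sum_window_weights(schedule, *SUM_WINDOW)
    in_slope = (mids >= SLOPE_WINDOW[0]) & (mids <= SLOPE_WINDOW[1])
    W = np.flatnonzero(in_slope)
    if W.size < 3:
        raise ValueError("schedule has too few late frames for TAC construction")
    if w_all[~in_slope].sum() > 1e-9:
        raise ValueError("sum window must be contained in the slope window frames")
    t_w = mids[W]
    w_w = w_all[W]

    last_err = None
    for _ in range(max_retries):
        tbr_target = rng.normal(params.tbr_mean_mu, params.tbr_mean_sd)
        # inclusion-criterion truncation: the emulated cohort consists of
        # patients with clearly pathological uptake
        tbr_target = max(tbr_target, 1.75)
        ttp = float(np.clip(rng.normal(params.ttp_mu, params.ttp_sd), mids[0], schedule.end[-1]))
        slope_suv_h = rng.normal(params.slope_mu, params.slope_sd)
        slope_tbr_h = slope_suv_h / background_suv

        # late-phase line with exact OLS slope and exact 20-40 min mean
        a = tbr_target - slope_tbr_h * float(w_w @ (t_w / 60.0))
        y_w = a + slope_tbr_h * t_w / 60.0

        k = schedule.frame_containing(ttp)
        margin = 0.05
        if k in W:
            k_local = int(np.flatnonzero(W == k)[0])
            needs_bump = not (k == W[-1] and slope_tbr_h >= 0)
            if needs_bump:
                bump = _peak_bump(t_w, w_w, k_local, y_w, margin)
                if bump is None:
                    last_err = ValueError("peak placement infeasible")
                    continue
                y_w = y_w + bump
        tbr = np.empty(len(schedule))
        tbr[W] = y_w
        first = W[0]
        if k < first:
            # early peak: rise to a supra-window value, then descend
            peak_val = y_w.max() + margin
            t_k = mids[k]
            pre = mids[:first]
            rise = pre <= t_k
            tbr[:first][rise] = peak_val * pre[rise] / t_k
            frac = (pre[~rise] - t_k) / (t_w[0] - t_k)
            tbr[:first][~rise] = peak_val + frac * (y_w[0] - peak_val)
        else:
            # plain rise from zero toward the first late frame
            tbr[:first] = y_w[0] * mids[:first] / t_w[0]
        if tbr.min() <= 0:
            last_err = ValueError("drawn slope makes the curve non-positive")
            continue
        targets = {
            "tbr_mean_target": float(tbr_target),
            "ttp_drawn_min": ttp,
            "ttp_frame_mid_min": float(mids[k]),
            "slope_target_suv_h": float(slope_suv_h),
        }
        return tbr, targets
    raise ValueError(f"could not draw a valid TAC shape after {max_retries} tries: {last_err}")


# ---------------------------------------------------------------------------
# Volume rendering


def _smooth_field(shape, rng, sigma_vox=1.0):
    z = rng.standard_normal(shape)
    z = ndimage.gaussian_filter(z, sigma_vox)
    return (z - z.mean()) / z.std()


def _ellipsoid_mask(config: CohortConfig, semi_axes_mm, center_mm) -> np.ndarray:
    shape = config.grid_shape
    spacing = np.asarray(config.spacing_mm)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    u = [(ax - c) / r for ax, c, r in zip(axes, center_mm, semi_axes_mm)]
    d2 = u[0][:, None, None] ** 2 + u[1][None, :, None] ** 2 + u[2][None, None, :] ** 2
    return d2 <= 1.0


def render_subject(
    config: CohortConfig,
    label: int,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> tuple[DynamicPETVolume, GroundTruth, SubjectRecord]:
    """Render one subject's dynamic volume (in kBq/mL) plus ground truth."""
    params = config.class_params[label]
    spacing = np.asarray(config.spacing_mm, dtype=float)
    shape = config.grid_shape

    tbr_curve, targets = sample_tac_shape(
        params, rng, config.schedule, config.background_suv
    )

    mean_r = rng.uniform(*config.tumor_radius_range_mm)
    semi_axes = mean_r * rng.uniform(0.8, 1.2, size=3)
    tumor = _ellipsoid_mask(config, semi_axes, config.tumor_center_mm)
    if not tumor.any():
        raise ValueError("tumor does not fit the grid")
    extent = config.extent_mm
    if np.any(config.tumor_center_mm - semi_axes < 0) or np.any(
        config.tumor_center_mm + semi_axes > extent
    ):
        raise ValueError("tumor does not fit the grid")

    # multiplicative lognormal texture, correlation length ~2 voxels,
    # renormalised to mean 1 over the tumor so the TBR target is preserved
    if params.heterogeneity > 0:
        z = _smooth_field(shape, rng)
        texture = np.exp(params.heterogeneity * z)
        texture /= texture[tumor].mean()
    else:
        rng.standard_normal(shape)  # keep the stream aligned across settings
        texture = np.ones(shape)

    if config.core_radius_fraction > 0:
        core = _ellipsoid_mask(
            config, semi_axes * config.core_radius_fraction, config.tumor_center_mm
        )
        texture = np.where(core, texture * config.core_uptake_multiplier, texture)

    if config.bg_variation_sd > 0:
        bg = config.background_suv * (1.0 + config.bg_variation_sd * _smooth_field(shape, rng))
    else:
        rng.standard_normal(shape)
        bg = np.full(shape, config.background_suv)

    sigma_vox = (
        config.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spacing
        if config.psf_fwhm_mm > 0
        else None
    )
    frames = np.empty((len(config.schedule), *shape))
    tumor_tex = config.background_suv * texture[tumor]
    for f, tbr_f in enumerate(tbr_curve):
        img = bg.copy()
        img[tumor] = tbr_f * tumor_tex
        if sigma_vox is not None:
            img = ndimage.gaussian_filter(img, sigma_vox)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, shape)
        frames[f] = np.clip(img, 0.0, None)

    body_weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 110.0))
    activity_mbq = DOSE_MBQ_PER_KG * body_weight
    # SUV -> kBq/mL: activity per gram is exactly the per-kg dose
    conc = frames * (activity_mbq / body_weight)

    dyn = DynamicPETVolume(conc, spacing, config.schedule)
    truth = GroundTruth(
        subject_id=subject_id,
        label=label,
        heterogeneity=params.heterogeneity,
        n_tumor_voxels=int(tumor.sum()),
        tumor_mask=VOIMask(tumor, spacing),
        tbr_curve=tbr_curve,
        **targets,
    )
    record = SubjectRecord(
        subject_id=subject_id,
        image=f"{subject_id}.nii.gz",
        injected_activity_mbq=activity_mbq,
        body_weight_kg=body_weight,
        label=label,
        reference_center_mm=tuple(config.ref_center_mm),
    )
    return dyn, truth, record


@dataclass
class CohortData:
    records: list[SubjectRecord]
    volumes: list[DynamicPETVolume]
    truths: list[GroundTruth]
    config: CohortConfig

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "label": t.label,
                    "tbr_mean_target": t.tbr_mean_target,
                    "ttp_drawn_min": t.ttp_drawn_min,
                    "ttp_frame_mid_min": t.ttp_frame_mid_min,
                    "slope_target_suv_h": t.slope_target_suv_h,
                    "heterogeneity": t.heterogeneity,
                    "n_tumor_voxels": t.n_tumor_voxels,
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig, out_dir=None) -> CohortData:
    """Render the full labelled cohort, reproducibly from ``config.seed``.

    Subjects are rendered wildtype-first then mutant, each from an
    independent child of the seed sequence.  When ``out_dir`` is given the
    volumes, true masks, cohort CSV, schedule CSV and ground-truth CSV are
    written there in a layout ``read_cohort`` can consume.
    """
    labels = [0] * config.n_wt + [1] * config.n_mut
    seeds = np.random.SeedSequence(config.seed).spawn(len(labels))
    records, volumes, truths = [], [], []
    for i, (label, ss) in enumerate(zip(labels, seeds)):
        sid = f"sub-{i:03d}"
        dyn, truth, record = render_subject(
            config, label, np.random.default_rng(ss), subject_id=sid
        )
        records.append(record)
        volumes.append(dyn)
        truths.append(truth)
    cohort = CohortData(records, volumes, truths, config)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for record, dyn, truth in zip(records, volumes, truths):
            write_volume(dyn, out / f"{record.subject_id}.nii.gz")
            write_volume(truth.tumor_mask, out / f"{record.subject_id}_truemask.nii.gz")
        write_cohort(records, out / "cohort.csv")
        write_schedule(config.schedule, out / "schedule.csv")
        cohort.truth_table().to_csv(out / "ground_truth.csv", index=False)
    return cohort
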