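"""End-to-end orchestration: simulate -> extract -> fit.

``run_all`` drives the three stages from a single config and leaves a
reproducibility manifest next to the outputs; every stochastic stage is
seeded, so re-running an unchanged config reproduces features.csv and
models.csv bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    FrameSchedule,
    SubjectRecord,
    read_cohort,
    read_dynamic,
    read_mask,
    read_schedule,
)
from .synthesis import ClassTacParams, CohortConfig, CohortData, generate_cohort
from .texture import FEATURE_NAMES, extract_features
from .uptake import compute_standard_params, suv_scale
from .modeling import run_model_search

__all__ = ["RunConfig", "extract_subject", "extract_cohort_features", "run_all", "load_config"]

log = logging.getLogger("fetradiomics")

#: the protocol defaults, kept together so deviations show up in one diff
DEFAULTS = {
    "tbr_threshold": 1.6,
    "sum_window": (20.0, 40.0),
    "slope_window": (20.0, 50.0),
    "ref_diameter_mm": 30.0,
    "n_grey_levels": 64,
    "cv_folds": (5, 10),
}


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    write_volumes: bool = False
    tbr_threshold: float = DEFAULTS["tbr_threshold"]
    sum_window: tuple[float, float] = DEFAULTS["sum_window"]
    slope_window: tuple[float, float] = DEFAULTS["slope_window"]
    ref_diameter_mm: float = DEFAULTS["ref_diameter_mm"]
    n_grey_levels: int = DEFAULTS["n_grey_levels"]
    cv_folds: tuple[int, ...] = DEFAULTS["cv_folds"]
    cv_seed: int = 17
    m_bonferroni: int | None = None


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys keep defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {})
    class_params = cohort_raw.pop("class_params", None)
    cohort_kwargs = dict(cohort_raw)
    for key in ("grid_shape", "spacing_mm", "tumor_radius_range_mm",
                "tumor_center_frac", "ref_center_frac"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    if class_params is not None:
        cohort_kwargs["class_params"] = {
            int(k): ClassTacParams(**v) for k, v in class_params.items()
        }
    cfg_kwargs = dict(raw)
    for key in ("sum_window", "slope_window", "cv_folds"):
        if key in cfg_kwargs:
            cfg_kwargs[key] = tuple(cfg_kwargs[key])
    return RunConfig(cohort=CohortConfig(**cohort_kwargs), **cfg_kwargs)


def extract_subject(
    dyn,
    record: SubjectRecord,
    tumor_mask=None,
    tbr_threshold: float = DEFAULTS["tbr_threshold"],
    sum_window: tuple[float, float] = DEFAULTS["sum_window"],
    slope_window: tuple[float, float] = DEFAULTS["slope_window"],
    ref_diameter_mm: float = DEFAULTS["ref_diameter_mm"],
    n_grey_levels: int = DEFAULTS["n_grey_levels"],
) -> tuple[dict | None, list[str]]:
    """Standard + texture feature row for one subject; (None, log) if excluded."""
    qc: list[str] = []
    dyn_suv = suv_scale(dyn, record.injected_activity_mbq, record.body_weight_kg)
    if record.reference_center_mm is None:
        raise ValueError(f"{record.subject_id}: no reference-VOI centre available")
    params, summed, mask, ref_mean, inclusion = compute_standard_params(
        dyn_suv,
        record.reference_center_mm,
        tumor_mask=tumor_mask,
        sum_win=sum_window,
        slope_win=slope_window,
        tbr_threshold=tbr_threshold,
        ref_diameter_mm=ref_diameter_mm,
    )
    if not inclusion.included:
        qc.append(f"{record.subject_id}: EXCLUDED ({inclusion.reason}, btv={inclusion.btv_voxels})")
        return None, qc
    feats, flagged = extract_features(summed, mask, n_levels=n_grey_levels)
    if flagged:
        qc.append(f"{record.subject_id}: degenerate features -> NaN: {', '.join(flagged)}")
    row = {
        "subject_id": record.subject_id,
        "label": record.label,
        "tbr_mean": params.tbr_mean,
        "tbr_max": params.tbr_max,
        "ttp_min": params.ttp_min,
        "slope_suv_per_h": params.slope_suv_per_h,
        "btv_voxels": params.btv_voxels,
        "btv_ml": params.btv_ml,
    }
    row.update(feats)
    return row, qc


def extract_cohort_features(
    cohort: CohortData | None = None,
    cohort_csv: str | Path | None = None,
    schedule: FrameSchedule | None = None,
    **extraction_kwargs,
) -> tuple[pd.DataFrame, list[str]]:
    """Feature table for a whole cohort, in-memory or from disk.

    Pass either a ``CohortData`` (from :func:`generate_cohort`) or a cohort
    CSV plus schedule; excluded subjects are logged and skipped.
    """
    rows, qc_all = [], []
    if cohort is not None:
        items = zip(cohort.volumes, cohort.records)
        for dyn, record in items:
            row, qc = extract_subject(dyn, record, **extraction_kwargs)
            qc_all.extend(qc)
            if row is not None:
                rows.append(row)
    else:
        if cohort_csv is None or schedule is None:
            raise ValueError("need either a CohortData or cohort_csv + schedule")
        base = Path(cohort_csv).parent
        for record in read_cohort(cohort_csv):
            paths = record.image
            if isinstance(paths, list):
                paths = [base / p for p in paths]
            else:
                paths = base / paths
            dyn = read_dynamic(paths, schedule)
            tumor_mask = read_mask(base / record.mask, dyn) if record.mask else None
            row, qc = extract_subject(dyn, record, tumor_mask=tumor_mask, **extraction_kwargs)
            qc_all.extend(qc)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows), qc_all


def _manifest(config: RunConfig) -> dict:
    def unpack(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, FrameSchedule):
            return {"start_min": obj.start.tolist(), "duration_min": obj.duration.tolist()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {str(k): unpack(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [unpack(v) for v in obj]
        return obj

    d = {k: unpack(v) for k, v in dataclasses.asdict(config).items()}
    # asdict loses the FrameSchedule custom repr; redo it explicitly
    d["cohort"]["schedule"] = unpack(config.cohort.schedule)
    d["package_version"] = __version__
    return d


def run_all(config: RunConfig) -> Path:
    """Simulate, extract and fit; returns the artifacts directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_lines: list[str] = []

    stage = "simulate"
    try:
        cohort = generate_cohort(
            config.cohort, out_dir=out / "volumes" if config.write_volumes else None
        )
        qc_lines.append(
            f"simulated {len(cohort.records)} subjects "
            f"({config.cohort.n_wt} wt / {config.cohort.n_mut} mut), seed {config.cohort.seed}"
        )
        cohort.truth_table().to_csv(out / "ground_truth.csv", index=False)

        stage = "extract"
        features, qc = extract_cohort_features(
            cohort,
            tbr_threshold=config.tbr_threshold,
            sum_window=config.sum_window,
            slope_window=config.slope_window,
            ref_diameter_mm=config.ref_diameter_mm,
            n_grey_levels=config.n_grey_levels,
        )
        qc_lines.extend(qc)
        features.to_csv(out / "features.csv", index=False)
        qc_lines.append(f"extracted features for {len(features)} included subjects")

        stage = "fit"
        models = run_model_search(
            features,
            cv_folds=config.cv_folds,
            cv_seed=config.cv_seed,
            m_bonferroni=config.m_bonferroni,
        )
        models.to_csv(out / "models.csv", index=False)
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    (out / "qc.log").write_text("\n".join(qc_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2) + "\n")
    return out
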