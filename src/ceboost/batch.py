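"""Batch driver: run the CE-boost pipeline + QA plan over phantom replicates.

This is the glue that produces the study-style comparison table on
synthetic data: for each seed it generates a paired pre/enhanced phantom,
runs CE-boost, measures every segment on both the conventional (enhanced)
and boosted volume, and stacks the records into the long table that
:func:`ceboost.stats_report.compare_report` consumes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .boost import BoostParams, ce_boost_pipeline
from .phantom import PhantomSpec, default_head_neck_spec, make_phantom
from .qa import LineProbe, MeasurementPlan, ROISpec, SegmentPlan, evaluate_case, records_to_dataframe

__all__ = ["default_plan", "run_phantom_case", "run_phantom_batch"]


def default_plan(spec: PhantomSpec) -> MeasurementPlan:
    """Measurement plan matched to the default head/neck phantom layout.

    Vessel attenuation is averaged over discs on three adjacent mid-stack
    slices; the vessel-ROI radius is 0.7x the true radius (a reproducible
    stand-in for "largest possible ROI avoiding the vessel wall"); the
    sharpness probe crosses each vessel horizontally through its center.
    """
    nz = spec.shape[0]
    z_mid = (nz // 2) * spec.spacing[0]
    dz = 4 * spec.spacing[0]
    fat = _region_center(spec.fat_region)
    muscle = _region_center(spec.muscle_region)
    plan = MeasurementPlan(
        fat_roi=ROISpec((z_mid, fat[1], fat[2]), 100.0, label="subcutaneous fat"),
        muscle_roi=ROISpec((z_mid, muscle[1], muscle[2]), 100.0, label="trapezius muscle"),
    )
    for v in spec.vessels:
        cy = (v.start[1] + v.end[1]) / 2.0
        cx = (v.start[2] + v.end[2]) / 2.0
        area = math.pi * (0.7 * v.radius) ** 2
        rois = [
            ROISpec((z, cy, cx), area, label=v.label)
            for z in (z_mid - dz, z_mid, z_mid + dz)
        ]
        probe = LineProbe((z_mid, cy, cx - 6.0), (z_mid, cy, cx + 6.0))
        plan.segments.append(SegmentPlan(label=v.label, rois=rois, probe=probe))
    return plan


def _region_center(region) -> np.ndarray:
    if hasattr(region, "center"):
        return np.asarray(region.center, float)
    return (np.asarray(region.lo, float) + np.asarray(region.hi, float)) / 2.0


def run_phantom_case(
    seed: int,
    spec: PhantomSpec | None = None,
    params: BoostParams | None = None,
) -> pd.DataFrame:
    """One replicate: phantom -> CE-boost -> QA records for both variants."""
    spec = spec if spec is not None else default_head_neck_spec(seed=seed)
    spec.seed = seed
    params = params or BoostParams(registration="none")
    pre, enhanced, _ = make_phantom(spec)
    boosted, _, _ = ce_boost_pipeline(pre, enhanced, params)
    plan = default_plan(spec)
    df = records_to_dataframe(evaluate_case(enhanced, boosted, plan))
    df.insert(0, "case", seed)
    return df


def run_phantom_batch(
    seeds,
    spec: PhantomSpec | None = None,
    params: BoostParams | None = None,
) -> pd.DataFrame:
    """Stack :func:`run_phantom_case` over many seeds (long QA table)."""
    frames = []
    for seed in seeds:
        base = spec if spec is None else _respec(spec, int(seed))
        frames.append(run_phantom_case(int(seed), base, params))
    return pd.concat(frames, ignore_index=True)


def _respec(spec: PhantomSpec, seed: int) -> PhantomSpec:
    import copy

    s = copy.deepcopy(spec)
    s.seed = seed
    return s
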