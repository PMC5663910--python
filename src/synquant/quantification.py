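"""Per-synapse functional indices and group aggregation.

The central quantity is the normalized tracer-uptake index of a bouton:
the ratio of background-subtracted tracer (SB) fluorescence to
background-subtracted reporter (GZ) fluorescence,

    uptake = (mean_SB - bg_SB) / (mean_GZ - bg_GZ),

a proxy for cumulative vesicle cycling per unit reporter expression.  A
bouton is classified *active* when its mean tracer fluorescence exceeds
the local background mean by more than ``k`` background SDs (default
k = 1).  Indices are averaged per field of view, optionally de-trended
against acquisition covariates (detector gain, or gain x laser power)
within each experimental group, and averaged per animal for population
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SynapseROI

__all__ = [
    "UptakeRecord",
    "FOVSummary",
    "uptake_index",
    "classify_active",
    "records_from_rois",
    "fraction_active",
    "detrend_index",
    "aggregate_per_animal",
]


@dataclass
class UptakeRecord:
    roi_id: int
    uptake_index: float
    sb_excess: float
    active: bool
    valid: bool
    fov_id: str = ""
    animal_id: str = ""
    group_label: str = ""
    detector_gain: float = 1.0
    laser_power: float = 1.0


@dataclass
class FOVSummary:
    fov_id: str
    n_synapses: int
    fraction_active: float
    mean_uptake: float
    mean_gz_expression: float
    animal_id: str = ""
    group_label: str = ""


def uptake_index(roi: SynapseROI) -> tuple[float, bool]:
    """Normalized uptake of one ROI and its validity flag.

    The index is undefined (valid=False) when the background-subtracted
    reporter signal is non-positive; the returned value is then NaN.
    """
    for f in ("mean_sb", "bg_sb_mean", "mean_gz", "bg_gz_mean"):
        if not np.isfinite(getattr(roi, f)):
            raise ValueError(f"ROI {roi.roi_id} missing {f}; run measure_rois first")
    denom = roi.mean_gz - roi.bg_gz_mean
    if denom <= 0:
        return float("nan"), False
    return (roi.mean_sb - roi.bg_sb_mean) / denom, True


def classify_active(roi: SynapseROI, k: float = 1.0) -> bool:
    """Active iff mean tracer fluorescence > local background mean + k SD.

    Uses the per-ROI annular background SD (local surroundings), with
    k = 1 by default.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    return roi.mean_sb > roi.bg_sb_mean + k * roi.bg_sb_sd


def records_from_rois(rois: list[SynapseROI], k_active: float = 1.0, *,
                      fov_id: str = "", animal_id: str = "",
                      group_label: str = "", detector_gain: float = 1.0,
                      laser_power: float = 1.0,
                      chained_only: bool = False) -> list[UptakeRecord]:
    """Build uptake records from measured ROIs.

    With ``chained_only`` only ROIs assigned to an axonal chain are kept
    (the acceptance rule for tissue with sporadic somatic expression).
    """
    records = []
    for roi in rois:
        if chained_only and roi.chain_id is None:
            continue
        idx, valid = uptake_index(roi)
        records.append(UptakeRecord(
            roi_id=roi.roi_id, uptake_index=idx,
            sb_excess=roi.mean_sb - roi.bg_sb_mean,
            active=classify_active(roi, k_active), valid=valid,
            fov_id=fov_id, animal_id=animal_id, group_label=group_label,
            detector_gain=detector_gain, laser_power=laser_power,
        ))
    return records


def fraction_active(records: list[UptakeRecord],
                    gz_means: list[float] | None = None) -> FOVSummary:
    """Per-FOV summary: fraction of active synapses, mean uptake over
    valid records, and mean reporter expression.

    Invalid records (non-positive reporter excess) are excluded from
    mean_uptake but still counted in ``n_synapses``: detection occurred,
    only the ratio is undefined.
    """
    if not records:
        raise ValueError("need at least one record")
    n = len(records)
    frac = sum(r.active for r in records) / n
    valid = [r.uptake_index for r in records if r.valid]
    mean_uptake = float(np.mean(valid)) if valid else float("nan")
    mean_gz = float(np.mean(gz_means)) if gz_means else float("nan")
    first = records[0]
    return FOVSummary(fov_id=first.fov_id, n_synapses=n, fraction_active=frac,
                      mean_uptake=mean_uptake, mean_gz_expression=mean_gz,
                      animal_id=first.animal_id, group_label=first.group_label)


def detrend_index(values, covariate, group_labels) -> np.ndarray:
    """Linear de-trend of an index against an acquisition covariate.

    Within each experimental group independently, fit ordinary least
    squares of index on covariate and return residual + group mean, so
    group means are preserved while the covariate trend is removed.
    Groups whose covariate is (near-)constant are returned unchanged,
    with a warning when they contain 2+ points.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    group_labels = np.asarray(group_labels)
    if not (len(values) == len(covariate) == len(group_labels)):
        raise ValueError("values, covariate and group_labels must align")
    out = values.copy()
    for g in np.unique(group_labels):
        sel = group_labels == g
        x, y = covariate[sel], values[sel]
        if len(np.unique(x)) < 2:
            if sel.sum() >= 2:
                warnings.warn(f"group {g!r}: constant covariate, no de-trend applied")
            continue
        slope, intercept = np.polyfit(x, y, 1)
        out[sel] = y - (slope * x + intercept) + y.mean()
    return out


def aggregate_per_animal(fov_summaries: list[FOVSummary],
                         fov_to_animal: dict[str, str] | None = None,
                         value: str = "mean_uptake") -> pd.DataFrame:
    """Unweighted mean of a per-FOV index across each animal's FOVs.

    ``value`` selects the endpoint: ``mean_uptake``, ``fraction_active``
    or ``mean_gz_expression``.  The animal id is taken from the summary
    unless an explicit ``fov_to_animal`` mapping is given; every FOV must
    resolve to exactly one animal.
    """
    rows = []
    for s in fov_summaries:
        if fov_to_animal is not None:
            if s.fov_id not in fov_to_animal:
                raise KeyError(f"FOV {s.fov_id!r} has no animal mapping")
            animal = fov_to_animal[s.fov_id]
        else:
            animal = s.animal_id
            if not animal:
                raise KeyError(f"FOV {s.fov_id!r} has no animal id")
        rows.append({"animal_id": animal, "group_label": s.group_label,
                     "fov_id": s.fov_id, "value": getattr(s, value)})
    frame = pd.DataFrame(rows)
    grouped = (frame.groupby(["animal_id", "group_label"], as_index=False)
               .agg(value=("value", "mean"), n_fovs=("fov_id", "count")))
    return grouped
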