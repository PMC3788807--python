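"""ROI definition and summary statistics over fitted parameter maps.

Implements the high-vascularity ROI (voxels above the 90th percentile of
pcCBV within a lesion), per-ROI parameter summaries including the
fraction of voxels preferring the two-stage model, a two-tailed paired
t test for tumor-vs-healthy comparisons, and a per-subject CSV report
with the columns: single-stage CBF; two-stage CBF, f_pc, pcTT, BAT_c;
pcCBV; and the two-stage-preferred fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import ParameterMaps

__all__ = [
    "ROISummary",
    "high_pcCBV_roi",
    "roi_summary",
    "paired_comparison",
    "roi_report",
]

#: parameters summarised per ROI, in report order
REPORT_PARAMS = ("CBF_single", "CBF", "f_pc", "pcTT", "BAT_c", "pcCBV")


def high_pcCBV_roi(
    pccbv_map: np.ndarray,
    lesion_mask: np.ndarray,
    percentile: float = 90.0,
    inclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxels of a lesion with pcCBV strictly above its percentile value.

    The threshold is the linear-interpolation percentile of pcCBV over
    the lesion voxels (restricted to the inclusion mask when given);
    "above" is strict, so a lesion with all-equal values yields an empty
    ROI (with a warning).
    """
    pccbv_map = np.asarray(pccbv_map, dtype=float)
    lesion = np.asarray(lesion_mask) != 0
    if inclusion_mask is not None:
        lesion = lesion & (np.asarray(inclusion_mask) != 0)
    lesion = lesion & np.isfinite(pccbv_map)
    if not lesion.any():
        raise ValueError("lesion mask is empty within the defined voxels")
    values = pccbv_map[lesion]
    threshold = np.percentile(values, percentile)  # linear interpolation
    roi = lesion & (pccbv_map > threshold)
    if not roi.any():
        import warnings

        warnings.warn(
            "high-pcCBV ROI is empty (no voxel strictly above the "
            f"{percentile:g}th-percentile threshold {threshold:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return roi


@dataclass(frozen=True)
class ROISummary:
    """Mean/SD/median per parameter over an ROI, plus model preference."""

    stats: pd.DataFrame  # index = parameter, columns = mean, sd, median
    n_voxels: int
    two_stage_fraction: float  # % of ROI voxels preferring the two-stage model

    def __getitem__(self, param: str) -> float:
        return float(self.stats.loc[param, "mean"])


def roi_summary(maps: ParameterMaps, roi_mask: np.ndarray) -> ROISummary:
    """Summarise fitted parameters over ``roi_mask`` ∩ inclusion mask."""
    roi = (np.asarray(roi_mask) != 0) & maps.inclusion_mask
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI does not intersect the inclusion mask")
    rows = {}
    for name in REPORT_PARAMS:
        vals = maps[name][roi]
        vals = vals[np.isfinite(vals)]
        rows[name] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "median": float(np.median(vals)),
        }
    frac = 100.0 * float((maps.model_choice[roi] == 2).sum()) / n
    return ROISummary(stats=pd.DataFrame(rows).T, n_voxels=n, two_stage_fraction=frac)


def paired_comparison(values_a, values_b):
    """Two-tailed paired t test on per-subject means.

    Returns ``(t, p, degenerate)``.  Identical vectors give (0, 1,
    False); a nonzero constant difference has zero variance, which makes
    the statistic undefined — flagged with ``degenerate=True`` and NaN
    results.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 subjects")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0, False
        return np.nan, np.nan, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def roi_report(
    maps_by_subject: dict,
    lesion_masks: dict,
    reference_masks: dict | None = None,
    percentile: float = 90.0,
) -> pd.DataFrame:
    """Per-subject report over high-pcCBV lesion ROIs.

    One row per subject: mean single-stage CBF; mean two-stage CBF,
    f_pc, pcTT, BAT_c; mean pcCBV; two-stage-preferred fraction (and the
    medians of each, reported alongside the means).  When reference
    (healthy-tissue) masks are supplied, the same summaries are added
    with a ``healthy_`` prefix, computed over the whole reference ROI.
    """
    rows = []
    for subject, maps in maps_by_subject.items():
        roi = high_pcCBV_roi(
            maps["pcCBV"], lesion_masks[subject], percentile=percentile,
            inclusion_mask=maps.inclusion_mask,
        )
        summ = roi_summary(maps, roi)
        row = {"subject": subject, "n_voxels": summ.n_voxels,
               "two_stage_pct": summ.two_stage_fraction}
        for p in REPORT_PARAMS:
            row[f"{p}_mean"] = summ.stats.loc[p, "mean"]
            row[f"{p}_median"] = summ.stats.loc[p, "median"]
            row[f"{p}_sd"] = summ.stats.loc[p, "sd"]
        if reference_masks is not None and subject in reference_masks:
            ref = roi_summary(maps, reference_masks[subject])
            row["healthy_two_stage_pct"] = ref.two_stage_fraction
            for p in REPORT_PARAMS:
                row[f"healthy_{p}_mean"] = ref.stats.loc[p, "mean"]
                row[f"healthy_{p}_median"] = ref.stats.loc[p, "median"]
        rows.append(row)
    return pd.DataFrame(rows)
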