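"""Segmentation-agreement statistics against a reference standard.

For every segmentation method the report gives mass areas
(mean +/- SD), Pearson's correlation and a paired Student's t-test of
the areas against the reference masks, and two area overlap ratios:

    AOR1 = |seg intersect ref| / |ref|
    AOR2 = |seg intersect ref| / |seg union ref|

AOR2 (the Jaccard index) never exceeds AOR1 because the union contains
the reference.  Both equal 1 exactly when the masks coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from breastcad.phantom import CaseRecord

__all__ = [
    "OverlapMeasures",
    "area_overlap",
    "pearson_r",
    "paired_t_test",
    "agreement_report",
]


@dataclass
class OverlapMeasures:
    aor1: float
    aor2: float
    seg_area: int
    ref_area: int


def area_overlap(seg: np.ndarray, ref: np.ndarray) -> OverlapMeasures:
    """Overlap ratios of a segmentation against a reference mask."""
    seg = np.asarray(seg, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if seg.shape != ref.shape:
        raise ValueError("mask shapes differ")
    ref_area = int(ref.sum())
    if ref_area == 0:
        raise ValueError("empty reference mask")
    inter = int((seg & ref).sum())
    union = int((seg | ref).sum())
    return OverlapMeasures(
        aor1=inter / ref_area,
        aor2=inter / union,
        seg_area=int(seg.sum()),
        ref_area=ref_area,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two area lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Paired Student's t-test; returns (t, two-sided p).

    Degenerate inputs follow the conventions: all differences zero
    gives (0, 1); zero difference variance with nonzero mean gives
    p = 0 with an infinite-magnitude t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two paired values")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def agreement_report(
    cohort: Sequence[CaseRecord],
    masks_by_method: Mapping[str, Sequence[np.ndarray]],
) -> dict[str, pd.DataFrame]:
    """Agreement statistics of each method against the ground truth.

    Returns three frames: ``summary`` (one row per method: area
    mean +/- SD, Pearson r, paired-t p, AOR means +/- SD, with a
    ``reference`` row for the ground-truth areas), ``scatter``
    (per-case areas for log-log scatter plots), and ``aor`` (per-case
    overlap ratios for histogramming).
    """
    ref_areas = np.array([c.mass_mask.sum() for c in cohort], dtype=float)
    summary_rows = []
    scatter_rows = []
    aor_rows = []
    for method, masks in masks_by_method.items():
        if len(masks) != len(cohort):
            raise ValueError(f"method {method!r} missing case masks")
        overlaps = [
            area_overlap(m, c.mass_mask) for m, c in zip(masks, cohort)
        ]
        areas = np.array([o.seg_area for o in overlaps], dtype=float)
        aor1 = np.array([o.aor1 for o in overlaps])
        aor2 = np.array([o.aor2 for o in overlaps])
        # correlation and test are undefined on tiny or degenerate
        # cohorts; report NaN rather than refuse the whole table
        try:
            r = pearson_r(areas, ref_areas)
        except ValueError:
            r = np.nan
        try:
            _, p = paired_t_test(areas, ref_areas)
        except ValueError:
            p = np.nan
        summary_rows.append(
            {
                "method": method,
                "area_mean": areas.mean(),
                "area_sd": areas.std(ddof=1),
                "pearson_r": r,
                "paired_t_p": p,
                "aor1_mean": aor1.mean(),
                "aor1_sd": aor1.std(ddof=1),
                "aor2_mean": aor2.mean(),
                "aor2_sd": aor2.std(ddof=1),
            }
        )
        for case, o in zip(cohort, overlaps):
            scatter_rows.append(
                {
                    "method": method,
                    "case_id": case.case_id,
                    "seg_area": o.seg_area,
                    "ref_area": o.ref_area,
                }
            )
            aor_rows.append(
                {
                    "method": method,
                    "case_id": case.case_id,
                    "aor1": o.aor1,
                    "aor2": o.aor2,
                }
            )
    summary_rows.append(
        {
            "method": "reference",
            "area_mean": ref_areas.mean(),
            "area_sd": ref_areas.std(ddof=1),
            "pearson_r": np.nan,
            "paired_t_p": np.nan,
            "aor1_mean": np.nan,
            "aor1_sd": np.nan,
            "aor2_mean": np.nan,
            "aor2_sd": np.nan,
        }
    )
    return {
        "summary": pd.DataFrame(summary_rows),
        "scatter": pd.DataFrame(scatter_rows),
        "aor": pd.DataFrame(aor_rows),
    }
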