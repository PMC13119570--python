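"""Evaluation statistics: IoU, area ratio, auto-acceptance, bias deltas.

The pipeline's headline quality-control statistic is the auto-acceptance
rate (AAR): the percentage of images whose predicted-to-ground-truth area
ratio AR = A_pred / A_true lies within a ±5% band of unity.  Within a
stratum (dataset x week x stage) the median AR (MAR) measures systematic
bias; comparisons between two pipeline arms report

    dAAR    = AAR_new - AAR_ref
    d|Bias| = |MAR_ref - 1| - |MAR_new - 1|

so that positive values always mean the "new" arm auto-accepts more and
is less biased.  A baseline-vs-final comparison assigns (ref, new) =
(baseline, final); a final-vs-ablation comparison assigns (ref, new) =
(final, ablation), in which case negative values favour the final arm.
The two published reporting conventions differ only in this role
assignment, never in the arithmetic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, JoinError
from .geometry import BoundingBox

__all__ = [
    "iou",
    "box_iou",
    "area_ratio",
    "aar",
    "median_ar",
    "mean_std_ar",
    "delta_aar",
    "delta_abs_bias",
    "detection_pr",
    "stratified_report",
    "compare_runs",
    "format_report_text",
]

#: Default half-width of the auto-acceptance band around AR = 1.
DEFAULT_AAR_TOLERANCE = 0.05


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Defined as 1.0 when both masks are empty and 0.0 when exactly one is.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(a & b) / union)


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """IoU of two axis-aligned boxes (continuous geometry, same frame)."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def area_ratio(a_pred: float, a_true: float) -> float:
    """AR = A_pred / A_true; 1 is perfect agreement, >1 overestimation."""
    if not a_true > 0:
        raise InvalidArgumentError(f"ground-truth area must be positive, got {a_true}")
    if a_pred < 0:
        raise InvalidArgumentError(f"predicted area must be non-negative, got {a_pred}")
    return float(a_pred) / float(a_true)


def aar(
    ars: Sequence[float],
    tolerance: float = DEFAULT_AAR_TOLERANCE,
    closed: bool = True,
) -> float:
    """Auto-acceptance rate in percent.

    Fraction of area ratios with |AR - 1| <= tolerance (closed interval
    [1-tol, 1+tol] by default; set ``closed=False`` for the strict
    variant), times 100.
    """
    arr = np.asarray(list(ars), dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("AAR of an empty sample is undefined")
    if not tolerance > 0:
        raise InvalidArgumentError("tolerance must be positive")
    dev = np.abs(arr - 1.0)
    if closed:
        # float-robust closed interval: an AR sitting exactly on the
        # printed band edge (e.g. 0.95) counts as accepted even when
        # rounding puts |AR - 1| one ulp above the tolerance
        inside = (dev < tolerance) | np.isclose(dev, tolerance, rtol=1e-9, atol=1e-12)
    else:
        inside = dev < tolerance
    return float(100.0 * np.count_nonzero(inside) / arr.size)


def median_ar(ars: Sequence[float]) -> float:
    """Median area ratio (MAR) of a stratum; deviation from 1 is bias."""
    arr = np.asarray(list(ars), dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("median of an empty sample is undefined")
    return float(np.median(arr))


def mean_std_ar(ars: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (N-1) standard deviation of ARs.

    The standard deviation is NaN for a single observation.
    """
    arr = np.asarray(list(ars), dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("mean of an empty sample is undefined")
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, std


def delta_aar(aar_new: float, aar_ref: float) -> float:
    """AAR_new - AAR_ref, in percentage points."""
    return float(aar_new) - float(aar_ref)


def delta_abs_bias(mar_ref: float, mar_new: float) -> float:
    """|MAR_ref - 1| - |MAR_new - 1|; positive means the new arm is less biased."""
    return abs(float(mar_ref) - 1.0) - abs(float(mar_new) - 1.0)


def detection_pr(
    pred: Sequence,
    gt: Sequence[BoundingBox],
    iou_thresh: float = 0.5,
) -> tuple[float, float]:
    """Detection precision and recall at a box-IoU threshold.

    Predictions (objects with ``box`` and ``confidence`` attributes, or
    bare boxes treated as confidence 1) are matched greedily to unmatched
    ground-truth boxes in order of descending confidence.  With no
    predictions precision is vacuously 1; with no ground truth recall is
    vacuously 1.
    """
    def conf(p) -> float:
        return getattr(p, "confidence", 1.0)

    def box_of(p) -> BoundingBox:
        return getattr(p, "box", p)

    order = sorted(range(len(pred)), key=lambda i: -conf(pred[i]))
    matched_gt: set[int] = set()
    tp = 0
    for i in order:
        best_j, best = -1, iou_thresh
        for j, g in enumerate(gt):
            if j in matched_gt:
                continue
            v = box_iou(box_of(pred[i]), g)
            if v >= best:
                best, best_j = v, j
        if best_j >= 0:
            matched_gt.add(best_j)
            tp += 1
    fp = len(pred) - tp
    fn = len(gt) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 1.0
    return float(precision), float(recall)


REPORT_COLUMNS = [
    "dataset", "week", "stage", "n", "aar", "mar", "mean_ar", "std_ar",
    "delta_aar", "delta_abs_bias", "excluded_n",
]


def _ars_per_stratum(
    records: pd.DataFrame,
    gt_table: pd.DataFrame,
    strata: Sequence[str],
    tolerance: float,
) -> pd.DataFrame:
    df = records.copy()
    gt = gt_table.copy()
    if "image_id" not in df.columns or "image_id" not in gt.columns:
        raise InvalidArgumentError("records and gt_table both need an image_id column")
    gt_cols = ["image_id", "gt_area_um2"] + [
        c for c in strata if c in gt.columns and c not in df.columns
    ]
    merged = df.merge(gt[gt_cols], on="image_id", how="left", validate="one_to_one")
    missing = merged.loc[merged["gt_area_um2"].isna(), "image_id"].tolist()
    if missing:
        raise JoinError(f"{len(missing)} record(s) with no ground-truth area", missing)

    for col in strata:
        if col not in merged.columns:
            merged[col] = ""

    # a record is usable when the pipeline produced an area
    usable = merged["area_um2"].notna()
    merged["_ar"] = np.where(
        usable, merged["area_um2"] / merged["gt_area_um2"], np.nan
    )

    rows = []
    for key, grp in merged.groupby(list(strata), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        ars = grp["_ar"].dropna().to_numpy()
        excluded = int(grp["_ar"].isna().sum())
        row = dict(zip(strata, key))
        if ars.size:
            mean, std = mean_std_ar(ars)
            row.update(
                n=int(ars.size),
                aar=aar(ars, tolerance),
                mar=median_ar(ars),
                mean_ar=mean,
                std_ar=std,
            )
        else:
            row.update(n=0, aar=np.nan, mar=np.nan, mean_ar=np.nan, std_ar=np.nan)
        row["excluded_n"] = excluded
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_report(
    records: pd.DataFrame,
    gt_table: pd.DataFrame,
    strata: Sequence[str] = ("dataset", "week", "stage"),
    reference_run: pd.DataFrame | None = None,
    tolerance: float = DEFAULT_AAR_TOLERANCE,
) -> pd.DataFrame:
    """Per-stratum evaluation table (n, AAR, MAR, mean±std AR).

    ``records`` is a measurement table with image_id, area_um2 and the
    stratum columns; ``gt_table`` supplies gt_area_um2 per image_id.
    Records without a predicted area (flagged failures) are excluded from
    the ratio statistics and counted in ``excluded_n``.  When a
    ``reference_run`` is supplied, per-stratum ``delta_aar`` and
    ``delta_abs_bias`` are computed with ``records`` as the "new" arm and
    the reference as the "ref" arm.
    """
    strata = list(strata)
    rep = _ars_per_stratum(records, gt_table, strata, tolerance)
    if reference_run is not None:
        ref = _ars_per_stratum(reference_run, gt_table, strata, tolerance)
        ref = ref.rename(columns={"aar": "_ref_aar", "mar": "_ref_mar"})
        rep = rep.merge(ref[strata + ["_ref_aar", "_ref_mar"]], on=strata, how="left")
        rep["delta_aar"] = rep.apply(
            lambda r: delta_aar(r["aar"], r["_ref_aar"]), axis=1
        )
        rep["delta_abs_bias"] = rep.apply(
            lambda r: delta_abs_bias(r["_ref_mar"], r["mar"]), axis=1
        )
        rep = rep.drop(columns=["_ref_aar", "_ref_mar"])
    else:
        rep["delta_aar"] = np.nan
        rep["delta_abs_bias"] = np.nan
    rep = rep.sort_values(strata).reset_index(drop=True)
    return rep[[c for c in REPORT_COLUMNS if c in rep.columns]
               + [c for c in rep.columns if c not in REPORT_COLUMNS]]


def compare_runs(
    run_ref: pd.DataFrame,
    run_new: pd.DataFrame,
    gt_table: pd.DataFrame,
    strata: Sequence[str] = ("dataset", "week", "stage"),
    tolerance: float = DEFAULT_AAR_TOLERANCE,
) -> pd.DataFrame:
    """Paired two-arm report: the new arm's rows with deltas vs the reference.

    Role assignment is the caller's choice of reporting convention: pass
    (baseline, final) to report final-pipeline improvement, or
    (final, ablation) to report ablation degradation.
    """
    ref_ids = set(run_ref["image_id"])
    new_ids = set(run_new["image_id"])
    if ref_ids != new_ids:
        off = sorted(ref_ids ^ new_ids)
        raise JoinError(f"runs cover different image ids ({len(off)} mismatched)", off)
    return stratified_report(run_new, gt_table, strata, reference_run=run_ref,
                             tolerance=tolerance)


def format_report_text(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of an evaluation table."""
    df = report.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    return df.to_string(index=False)
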