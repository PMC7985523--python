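"""Error metrics, summaries, and reference-curve utilities.

The headline metric is the relative sO2 estimation error
e = |sO2_est - sO2_gt| / sO2_gt, summarized by its median and
interquartile range; the absolute error is reported in percentage points,
100 * |est - gt|.  Rows with gt = 0 are excluded from relative-error
summaries (the ratio is undefined) with their count logged; absolute-error
summaries keep them.  Percentiles interpolate linearly between order
statistics.

``severinghaus_so2`` converts a partial oxygen pressure (mmHg) into the
saturation of the hemoglobin dissociation curve using the standard
empirical form sO2 = 1 / (23400 / (pO2^3 + 150 pO2) + 1); this is how
needle-probe pO2 reference measurements are translated into sO2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .errors import DataError, ValidationError


@dataclass(frozen=True)
class ErrorSummary:
    """Median + IQR of relative and absolute sO2 errors."""

    median_relative: float
    iqr_relative: Tuple[float, float]
    median_absolute_pp: float
    iqr_absolute_pp: Tuple[float, float]
    n: int
    n_excluded_relative: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("summary needs n >= 1")

    def as_dict(self) -> dict:
        return {
            "median_relative": self.median_relative,
            "iqr_relative": list(self.iqr_relative),
            "median_absolute_pp": self.median_absolute_pp,
            "iqr_absolute_pp": list(self.iqr_absolute_pp),
            "n": self.n,
            "n_excluded_relative": self.n_excluded_relative,
        }


def relative_error(est, gt) -> np.ndarray:
    """|est - gt| / gt; caller must exclude gt = 0 rows (see evaluate)."""
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if np.any(gt <= 0):
        raise ValidationError("relative error undefined for gt <= 0")
    return np.abs(est - gt) / gt


def absolute_error_pp(est, gt) -> np.ndarray:
    """100 * |est - gt|, in percentage points."""
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if np.any((est < 0) | (est > 1) | (gt < 0) | (gt > 1)):
        raise ValidationError("est and gt must lie in [0, 1]")
    return 100.0 * np.abs(est - gt)


def summarize(errors: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    """Median and (q25, q75) with linear percentile interpolation."""
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise DataError("cannot summarize an empty error sequence")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), (float(q25), float(q75))


def evaluate_estimates(est, gt) -> ErrorSummary:
    """Full error summary of a set of estimates against ground truth."""
    est = np.asarray(est, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if est.shape != gt.shape or est.size == 0:
        raise DataError("est/gt must be equal-length and non-empty")
    keep = gt > 0
    n_excluded = int((~keep).sum())
    abs_med, abs_iqr = summarize(absolute_error_pp(est, gt))
    if not keep.any():
        raise DataError("all ground-truth values are zero")
    rel_med, rel_iqr = summarize(relative_error(est[keep], gt[keep]))
    return ErrorSummary(rel_med, rel_iqr, abs_med, abs_iqr,
                        n=int(est.size), n_excluded_relative=n_excluded)


@dataclass(frozen=True)
class DissociationParams:
    """Constants of the empirical oxygen dissociation curve."""

    cubic_coefficient: float = 23400.0
    linear_coefficient: float = 150.0

    def __post_init__(self) -> None:
        if self.cubic_coefficient <= 0 or self.linear_coefficient < 0:
            raise ValidationError("dissociation constants must be positive")


def severinghaus_so2(po2_mmhg, params: Optional[DissociationParams] = None):
    """sO2 fraction from partial oxygen pressure (mmHg)."""
    params = params or DissociationParams()
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 <= 0):
        raise ValidationError("pO2 must be > 0 mmHg")
    denom = params.cubic_coefficient / (
        po2 ** 3 + params.linear_coefficient * po2) + 1.0
    out = 1.0 / denom
    return float(out) if np.isscalar(po2_mmhg) else out


def severinghaus_po2(so2, params: Optional[DissociationParams] = None
                     ) -> float:
    """Inverse dissociation curve: pO2 (mmHg) for a given sO2 fraction."""
    params = params or DissociationParams()
    if not 0.0 < so2 < 1.0:
        raise ValidationError("invertible only for sO2 in (0, 1)")
    return float(brentq(lambda p: severinghaus_so2(p, params) - so2,
                        1e-6, 5000.0, xtol=1e-10))


def roi_time_series(so2_maps: Sequence[np.ndarray], mask,
                    statistic: str = "median"
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-frame ROI statistic and dispersion over a map sequence.

    ``statistic="mean"`` returns (mean, std) per frame;
    ``statistic="median"`` returns (median, IQR width).  Frames whose
    masked values are all NaN yield NaN entries.
    """
    mask = np.asarray(mask, dtype=bool)
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    stats: List[float] = []
    disps: List[float] = []
    for frame in so2_maps:
        frame = np.asarray(frame, dtype=float)
        if mask.shape != frame.shape:
            raise ValidationError("mask/frame shape mismatch")
        vals = frame[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            stats.append(float("nan"))
            disps.append(float("nan"))
        elif statistic == "mean":
            stats.append(float(vals.mean()))
            disps.append(float(vals.std()))
        else:
            q25, q75 = np.percentile(vals, [25.0, 75.0])
            stats.append(float(np.median(vals)))
            disps.append(float(q75 - q25))
    return np.asarray(stats), np.asarray(disps)


def dynamic_range(series) -> Tuple[float, float]:
    """(max, min) of a per-frame estimate series; NaNs ignored."""
    arr = np.asarray(series, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DataError("dynamic range of an empty series")
    return float(arr.max()), float(arr.min())
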