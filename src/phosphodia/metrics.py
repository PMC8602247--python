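"""Evaluation metrics for spectrum and retention-time prediction.

Spectrum metrics (PCC, normalized spectral angle) compare a predicted and a
target fragment matrix over the cells that are valid in the *target* mask
(sentinel ``-1`` cells never enter the computation).  RT metrics operate on
paired predicted/observed arrays.  Undefined values (zero variance, zero
norm) are returned as NaN and dropped by :func:`median_summary`.
"""

from __future__ import annotations

import numpy as np

from .ion_space import SENTINEL

__all__ = [
    "pearson_cc",
    "spectral_angle",
    "median_summary",
    "median_absolute_error",
    "delta_t95",
    "linear_fit_r2",
]


def _valid_vectors(pred: np.ndarray, target: np.ndarray):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    mask = target != SENTINEL
    return pred[mask], target[mask]


def pearson_cc(pred: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation over target-valid cells; NaN when undefined."""
    x, y = _valid_vectors(pred, target)
    if x.size < 2:
        return float("nan")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def spectral_angle(pred: np.ndarray, target: np.ndarray) -> float:
    """Normalized spectral angle ``1 - 2*arccos(p . t)/pi`` on unit vectors."""
    x, y = _valid_vectors(pred, target)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return float("nan")
    dot = float(np.clip(np.dot(x / nx, y / ny), -1.0, 1.0))
    return 1.0 - 2.0 * np.arccos(dot) / np.pi


def median_summary(values) -> tuple[float, int]:
    """Median and count after dropping NaN; raises when nothing remains."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined values to summarize")
    return float(np.median(arr)), int(arr.size)


def median_absolute_error(pred_rt, true_rt) -> float:
    """Median (not mean) of absolute deviations, in RT units."""
    pred_rt = np.asarray(pred_rt, dtype=float)
    true_rt = np.asarray(true_rt, dtype=float)
    if pred_rt.shape != true_rt.shape:
        raise ValueError("paired arrays required")
    if pred_rt.size == 0:
        raise ValueError("empty input")
    return float(np.median(np.abs(pred_rt - true_rt)))


def delta_t95(pred_rt, true_rt, warn_below: int = 20) -> float:
    """Delta-t95: twice the nearest-rank 95th percentile of |deviation|.

    The minimal RT window containing the prediction error of 95% of the
    peptides.  Nearest-rank: the ceil(0.95 n)-th order statistic.
    """
    import warnings

    pred_rt = np.asarray(pred_rt, dtype=float)
    true_rt = np.asarray(true_rt, dtype=float)
    if pred_rt.size == 0:
        raise ValueError("empty input")
    if pred_rt.size < warn_below:
        warnings.warn(
            f"delta_t95 on only {pred_rt.size} pairs is unstable", stacklevel=2
        )
    dev = np.sort(np.abs(pred_rt - true_rt))
    rank = int(np.ceil(0.95 * dev.size))  # 1-based nearest rank
    return float(2.0 * dev[rank - 1])


def linear_fit_r2(pred_rt, true_rt) -> float:
    """Coefficient of determination of the OLS line observed ~ predicted."""
    x = np.asarray(pred_rt, dtype=float)
    y = np.asarray(true_rt, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 pairs required")
    if np.ptp(x) == 0:
        # a constant predictor explains nothing
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid * resid).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return max(0.0, 1.0 - ss_res / ss_tot)
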