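"""Agreement metrics between ground-truth and predicted amplitudes.

MAE = (1/n) sum |y_i - yhat_i|;  MAPE = (1/n) sum |(y_i - yhat_i)/y_i| x 100
with pairs whose ground-truth magnitude falls below a threshold (default 1
degree) excluded to avoid division by near-zero.  Pearson r (with two-sided
p-value), raw (non-centered) cosine similarity and an ordinary least-squares
fit y = slope*x + intercept (x = predicted, y = ground truth) complete the
battery, evaluated separately for peak amplitudes (per-repetition maxima)
and motion amplitudes (all within-repetition samples).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import MetricUndefinedError, ValidationError
from .temporal_alignment import AlignedPair, RepetitionWindow


def _as_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.ndim != 1 or yhat.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors")
    if len(y) != len(yhat):
        raise ValidationError(f"length mismatch: {len(y)} vs {len(yhat)}")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValidationError("inputs must be finite")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error, same units as the inputs."""
    y, yhat = _as_pair(y, yhat)
    if len(y) == 0:
        raise ValidationError("mae of empty vectors is undefined")
    return float(np.mean(np.abs(y - yhat)))


def mape(y, yhat, threshold: float = 1.0) -> tuple[float, int]:
    """Mean absolute percentage error and the count of excluded pairs.

    Pairs with |y_i| < threshold are dropped before averaging.
    """
    y, yhat = _as_pair(y, yhat)
    keep = np.abs(y) >= threshold
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise MetricUndefinedError("all pairs excluded by the MAPE threshold")
    ys, yhs = y[keep], yhat[keep]
    return float(np.mean(np.abs((ys - yhs) / ys)) * 100.0), n_excluded


def pearson_r(y, yhat) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value."""
    y, yhat = _as_pair(y, yhat)
    if len(y) < 3:
        raise MetricUndefinedError("Pearson correlation needs at least 3 pairs")
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise MetricUndefinedError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(y, yhat)
    return float(res.statistic), float(res.pvalue)


def cosine_similarity(y, yhat) -> float:
    """Cosine of the angle between the raw (non-centered) vectors."""
    y, yhat = _as_pair(y, yhat)
    ny, nyh = np.linalg.norm(y), np.linalg.norm(yhat)
    if ny == 0 or nyh == 0:
        raise MetricUndefinedError("cosine similarity undefined for a zero vector")
    return float(y @ yhat / (ny * nyh))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError("r_squared must lie in [0, 1]")


def linear_fit(x, y) -> RegressionResult:
    """OLS fit y = slope*x + intercept (x = predicted, y = ground truth)."""
    x, y = _as_pair(x, y)
    if len(x) < 3:
        raise MetricUndefinedError("linear fit needs at least 3 pairs")
    if np.std(x) == 0:
        raise MetricUndefinedError("linear fit undefined for zero-variance x")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=float(res.rvalue**2)
    )


def peak_amplitudes(
    aligned: AlignedPair, reps: list[RepetitionWindow]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-repetition maxima of the aligned gt and predicted values."""
    if not reps:
        raise ValidationError("no repetition windows provided")
    gt_peaks, pred_peaks = [], []
    for w in reps:
        mask = (aligned.times >= w.start_s) & (aligned.times <= w.end_s)
        g = aligned.gt_values[mask]
        p = aligned.pred_values[mask]
        g = g[np.isfinite(g)]
        p = p[np.isfinite(p)]
        if g.size == 0 or p.size == 0:
            warnings.warn(f"repetition window [{w.start_s:.2f}, {w.end_s:.2f}] s is empty; skipped")
            continue
        gt_peaks.append(float(g.max()))
        pred_peaks.append(float(p.max()))
    return np.asarray(gt_peaks), np.asarray(pred_peaks)


@dataclass
class MetricBlock:
    mae_deg: float
    mape_pct: float
    pearson_r: float
    p_value: float
    cosine_sim: float
    n: int
    n_excluded_by_threshold: int = 0
    regression: Optional[RegressionResult] = None

    def to_dict(self) -> dict:
        d = {
            "mae_deg": self.mae_deg,
            "mape_pct": self.mape_pct,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "cosine_sim": self.cosine_sim,
            "n": self.n,
            "n_excluded_by_threshold": self.n_excluded_by_threshold,
        }
        if self.regression is not None:
            d["regression"] = {
                "slope": self.regression.slope,
                "intercept": self.regression.intercept,
                "r_squared": self.regression.r_squared,
            }
        return d


@dataclass
class EvaluationReport:
    exercise: str
    peak: MetricBlock
    motion: MetricBlock
    mape_threshold_deg: float = 1.0

    def to_dict(self) -> dict:
        return {
            "exercise": self.exercise,
            "mape_threshold_deg": self.mape_threshold_deg,
            "peak": self.peak.to_dict(),
            "motion": self.motion.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _block(y: np.ndarray, yhat: np.ndarray, threshold: float, with_regression: bool) -> MetricBlock:
    keep = np.abs(y) >= threshold
    n_excluded = int((~keep).sum())
    ys, yhs = y[keep], yhat[keep]
    if ys.size == 0:
        raise MetricUndefinedError("all pairs excluded by the amplitude threshold")
    mape_pct, _ = mape(ys, yhs, threshold=0.0)
    # Degenerate sub-metrics (e.g. zero-variance peaks when every repetition
    # hits the same angle) become NaN rather than failing the whole report.
    try:
        r, p = pearson_r(ys, yhs)
    except MetricUndefinedError:
        r, p = float("nan"), float("nan")
    block = MetricBlock(
        mae_deg=mae(ys, yhs),
        mape_pct=mape_pct,
        pearson_r=r,
        p_value=p,
        cosine_sim=cosine_similarity(ys, yhs),
        n=int(ys.size),
        n_excluded_by_threshold=n_excluded,
    )
    if with_regression:
        try:
            block.regression = linear_fit(yhs, ys)  # x = predicted, y = ground truth
        except MetricUndefinedError:
            block.regression = None
    return block


def evaluate_exercise(
    aligned: AlignedPair,
    reps: list[RepetitionWindow],
    threshold: float = 1.0,
    exercise: str = "",
) -> EvaluationReport:
    """Full agreement report for one exercise acquisition.

    The peak block compares per-repetition maxima (no threshold filter —
    peaks are far from zero by construction); the motion block pools all
    within-repetition samples with |gt| < threshold excluded from every
    metric, and additionally carries the OLS regression.
    """
    gt_pk, pred_pk = peak_amplitudes(aligned, reps)
    peak_block = _block(gt_pk, pred_pk, threshold=0.0, with_regression=False)

    mask = np.zeros(len(aligned), dtype=bool)
    for w in reps:
        mask |= (aligned.times >= w.start_s) & (aligned.times <= w.end_s)
    y = aligned.gt_values[mask]
    yhat = aligned.pred_values[mask]
    ok = np.isfinite(y) & np.isfinite(yhat)
    motion_block = _block(y[ok], yhat[ok], threshold=threshold, with_regression=True)

    return EvaluationReport(
        exercise=exercise, peak=peak_block, motion=motion_block, mape_threshold_deg=threshold
    )
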