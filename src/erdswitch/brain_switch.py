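"""Sequential brain-switch detector with false-alarm control.

Single-trial classifier decisions are noisy; an awareness monitor instead
combines consecutive trial-level decision values (about one minute of
data at 7 s per trial for the default 8-trial window) and raises an alarm
when the combined score crosses a threshold calibrated on no-movement
data.  Calibration and evaluation use disjoint null data so the achieved
false-alarm rate is honest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DetectorConfig",
    "DetectorReport",
    "accumulate_decisions",
    "calibrate_threshold",
    "characterize_detector",
    "evaluate_brain_switch",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Windowing and combination rule of the sequential detector."""

    window_trials: int = 8
    threshold: float = 0.0
    combine: str = "mean"

    def __post_init__(self) -> None:
        if self.window_trials < 1:
            raise ValueError("window_trials must be >= 1")
        if self.combine not in ("mean", "vote"):
            raise ValueError("combine must be 'mean' or 'vote'")


@dataclass(frozen=True)
class DetectorReport:
    """Operating point: rates in percent over their respective windows."""

    false_alarm_rate: float
    true_positive_rate: float
    threshold: float
    window_trials: int
    combine: str = "mean"

    def to_dict(self) -> dict:
        return {
            "false_alarm_rate": self.false_alarm_rate,
            "true_positive_rate": self.true_positive_rate,
            "threshold": self.threshold,
            "window_trials": self.window_trials,
            "combine": self.combine,
        }


def accumulate_decisions(
    decision_values,
    window_trials: int,
    combine: str = "mean",
) -> np.ndarray:
    """Stride-1 sliding combination of consecutive trial decision values.

    ``combine="mean"`` averages the raw scores; ``combine="vote"`` takes
    the mean of their signs (majority vote on the scale [-1, 1]).
    """
    values = np.asarray(decision_values, dtype=float)
    if values.ndim != 1:
        raise ValueError("decision_values must be 1-D")
    if window_trials < 1:
        raise ValueError("window_trials must be >= 1")
    if window_trials > values.size:
        raise ValueError(
            f"window of {window_trials} trials exceeds the {values.size} "
            "available decision values"
        )
    if combine == "vote":
        values = np.sign(values)
    elif combine != "mean":
        raise ValueError("combine must be 'mean' or 'vote'")
    windows = np.lib.stride_tricks.sliding_window_view(values, window_trials)
    return windows.mean(axis=-1)


def calibrate_threshold(null_scores, target_fa: float = 0.0) -> float:
    """Smallest threshold keeping the null exceedance rate at or below
    ``target_fa`` percent.

    For a 0% target the threshold is the observed null maximum plus a tiny
    margin (1e-9 of the score scale), so the calibration-set false-alarm
    rate is exactly zero.
    """
    scores = np.sort(np.asarray(null_scores, dtype=float))
    if scores.size < 20:
        raise ValueError("need at least 20 null windows to calibrate")
    if not 0.0 <= target_fa <= 100.0:
        raise ValueError("target_fa must be a percentage in [0, 100]")
    scale = max(float(np.abs(scores).max()), 1.0)
    eps = 1e-9 * scale
    if target_fa == 0.0:
        return float(scores[-1]) + eps
    # candidate thresholds: just below the minimum, then each observed score;
    # pick the smallest whose null exceedance rate meets the target
    candidates = np.concatenate([[scores[0] - eps], scores])
    exceedance = (scores[None, :] > candidates[:, None]).mean(axis=1) * 100.0
    ok = np.nonzero(exceedance <= target_fa)[0]
    return float(candidates[ok[0]])


def _rates(movement_w: np.ndarray, null_w: np.ndarray, thr: float) -> tuple[float, float]:
    fa = 100.0 * float(np.mean(null_w > thr))
    tp = 100.0 * float(np.mean(movement_w > thr))
    return fa, tp


def characterize_detector(
    movement_scores,
    null_scores,
    window_grid=(1, 2, 4, 8),
    thresholds=None,
    combine: str = "mean",
) -> list[DetectorReport]:
    """Full false-alarm / true-positive trade-off over a config grid.

    For each window length, thresholds default to the union of observed
    windowed scores (plus one point above the maximum), tracing the whole
    operating curve.
    """
    movement_scores = np.asarray(movement_scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    if movement_scores.size == 0 or null_scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    reports: list[DetectorReport] = []
    for w in window_grid:
        if w > movement_scores.size or w > null_scores.size:
            continue
        mw = accumulate_decisions(movement_scores, w, combine)
        nw = accumulate_decisions(null_scores, w, combine)
        if thresholds is None:
            pool = np.unique(np.concatenate([mw, nw]))
            grid = np.concatenate([pool, [pool[-1] + 1e-9 * max(1.0, abs(pool[-1]))]])
        else:
            grid = np.asarray(thresholds, dtype=float)
        for thr in grid:
            fa, tp = _rates(mw, nw, float(thr))
            reports.append(
                DetectorReport(
                    false_alarm_rate=fa,
                    true_positive_rate=tp,
                    threshold=float(thr),
                    window_trials=int(w),
                    combine=combine,
                )
            )
    return reports


def tradeoff_frame(reports: list[DetectorReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def save_tradeoff_tsv(reports: list[DetectorReport], path: str | Path) -> None:
    tradeoff_frame(reports)[
        ["window_trials", "threshold", "false_alarm_rate", "true_positive_rate"]
    ].to_csv(path, sep="\t", index=False)


def evaluate_brain_switch(
    movement_scores,
    null_scores,
    window_trials: int = 8,
    target_fa: float = 0.0,
    combine: str = "mean",
    calibration_fraction: float = 0.5,
) -> DetectorReport:
    """Calibrate on the first part of the null data, evaluate on the rest.

    The null windows are split chronologically: the leading
    ``calibration_fraction`` sets the threshold for the requested
    false-alarm target, and the report's rates come from the held-out null
    windows and all movement windows.
    """
    mw = accumulate_decisions(movement_scores, window_trials, combine)
    nw = accumulate_decisions(null_scores, window_trials, combine)
    n_cal = int(round(calibration_fraction * nw.size))
    if n_cal < 20 or nw.size - n_cal < 1:
        raise ValueError(
            "too few null windows to split into calibration and evaluation sets"
        )
    thr = calibrate_threshold(nw[:n_cal], target_fa=target_fa)
    fa, tp = _rates(mw, nw[n_cal:], thr)
    return DetectorReport(
        false_alarm_rate=fa,
        true_positive_rate=tp,
        threshold=thr,
        window_trials=window_trials,
        combine=combine,
    )
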