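"""Accuracy confidence intervals and permutation chance-level checks.

Subject-level accuracies get a binomial CI (Clopper-Pearson exact by
default, normal approximation optionally); group means over subjects get
the standard t-based CI, mean +/- t(0.975, n-1) * sd / sqrt(n).  With
balanced two-class trials, chance level is 50%, so a lower CI limit above
50 marks above-chance performance at p = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.proportion import proportion_confint

from .classifier import crossval_accuracy

__all__ = [
    "AccuracyCI",
    "GroupCI",
    "PermutationResult",
    "binomial_ci",
    "group_mean_ci",
    "permutation_chance",
    "round_percent",
    "format_ci",
]


@dataclass(frozen=True)
class AccuracyCI:
    """Single-accuracy binomial confidence interval, in percent."""

    accuracy: float
    n: int
    lower: float
    upper: float
    method: str
    level: float = 0.95


@dataclass(frozen=True)
class GroupCI:
    """t-based confidence interval for a group-mean accuracy, in percent."""

    mean: float
    lower: float
    upper: float
    n_subjects: int
    level: float = 0.95


@dataclass(frozen=True)
class PermutationResult:
    accuracies: np.ndarray
    observed: float
    quantile: float  # empirical quantile of the observed accuracy
    seed: int


def binomial_ci(
    correct: int,
    n: int,
    level: float = 0.95,
    method: str = "clopper_pearson",
) -> AccuracyCI:
    """Binomial CI for ``correct`` successes out of ``n`` trials (percent).

    ``method="clopper_pearson"`` gives the exact beta-quantile interval;
    ``method="normal"`` the Wald approximation p +/- z*sqrt(p(1-p)/n),
    clipped to [0, 100].
    """
    if n < 1 or not 0 <= correct <= n:
        raise ValueError(f"invalid counts: correct={correct}, n={n}")
    alpha = 1.0 - level
    if method == "clopper_pearson":
        lo, hi = proportion_confint(correct, n, alpha=alpha, method="beta")
    elif method == "normal":
        lo, hi = proportion_confint(correct, n, alpha=alpha, method="normal")
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AccuracyCI(
        accuracy=100.0 * correct / n,
        n=n,
        lower=100.0 * float(lo),
        upper=100.0 * float(hi),
        method=method,
        level=level,
    )


def group_mean_ci(accuracies, level: float = 0.95) -> GroupCI:
    """t-interval for the mean of per-subject accuracies (percent in/out)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 accuracies for a group CI")
    n = acc.size
    mean = float(acc.mean())
    sem = float(acc.std(ddof=1) / np.sqrt(n))
    tcrit = float(spstats.t.ppf(1.0 - (1.0 - level) / 2.0, df=n - 1))
    half = tcrit * sem
    return GroupCI(mean=mean, lower=mean - half, upper=mean + half, n_subjects=n)


def permutation_chance(
    features,
    labels=None,
    n_perm: int = 100,
    seed: int = 0,
    k: int = 10,
    selection: str = "nested",
) -> PermutationResult:
    """Empirical chance distribution by label shuffling.

    Each permutation shuffles the labels and recomputes the full
    cross-validated accuracy; the observed (unpermuted) accuracy is placed
    on the resulting distribution.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    from .classifier import _as_xy  # shared unpacking

    X, y, _ = _as_xy(features, labels)
    observed = crossval_accuracy(X, y, k=k, seed=seed, selection=selection).overall_accuracy
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        y_perm = rng.permutation(y)
        accs[p] = crossval_accuracy(
            X, y_perm, k=k, seed=seed, selection=selection
        ).overall_accuracy
    quantile = float(np.mean(accs < observed))
    return PermutationResult(
        accuracies=accs, observed=observed, quantile=quantile, seed=seed
    )


def round_percent(x: float) -> int:
    """Nearest-integer percent, halves away from zero (display convention)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def format_ci(mean: float, lower: float, upper: float) -> str:
    """Render like ``84 (74-93)``."""
    return f"{round_percent(mean)} ({round_percent(lower)}–{round_percent(upper)})"
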