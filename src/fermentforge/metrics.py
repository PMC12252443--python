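"""Loss and agreement measures shared by all modules.

RMSE = sqrt(RSS/n) is the loss used for soft-sensor calibration and
forecaster training/tuning; R² = 1 − RSS/TSS measures explained
variance and may be negative when a model underperforms the mean
predictor.  For multi-attribute prediction windows, RMSE is taken over
the flattened residuals.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rmse", "r_squared", "relative_reduction"]


def _pair(actual, predicted):
    y = np.asarray(actual, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty prediction pair")
    return y, yhat


def rmse(actual, predicted) -> float:
    """Root-mean-square error; 0 iff the sequences are identical."""
    y, yhat = _pair(actual, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 − RSS/TSS (≤ 1, possibly negative)."""
    y, yhat = _pair(actual, predicted)
    if y.size < 2:
        raise ValueError("R² needs at least 2 observations")
    tss = float(np.sum((y - np.mean(y)) ** 2))
    if tss == 0:
        raise ValueError("R² undefined for a constant actual series (TSS = 0)")
    rss = float(np.sum((y - yhat) ** 2))
    return 1.0 - rss / tss


def relative_reduction(baseline: float, achieved: float) -> float:
    """Percent reduction of ``achieved`` relative to ``baseline``.

    E.g. a loss of 0.16 against a baseline of 0.3 is a 46.67 % reduction.
    """
    if baseline == 0:
        raise ValueError("baseline must be non-zero")
    return (baseline - achieved) / baseline * 100.0
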