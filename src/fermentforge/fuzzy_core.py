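"""Membership-function primitives and data-driven Gaussian partitions.

Each fermentation attribute (sugar, pH, CO₂, biomass, temperature,
alcohol) is partitioned into three fuzzy classes — low, medium, high —
by Gaussian membership functions whose centers and bandwidth are
calibrated from data statistics: the low center sits at the observed
minimum, the medium center at the mean, and the high center at the
maximum shifted by a normalized skewness adjustment δ = (mean−median)/κ,
where κ is the sample standard deviation floored at 0.01.  The module
also provides the triangular / trapezoidal / S-shaped memberships used
for fermentation-phase labelling and a truncated-Gaussian time-series
smoother.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "AttributeStats",
    "GaussianPartition",
    "PartitionSettings",
    "compute_stats",
    "gaussmf",
    "trimf",
    "trapmf",
    "smf",
    "build_partition",
    "gaussian_smooth",
]

logger = logging.getLogger(__name__)

KAPPA_FLOOR = 0.01
CLASSES = ("low", "medium", "high")


@dataclass(frozen=True)
class AttributeStats:
    """Summary statistics of one attribute's pooled observations.

    ``kappa`` is the dispersion used as Gaussian bandwidth and skew
    normalizer: the sample std (ddof=1) floored at 0.01 so that
    near-constant attributes (temperature under strict control) keep a
    well-defined, narrow partition.  ``delta`` = (mean − median)/kappa
    is the dimensionless skewness adjustment.
    """

    mean: float
    median: float
    std: float
    min: float
    max: float
    kappa: float
    delta: float


def compute_stats(series) -> AttributeStats:
    """Compute the partition-calibration statistics of a 1-D series."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 observations to compute statistics")
    mean = float(np.mean(x))
    median = float(np.median(x))
    std = float(np.std(x, ddof=1))
    kappa = KAPPA_FLOOR if std < KAPPA_FLOOR else std
    delta = (mean - median) / kappa
    return AttributeStats(
        mean=mean,
        median=median,
        std=std,
        min=float(np.min(x)),
        max=float(np.max(x)),
        kappa=kappa,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# membership primitives


def gaussmf(x, center: float, width: float):
    """Gaussian membership exp(−(x−c)²/2w²); 1 at the center."""
    if width <= 0:
        raise ValueError("width must be strictly positive")
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - center) ** 2) / (2.0 * width**2))
    return out if out.ndim else float(out)


def trimf(x, a: float, b: float, c: float):
    """Triangular membership with feet a, c and peak b (a ≤ b ≤ c)."""
    if not a <= b <= c:
        raise ValueError("trimf parameters must be non-decreasing")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if b > a:
        rising = (x > a) & (x < b)
        out[rising] = (x[rising] - a) / (b - a)
    if c > b:
        falling = (x >= b) & (x < c)
        out[falling] = (c - x[falling]) / (c - b)
    out[x == b] = 1.0
    return out if out.ndim else float(out)


def trapmf(x, a: float, b: float, c: float, d: float):
    """Trapezoidal membership with feet a, d and plateau [b, c]."""
    if not a <= b <= c <= d:
        raise ValueError("trapmf parameters must be non-decreasing")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    if b > a:
        rising = (x > a) & (x < b)
        out[rising] = (x[rising] - a) / (b - a)
    if d > c:
        falling = (x > c) & (x < d)
        out[falling] = (d - x[falling]) / (d - c)
    out[(x >= b) & (x <= c)] = 1.0
    return out if out.ndim else float(out)


def smf(x, a: float, b: float):
    """S-shaped membership: 0 below a, 1 above b, 0.5 at the midpoint.

    The standard C¹ quadratic-spline S-function.
    """
    if a > b:
        raise ValueError("smf parameters must be non-decreasing")
    x = np.asarray(x, dtype=float)
    if a == b:
        out = (x >= a).astype(float)
        return out if out.ndim else float(out)
    mid = (a + b) / 2.0
    out = np.zeros_like(x)
    lower = (x >= a) & (x <= mid)
    upper = (x > mid) & (x <= b)
    out[lower] = 2.0 * ((x[lower] - a) / (b - a)) ** 2
    out[upper] = 1.0 - 2.0 * ((x[upper] - b) / (b - a)) ** 2
    out[x > b] = 1.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# partitions


@dataclass(frozen=True)
class PartitionSettings:
    """Calibrated partition hyperparameters.

    ``k`` divides the sample std to give the Gaussian bandwidth
    (w = σ/k, default k=3); ``kd`` scales the skewness offset added to
    the high center; ``c_off_low``/``c_off_med`` shift the low/medium
    centers (0 by default); the universe-of-discourse bounds are the
    data range shifted by the calibrated offsets Cmin = −2·min and
    Cmax = 0.2·max.  ``convention`` selects the calibrated-table center
    placement (``"calibrated"``, default: high = max + kd·δ, medium = mean,
    width σ/k) or the alternative (``"median"``: high = max − δ, medium =
    median, width κ).
    """

    k: float = 3.0
    kd: float = 1.0
    c_off_low: float = 0.0
    c_off_med: float = 0.0
    cmin_scale: float = -2.0
    cmax_scale: float = 0.2
    convention: str = "calibrated"


@dataclass(frozen=True)
class GaussianPartition:
    """Low/medium/high Gaussian membership functions of one attribute."""

    attribute_name: str
    centers: tuple  # (low, medium, high)
    width: float
    universe: tuple  # (lo, hi) universe-of-discourse bounds
    offsets: tuple = (0.0, 0.0, 0.0)  # (Cmin, Cmax, Coff_high)

    def __post_init__(self) -> None:
        lo, med, hi = self.centers
        if not lo < med < hi:
            raise ValueError("partition centers must be strictly increasing")
        if self.width <= 0:
            raise ValueError("partition width must be strictly positive")

    def membership(self, x, cls: str):
        return gaussmf(x, self.centers[CLASSES.index(cls)], self.width)

    def memberships(self, x) -> np.ndarray:
        """(3, ...) array of low/medium/high memberships at x."""
        x = np.asarray(x, dtype=float)
        return np.stack([gaussmf(x, c, self.width) for c in self.centers])

    def grid(self, n: int = 501) -> np.ndarray:
        return np.linspace(self.universe[0], self.universe[1], n)


def build_partition(
    stats: AttributeStats,
    attribute_name: str = "",
    settings: PartitionSettings = PartitionSettings(),
) -> GaussianPartition:
    """Build the calibrated low/medium/high partition of an attribute.

    With the default (calibrated-table) convention the centers are
    (min + Cofflow, mean + Coffmed, max + kd·δ) and the bandwidth σ/k;
    a degenerate data range is widened by κ on each side.
    """
    lo, hi = stats.min, stats.max
    if hi - lo <= 0:
        logger.warning(
            "degenerate range for %s (min == max == %g); widening by kappa",
            attribute_name,
            lo,
        )
        lo -= stats.kappa
        hi += stats.kappa

    if settings.convention == "calibrated":
        centers = (
            lo + settings.c_off_low,
            stats.mean + settings.c_off_med,
            hi + settings.kd * stats.delta,
        )
        width = (stats.std if stats.std >= KAPPA_FLOOR else KAPPA_FLOOR) / settings.k
    elif settings.convention == "median":
        centers = (lo, stats.median, hi - stats.delta)
        width = stats.kappa
    else:
        raise ValueError(f"unknown partition convention {settings.convention!r}")

    if not centers[0] < centers[1] < centers[2]:
        # extreme skew can push centers out of order; fall back to the
        # unshifted data anchors, which are ordered after range widening
        logger.warning("center offsets broke ordering for %s; using raw anchors", attribute_name)
        centers = (lo, (lo + hi) / 2.0, hi)

    universe = (lo + settings.cmin_scale * lo, hi + settings.cmax_scale * hi)
    if universe[0] > centers[0]:
        universe = (centers[0] - 3 * width, universe[1])
    if universe[1] < centers[2]:
        universe = (universe[0], centers[2] + 3 * width)
    off_high = (
        settings.kd * stats.delta if settings.convention == "calibrated" else -stats.delta
    )
    return GaussianPartition(
        attribute_name=attribute_name,
        centers=centers,
        width=width,
        universe=universe,
        offsets=(settings.cmin_scale * lo, settings.cmax_scale * hi, off_high),
    )


# ---------------------------------------------------------------------------
# smoothing


def gaussian_smooth(series, sigma: float):
    """Smooth a series by a truncated, normalized Gaussian kernel.

    The kernel is truncated at |lag| ≤ 4σ and normalized to sum to
    unity; boundaries replicate the nearest observed value, so constant
    series pass through unchanged.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    return gaussian_filter1d(x, sigma=sigma, mode="nearest", truncate=4.0)
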