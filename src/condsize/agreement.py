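"""Agreement and repeatability statistics for method validation.

Bland–Altman analysis of predicted vs reference diameters: mean and
(sample, n-1) standard deviation of the pairwise differences, the SD
doubling as the repeatability coefficient, plus the fractions of points
within 1 and 2 SD of the mean difference and an ordinary least-squares
fit of predicted on measured with its r-squared.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FitError, InputError

__all__ = ["AgreementStats", "bland_altman", "linear_fit_r2", "bland_altman_plot"]


@dataclass(frozen=True)
class AgreementStats:
    """Summary of a Bland–Altman agreement analysis (units follow the input, mm here)."""

    mean_diff: float
    sd_diff: float
    repeatability: float
    frac_within_1sd: float
    frac_within_2sd: float
    loa_low: float   # mean_diff - 1.96 sd
    loa_high: float  # mean_diff + 1.96 sd
    slope: float
    intercept: float
    r2: float
    n: int


def linear_fit_r2(x, y):
    """Ordinary least squares of y on x; returns (slope, intercept, r2).

    r2 is the squared Pearson correlation.  A constant y gives r2 = 0;
    a constant x has no defined fit and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("need at least three points for a fit")
    if np.ptp(x) == 0:
        raise FitError("zero variance in x: slope undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    from scipy.stats import linregress

    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(predicted, measured, *, center: str = "mean") -> AgreementStats:
    """Bland–Altman agreement between predicted and reference values.

    Differences are predicted - measured.  ``frac_within_ksd`` counts
    points with |diff - center| <= k * SD, where the centre is the mean
    difference by default (``center="zero"`` counts from zero instead).
    Swapping the inputs negates the mean difference and preserves the SD.
    """
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size != m.size:
        raise InputError("predicted and measured must have equal length")
    if p.size < 2:
        raise InputError("need at least two pairs")
    if center not in ("mean", "zero"):
        raise InputError("center must be 'mean' or 'zero'")
    diff = p - m
    mean_diff = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    c = mean_diff if center == "mean" else 0.0
    # sd = 0 degenerates to exact-equality counting
    within1 = float(np.mean(np.abs(diff - c) <= sd))
    within2 = float(np.mean(np.abs(diff - c) <= 2 * sd))
    try:
        slope, intercept, r2 = linear_fit_r2(m, p)
    except (FitError, InputError):
        slope = intercept = r2 = float("nan")
    return AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd,
        repeatability=sd,
        frac_within_1sd=within1,
        frac_within_2sd=within2,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n=int(p.size),
    )


def bland_altman_plot(predicted, measured, path, *, units: str = "mm"):
    """Write a Bland–Altman scatter (difference vs mean) with limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    stats = bland_altman(p, m)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((p + m) / 2, p - m, color="k", s=25)
    ax.axhline(stats.mean_diff, color="b", label="mean")
    for y, style in ((stats.loa_low, "--"), (stats.loa_high, "--")):
        ax.axhline(y, color="r", linestyle=style)
    ax.set_xlabel(f"mean of methods ({units})")
    ax.set_ylabel(f"difference ({units})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return stats
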