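"""Ratio-scale (log-transformed) Bland-Altman agreement and paired summaries.

Urinary iodine excretion is right-skewed, so method agreement between a
predicted and a measured 24-h excretion is assessed on the natural-log
scale.  Per pair the difference ``d_i = ln(pred_i) - ln(meas_i)`` is
formed; the antilog of the mean difference is the geometric-mean ratio of
the two methods (reported as a percentage: 100% = exact agreement, 80% =
the prediction under-reads the measurement by 20% on average), and the
antilogs of ``mean(d) ± z·sd(d)`` are the 95% limits of agreement (LOA) —
the interval expected to contain 95% of the between-method ratios.

The ratio is taken in the prediction-over-measurement direction by
default, so a mean below 100% reads directly as average under-prediction;
a ``direction`` flag flips it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "PairedSummary",
    "bland_altman_log",
    "loa_coverage",
    "paired_summary",
    "bland_altman_frame",
]


@dataclass
class BlandAltmanResult:
    """Log-scale Bland-Altman agreement between two positive-valued methods.

    Percentages are antilogged ratios (100 = perfect agreement).  The
    per-pair arrays ``mean_log`` (x-axis: mean of the two ln values) and
    ``log_diff`` (y-axis: ln difference) reproduce the conventional plot.
    """

    mean_ratio_pct: float
    loa_low_pct: float
    loa_high_pct: float
    mean_log_diff: float
    sd_log_diff: float
    z: float
    n: int
    n_excluded_nonpositive: int
    direction: str
    mean_log: np.ndarray = field(repr=False)
    log_diff: np.ndarray = field(repr=False)


def _paired_positive(pred, meas, what: str = "Bland-Altman"):
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape:
        raise ValueError("pred and meas must be paired (equal length)")
    finite = np.isfinite(p) & np.isfinite(m)
    positive = finite & (p > 0) & (m > 0)
    n_excluded = int(np.sum(finite & ~positive))
    if n_excluded:
        warnings.warn(
            f"{what}: excluded {n_excluded} pair(s) with non-positive values "
            "(log undefined)",
            stacklevel=3,
        )
    return p[positive], m[positive], n_excluded


def bland_altman_log(
    pred, meas, z: float = 1.96, direction: str = "pred_over_meas"
) -> BlandAltmanResult:
    """Compute log-scale Bland-Altman agreement between paired series.

    Parameters
    ----------
    pred, meas
        Paired positive series (µg/day or any common unit — the statistics
        are scale-invariant).  Pairs containing non-positive or missing
        values are excluded with a warning and counted in the result.
    z
        LOA multiplier (1.96 for 95% limits).
    direction
        ``"pred_over_meas"`` (default) or ``"meas_over_pred"``.

    The sd of the log differences uses the n-1 sample estimator.
    """
    if direction not in ("pred_over_meas", "meas_over_pred"):
        raise ValueError(f"unknown direction {direction!r}")
    p, m, n_excluded = _paired_positive(pred, meas)
    if p.size < 3:
        raise ValueError("need at least 3 positive pairs for limits of agreement")
    lp, lm = np.log(p), np.log(m)
    d = lp - lm if direction == "pred_over_meas" else lm - lp
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_ratio_pct=float(np.exp(mean_d) * 100.0),
        loa_low_pct=float(np.exp(mean_d - z * sd_d) * 100.0),
        loa_high_pct=float(np.exp(mean_d + z * sd_d) * 100.0),
        mean_log_diff=mean_d,
        sd_log_diff=sd_d,
        z=z,
        n=int(p.size),
        n_excluded_nonpositive=n_excluded,
        direction=direction,
        mean_log=(lp + lm) / 2.0,
        log_diff=d,
    )


def loa_coverage(result: BlandAltmanResult, pred=None, meas=None) -> float:
    """Percent of per-pair ratios falling inside the limits of agreement.

    Uses the pairs stored in ``result`` unless fresh series are supplied
    (which must then be the same pairs the limits were computed from).
    """
    if pred is not None or meas is not None:
        p, m, _ = _paired_positive(pred, meas, what="loa_coverage")
        d = np.log(p) - np.log(m)
        if result.direction == "meas_over_pred":
            d = -d
    else:
        d = result.log_diff
    ratio_pct = np.exp(d) * 100.0
    inside = (ratio_pct >= result.loa_low_pct) & (ratio_pct <= result.loa_high_pct)
    return float(np.mean(inside) * 100.0)


@dataclass(frozen=True)
class PairedSummary:
    """Distribution comparison of paired predicted vs measured series."""

    n: int
    median_pred: float
    iqr_pred: float
    median_meas: float
    iqr_meas: float
    median_difference: float
    iqr_difference: float
    mannwhitney_p: float
    spearman_rho: float
    spearman_p: float


def _median_iqr(x):
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q75 - q25)


def paired_summary(pred, meas) -> PairedSummary:
    """Medians with IQR, median paired difference (measured minus predicted),
    a two-sided Mann-Whitney rank-sum p-value for the two distributions,
    and the Spearman rank correlation of the pairs."""
    p = np.asarray(pred, dtype=float)
    m = np.asarray(meas, dtype=float)
    if p.shape != m.shape:
        raise ValueError("pred and meas must be paired (equal length)")
    keep = np.isfinite(p) & np.isfinite(m)
    p, m = p[keep], m[keep]
    if p.size < 2:
        raise ValueError("need at least 2 pairs")
    med_p, iqr_p = _median_iqr(p)
    med_m, iqr_m = _median_iqr(m)
    med_d, iqr_d = _median_iqr(m - p)
    mw = stats.mannwhitneyu(p, m, alternative="two-sided")
    rho = stats.spearmanr(p, m)
    return PairedSummary(
        n=int(p.size),
        median_pred=med_p,
        iqr_pred=iqr_p,
        median_meas=med_m,
        iqr_meas=iqr_m,
        median_difference=med_d,
        iqr_difference=iqr_d,
        mannwhitney_p=float(mw.pvalue),
        spearman_rho=float(rho.statistic),
        spearman_p=float(rho.pvalue),
    )


def bland_altman_frame(result: BlandAltmanResult) -> pd.DataFrame:
    """Per-pair plot data: x = mean of ln values, y = ln difference."""
    return pd.DataFrame(
        {"mean_log": result.mean_log, "log_diff": result.log_diff}
    )


def plot_bland_altman(result: BlandAltmanResult, ax=None):
    """Render the conventional plot (requires matplotlib).

    Scatter of ln difference against the per-pair mean of the ln values,
    with horizontal reference lines at the mean and the limits of
    agreement, annotated with their antilogged percentages.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.mean_log, result.log_diff, s=12, alpha=0.6, edgecolors="none")
    for value, pct, style in (
        (result.mean_log_diff, result.mean_ratio_pct, "-"),
        (result.mean_log_diff - result.z * result.sd_log_diff, result.loa_low_pct, "--"),
        (result.mean_log_diff + result.z * result.sd_log_diff, result.loa_high_pct, "--"),
    ):
        ax.axhline(value, linestyle=style, color="grey")
        ax.annotate(f"{pct:.0f}%", xy=(1.0, value), xycoords=("axes fraction", "data"),
                    xytext=(3, 0), textcoords="offset points", va="center")
    ax.set_xlabel("mean of ln(predicted) and ln(measured)")
    ax.set_ylabel("ln(predicted) − ln(measured)")
    return ax
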