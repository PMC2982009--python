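"""Empirical confidence envelopes and linear trend fits.

The sweep's per-alpha predicted metric means are compared against 95%
confidence limits built from the observed annual values of the same
metric.  The default band is the normal-theory band on the annual values,
mean +/- t_{0.975, n-1} * s.d.: it describes the spread of single annual
values, which is what a predicted annual mean is being compared against,
and with short series (n ~ 30) it is far less ragged than raw 2.5/97.5
percentiles, which are dominated by the two most extreme years.  A
"percentile" method is available.  Standard-error-of-the-mean bands are
deliberately not offered as a default: predicted values are compared to
annual-value variability, not to the uncertainty of the empirical mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import SweepResult

__all__ = [
    "EnvelopeReport",
    "TrendFit",
    "empirical_limits",
    "compare_to_envelope",
    "linear_trend",
]


@dataclass(frozen=True)
class EnvelopeReport:
    """Per-alpha envelope membership for one metric.

    ``per_alpha`` lists (alpha, predicted_mean, within_limits) with a closed
    interval convention (a prediction exactly on a limit is within);
    ``matching_interval`` is the maximal contiguous alpha range flagged
    within, or None if no alpha matches.
    """

    metric_name: str
    lower_limit: float
    upper_limit: float
    limit_method: str
    per_alpha: list[tuple[float, float, bool]] = field(repr=False)
    matching_interval: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
            "limit_method": self.limit_method,
            "matching_interval": self.matching_interval,
            "per_alpha": [
                {"alpha": a, "predicted_mean": m, "within_limits": bool(w)}
                for a, m, w in self.per_alpha
            ],
        }


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an annual metric series on its 1-based year index."""

    metric_name: str
    slope: float
    intercept: float
    r_squared: float
    slope_p_value: float
    n_points: int


def empirical_limits(values, method: str = "normal-band") -> tuple[float, float]:
    """95% confidence limits from the annual values of a metric series.

    ``"normal-band"``: mean +/- t_{0.975, n-1} * sample s.d. of the annual
    values.  ``"percentile"``: empirical 2.5/97.5 quantiles.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("empirical limits need at least 3 annual values")
    if np.ptp(values) == 0:
        warnings.warn("constant series: degenerate limits (lower = upper = mean)")
        return float(values[0]), float(values[0])
    if method == "normal-band":
        n = values.size
        mean = values.mean()
        half = stats.t.ppf(0.975, n - 1) * values.std(ddof=1)
        return float(mean - half), float(mean + half)
    if method == "percentile":
        lo, hi = np.quantile(values, [0.025, 0.975])
        return float(lo), float(hi)
    raise ValueError("method must be 'normal-band' or 'percentile'")


def _matching_interval(alphas, within) -> tuple[float, float] | None:
    """Longest contiguous run of within-flags (first run wins ties)."""
    best = None
    best_len = 0
    run_start = None
    for i, w in enumerate(within):
        if w and run_start is None:
            run_start = i
        if (not w or i == len(within) - 1) and run_start is not None:
            end = i if w else i - 1
            length = end - run_start + 1
            if length > best_len:
                best_len = length
                best = (float(alphas[run_start]), float(alphas[end]))
            run_start = None
    return best


def compare_to_envelope(
    sweep: SweepResult,
    limits: dict[str, tuple[float, float]],
    limit_method: str = "normal-band",
) -> dict[str, EnvelopeReport]:
    """Flag each alpha whose predicted mean lies inside the empirical band."""
    reports: dict[str, EnvelopeReport] = {}
    for metric, (lo, hi) in limits.items():
        if metric not in sweep.metric_names:
            raise KeyError(f"metric {metric!r} missing from sweep result")
        if lo > hi:
            raise ValueError(f"lower limit exceeds upper limit for {metric!r}")
        preds = sweep.mean[metric].to_numpy()
        within = (preds >= lo) & (preds <= hi)
        reports[metric] = EnvelopeReport(
            metric_name=metric,
            lower_limit=lo,
            upper_limit=hi,
            limit_method=limit_method,
            per_alpha=[
                (float(a), float(p), bool(w))
                for a, p, w in zip(sweep.alphas, preds, within)
            ],
            matching_interval=_matching_interval(sweep.alphas, within),
        )
    return reports


def linear_trend(values, metric_name: str = "") -> TrendFit:
    """OLS of a metric series against its 1-based index, with slope p-value.

    A constant series gets slope 0, R-squared 0 and p-value 1 with a
    warning (the regression is degenerate, not an error).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("linear trend needs at least 3 points")
    x = np.arange(1, values.size + 1, dtype=float)
    if np.ptp(values) == 0:
        warnings.warn("constant series: trend fit degenerate (slope 0)")
        return TrendFit(metric_name, 0.0, float(values[0]), 0.0, 1.0, values.size)
    fit = stats.linregress(x, values)
    return TrendFit(
        metric_name=metric_name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_p_value=float(fit.pvalue),
        n_points=values.size,
    )
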