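"""Optional matplotlib figures: annual metric series with fitted trend,
and sweep predictions against the empirical 95% envelope.

Imported lazily so the core package has no hard matplotlib dependency.
"""

from __future__ import annotations

import numpy as np

from .envelope import EnvelopeReport, TrendFit


def plot_annual_series(years, values, fit: TrendFit | None = None, ax=None):
    """Metric value per year with the OLS trend line overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(years, values, "o-", color="0.3")
    if fit is not None:
        x = np.arange(1, len(values) + 1)
        ax.plot(years, fit.intercept + fit.slope * x, "--", color="crimson")
        ax.set_title(
            f"{fit.metric_name}: slope {fit.slope:.4g}, R^2 {fit.r_squared:.3f}"
        )
    ax.set_xlabel("year")
    return ax


def plot_envelope(report: EnvelopeReport, ax=None):
    """Predicted metric mean vs alpha, shaded by the empirical 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    alphas = [a for a, _, _ in report.per_alpha]
    preds = [m for _, m, _ in report.per_alpha]
    within = [w for _, _, w in report.per_alpha]
    ax.axhspan(report.lower_limit, report.upper_limit, color="0.85")
    ax.plot(alphas, preds, "-", color="0.3")
    ax.plot(
        [a for a, w in zip(alphas, within) if w],
        [p for p, w in zip(preds, within) if w],
        "o",
        color="seagreen",
        label="within 95% limits",
    )
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(report.metric_name)
    ax.legend(loc="best")
    return ax
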