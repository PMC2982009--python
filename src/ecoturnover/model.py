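"""AR(1) turnover simulator and the autocorrelation sweep.

Each species' abundance trajectory follows

    Y_t = alpha * Y_{t-1} + Z_t,      Z_t ~ Normal(0, sd_i),

started at Y_0 = 0, run for ``years_total`` years with the last
``years_keep`` retained, then rescaled by adding the species' empirical
mean.  alpha is shared across species; noise is independent per species and
there is no among-species correlation — species dynamics are completely
independent.  alpha = 0 is white noise about the mean, alpha -> 1 a random
walk, alpha < 0 year-to-year overcompensation.

The sweep runs the simulator over a grid of alpha values (default -1..+1 in
steps of 0.05, 41 values), replicated, and reduces each assemblage metric
to its mean over the kept years (or year pairs) and then over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import rankdata

from .io import AbundanceMatrix, SpeciesProfile
from .metrics import DIVERSITY_METRICS, TURNOVER_METRICS

__all__ = [
    "SimulationConfig",
    "SimulatedAssemblage",
    "SweepResult",
    "default_alpha_grid",
    "ar1_filter",
    "simulate_species",
    "simulate_assemblage",
    "alpha_sweep",
]

ALL_METRICS = DIVERSITY_METRICS + TURNOVER_METRICS


def default_alpha_grid() -> np.ndarray:
    """-1.00 to +1.00 inclusive in steps of 0.05 (41 values)."""
    return np.round(np.linspace(-1.0, 1.0, 41), 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Sweep design: alpha grid, replication and the 50/30-year window.

    ``years_total`` years are simulated and the last ``years_keep`` kept, a
    fixed burn-in rather than a convergence test.  ``clamp_negative``
    truncates negative predicted abundances at 0 before metrics are
    computed (the metrics require non-negative abundances); raw values are
    available by turning it off.
    """

    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    n_replicates: int = 1000
    years_total: int = 50
    years_keep: int = 30
    clamp_negative: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.alpha_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", grid)
        if np.any(np.abs(grid) > 1):
            raise ValueError("every alpha must lie in [-1, 1]")
        if self.years_keep > self.years_total:
            raise ValueError("years_keep must not exceed years_total")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimulatedAssemblage:
    alpha: float
    replicate_id: int
    matrix: AbundanceMatrix


@dataclass(frozen=True)
class SweepResult:
    """Per-alpha, per-metric means over replicates, with replicate spread.

    ``mean``, ``rep_sd`` and ``n_skipped`` are DataFrames indexed by alpha
    with one column per metric; ``n_skipped`` counts degenerate simulated
    years (or year pairs) that were excluded from a replicate's average.
    """

    alphas: np.ndarray
    metric_names: tuple[str, ...]
    mean: pd.DataFrame
    rep_sd: pd.DataFrame
    n_skipped: pd.DataFrame
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: alpha, metric, mean, rep_sd, n_skipped."""
        rows = []
        for alpha in self.mean.index:
            for m in self.metric_names:
                rows.append(
                    {
                        "alpha": alpha,
                        "metric": m,
                        "mean": self.mean.loc[alpha, m],
                        "rep_sd": self.rep_sd.loc[alpha, m],
                        "n_skipped": int(self.n_skipped.loc[alpha, m]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ar1_filter(noise: np.ndarray, alpha: float) -> np.ndarray:
    """Run Y_t = alpha*Y_{t-1} + Z_t from Y_0 = 0 along the last axis."""
    return lfilter([1.0], [1.0, -alpha], np.asarray(noise, dtype=float), axis=-1)


def simulate_species(
    alpha: float,
    profile: SpeciesProfile,
    years_total: int = 50,
    years_keep: int = 30,
    rng: np.random.Generator | None = None,
    clamp_negative: bool = True,
) -> np.ndarray:
    """One species' predicted abundances over the kept years.

    Gaussian noise with the species' empirical s.d. drives the AR(1)
    recursion from 0; the last ``years_keep`` states are kept and the
    empirical mean added to each.
    """
    if years_keep > years_total:
        raise ValueError("years_keep must not exceed years_total")
    if rng is None:
        rng = np.random.default_rng()
    z = rng.normal(0.0, profile.sd, size=years_total)
    y = ar1_filter(z, alpha)[years_total - years_keep :]
    out = y + profile.mean
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return out


def simulate_assemblage(
    profiles: list[SpeciesProfile],
    alpha: float,
    years_total: int = 50,
    years_keep: int = 30,
    rng: np.random.Generator | None = None,
    clamp_negative: bool = True,
    replicate_id: int = 0,
) -> SimulatedAssemblage:
    """Independent AR(1) series for every species under a shared alpha."""
    if not profiles:
        raise ValueError("at least one species profile is required")
    if rng is None:
        rng = np.random.default_rng()
    sds = np.array([p.sd for p in profiles])
    means = np.array([p.mean for p in profiles])
    values = _simulate_values(
        alpha, means, sds, years_total, years_keep, rng, clamp_negative
    )
    matrix = AbundanceMatrix(
        [p.species_id for p in profiles], list(range(1, years_keep + 1)), values
    )
    return SimulatedAssemblage(alpha=alpha, replicate_id=replicate_id, matrix=matrix)


def _simulate_values(alpha, means, sds, years_total, years_keep, rng, clamp):
    z = rng.normal(size=(len(sds), years_total)) * sds[:, None]
    y = ar1_filter(z, alpha)[:, years_total - years_keep :]
    out = y + means[:, None]
    if clamp:
        out = np.maximum(out, 0.0)
    return out


def _cell_rng(seed: int, alpha: float, replicate: int) -> np.random.Generator:
    """Independent stream per (alpha, replicate): changing the grid or the
    replicate count never perturbs other cells."""
    akey = int(round(alpha * 100)) + 100  # 0..200, unique per grid point
    return np.random.default_rng(np.random.SeedSequence((seed, akey, replicate)))


def _replicate_metric_means(values: np.ndarray, metric_names) -> dict[str, tuple[float, int]]:
    """Per-metric mean over the kept years/pairs of one simulated matrix.

    Degenerate units (an all-zero year for diversity metrics; a year pair
    with no individuals in either year for turnover metrics) are skipped
    and counted, so extreme-alpha cells stay computable.
    """
    out: dict[str, tuple[float, int]] = {}
    totals = values.sum(axis=0)
    alive = totals > 0

    need_div = [m for m in metric_names if m in DIVERSITY_METRICS]
    if need_div:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = values / totals
        skipped = int((~alive).sum())
        for m in need_div:
            if m == "N0":
                per_year = (values > 0).sum(axis=0).astype(float)
            elif m == "N1":
                plogp = np.where(values > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
                per_year = np.exp(-plogp.sum(axis=0))
            elif m == "N2":
                per_year = 1.0 / (p * p).sum(axis=0)
            else:  # Ninf
                maxv = values.max(axis=0)
                per_year = np.where(maxv > 0, totals / np.where(maxv > 0, maxv, 1.0), np.nan)
            ok = per_year[alive]
            out[m] = (float(ok.mean()) if ok.size else float("nan"), skipped)

    need_turn = [m for m in metric_names if m in TURNOVER_METRICS]
    if need_turn:
        x = values[:, :-1]
        y = values[:, 1:]
        pair_alive = (totals[:-1] + totals[1:]) > 0
        skipped = int((~pair_alive).sum())
        if "BrayCurtis" in need_turn:
            num = np.abs(x - y).sum(axis=0)
            den = (x + y).sum(axis=0)
            bc = np.where(pair_alive, num / np.where(den > 0, den, 1.0), np.nan)
            ok = bc[pair_alive]
            out["BrayCurtis"] = (float(ok.mean()) if ok.size else float("nan"), skipped)
        if "MRS" in need_turn:
            vals = []
            for k in range(values.shape[1] - 1):
                if not pair_alive[k]:
                    continue
                xk, yk = x[:, k], y[:, k]
                pool = (xk > 0) | (yk > 0)
                rx = rankdata(-xk[pool], method="average")
                ry = rankdata(-yk[pool], method="average")
                vals.append(np.mean(np.abs(ry - rx)))
            out["MRS"] = (float(np.mean(vals)) if vals else float("nan"), skipped)
    return out


def alpha_sweep(
    profiles: list[SpeciesProfile],
    config: SimulationConfig | None = None,
    metric_names=ALL_METRICS,
) -> SweepResult:
    """Replicated simulation over the alpha grid, reduced to metric means.

    For every alpha and replicate an assemblage is simulated from the
    profiles, each requested metric is averaged over the kept years (or
    consecutive pairs), and those replicate values are then averaged (and
    spread measured) over replicates.
    """
    if config is None:
        config = SimulationConfig()
    unknown = [m for m in metric_names if m not in ALL_METRICS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {ALL_METRICS}")
    if not profiles:
        raise ValueError("at least one species profile is required")
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))

    means = np.array([p.mean for p in profiles])
    sds = np.array([p.sd for p in profiles])
    alphas = config.alpha_grid
    metric_names = tuple(metric_names)

    mean_tab = np.empty((len(alphas), len(metric_names)))
    sd_tab = np.empty_like(mean_tab)
    skip_tab = np.zeros_like(mean_tab, dtype=int)

    for i, alpha in enumerate(alphas):
        rep_vals = np.empty((config.n_replicates, len(metric_names)))
        for r in range(config.n_replicates):
            rng = _cell_rng(seed, alpha, r)
            values = _simulate_values(
                alpha, means, sds, config.years_total, config.years_keep,
                rng, config.clamp_negative,
            )
            per = _replicate_metric_means(values, metric_names)
            for j, m in enumerate(metric_names):
                rep_vals[r, j] = per[m][0]
                skip_tab[i, j] += per[m][1]
        mean_tab[i] = np.nanmean(rep_vals, axis=0)
        sd_tab[i] = np.nanstd(rep_vals, axis=0, ddof=1)

    idx = pd.Index(alphas, name="alpha")
    return SweepResult(
        alphas=alphas,
        metric_names=metric_names,
        mean=pd.DataFrame(mean_tab, index=idx, columns=metric_names),
        rep_sd=pd.DataFrame(sd_tab, index=idx, columns=metric_names),
        n_skipped=pd.DataFrame(skip_tab, index=idx, columns=metric_names),
        n_replicates=config.n_replicates,
    )
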