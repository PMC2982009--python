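"""Diversity and composition-turnover metrics.

Hill numbers (N0 richness, N1 = exp Shannon, N2 = inverse Simpson,
Ninf = reciprocal Berger-Parker dominance) summarise the shape of the
species-abundance distribution for a single year while ignoring species
identities.  Mean rank shift (MRS) and Bray-Curtis dissimilarity track
identity: they compare consecutive pairs of years and respond to species
swapping ranks or flickering in and out of the assemblage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.stats import rankdata

from .io import AbundanceMatrix

__all__ = [
    "DiversityProfile",
    "TurnoverProfile",
    "hill_n0",
    "hill_n1",
    "hill_n2",
    "hill_ninf",
    "berger_parker_dominance",
    "bray_curtis",
    "mean_rank_shift",
    "diversity_series",
    "turnover_series",
    "DIVERSITY_METRICS",
    "TURNOVER_METRICS",
]

DIVERSITY_METRICS = ("N0", "N1", "N2", "Ninf")
TURNOVER_METRICS = ("MRS", "BrayCurtis")


@dataclass(frozen=True)
class DiversityProfile:
    """Annual values of one Hill number across the years of a series."""

    metric_name: str
    years: list[int]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "metric": self.metric_name, "value": self.values}
        )


@dataclass(frozen=True)
class TurnoverProfile:
    """Values of one composition metric for consecutive year pairs."""

    metric_name: str
    year_pairs: list[tuple[int, int]]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year_from": [a for a, _ in self.year_pairs],
                "year_to": [b for _, b in self.year_pairs],
                "metric": self.metric_name,
                "value": self.values,
            }
        )


def _as_abundances(x, name: str = "abundances") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be a 1-d vector")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite and non-negative")
    return x


def _require_individuals(x: np.ndarray) -> np.ndarray:
    if x.sum() <= 0:
        raise ValueError("diversity is undefined for an all-zero abundance vector")
    return x


def hill_n0(abundances) -> int:
    """Species richness: the number of species with positive abundance."""
    x = _require_individuals(_as_abundances(abundances))
    return int(np.count_nonzero(x > 0))


def hill_n1(abundances) -> float:
    """Exponential of the Shannon entropy (effective species number).

    Zero abundances contribute nothing to the entropy sum (the limit
    convention 0*ln 0 = 0).
    """
    x = _require_individuals(_as_abundances(abundances))
    p = x[x > 0] / x.sum()
    p = p[p > 0]  # guard against underflow of extreme abundance ratios
    return float(np.exp(-np.sum(p * np.log(p))))


def hill_n2(abundances) -> float:
    """Inverse Simpson concentration, 1 / sum(p_i^2)."""
    x = _require_individuals(_as_abundances(abundances))
    p = x[x > 0] / x.sum()
    p = p[p > 0]
    return float(1.0 / np.sum(p * p))


def hill_ninf(abundances) -> float:
    """Reciprocal Berger-Parker dominance, sum(x) / max(x).

    This is Hill's N_inf form: the reciprocal of the relative abundance of
    the single most abundant species, so a perfectly even S-species
    assemblage scores S and a monoculture scores 1.
    """
    x = _require_individuals(_as_abundances(abundances))
    return float(x.sum() / x.max())


def berger_parker_dominance(abundances) -> float:
    """Raw Berger-Parker dominance d = max(x) / sum(x) (in (0, 1])."""
    x = _require_individuals(_as_abundances(abundances))
    return float(x.max() / x.sum())


_HILL = {"N0": hill_n0, "N1": hill_n1, "N2": hill_n2, "Ninf": hill_ninf}


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = _as_abundances(x, "x")
    y = _as_abundances(y, "y")
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if x.sum() + y.sum() <= 0:
        raise ValueError("Bray-Curtis is undefined when both vectors are all zero")
    return float(_sp_braycurtis(x, y))


def mean_rank_shift(x, y, species_pool: str = "union") -> float:
    """Mean absolute change in abundance rank between two censuses.

    Species are pooled over the two years (``species_pool="union"``: any
    species positive in either year; ``"intersection"``: positive in both),
    ranked by abundance descending within each year (rank 1 = most
    abundant), with ties — including the block of species absent in one
    year — assigned the mid-rank of their tied block.  Returns the mean of
    the absolute rank differences over the pooled species.

    The union pool is the default because species that shift between
    presence at low rank and absence are exactly what the metric should
    register; mid-rank ties keep the result invariant to species ordering.
    """
    x = _as_abundances(x, "x")
    y = _as_abundances(y, "y")
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if species_pool == "union":
        pool = (x > 0) | (y > 0)
    elif species_pool == "intersection":
        pool = (x > 0) & (y > 0)
    else:
        raise ValueError("species_pool must be 'union' or 'intersection'")
    if not pool.any():
        raise ValueError("mean rank shift is undefined for an empty species pool")
    rx = rankdata(-x[pool], method="average")
    ry = rankdata(-y[pool], method="average")
    return float(np.mean(np.abs(ry - rx)))


def diversity_series(matrix: AbundanceMatrix, metric_name: str) -> DiversityProfile:
    """One Hill number evaluated per year, in year order."""
    if metric_name not in _HILL:
        raise ValueError(f"unknown diversity metric {metric_name!r}; use {DIVERSITY_METRICS}")
    fn = _HILL[metric_name]
    out = np.empty(matrix.n_years)
    for j, year in enumerate(matrix.years):
        col = matrix.values[:, j]
        if col.sum() <= 0:
            raise ValueError(f"year {year} has no individuals; diversity undefined")
        out[j] = fn(col)
    return DiversityProfile(metric_name, list(matrix.years), out)


def turnover_series(
    matrix: AbundanceMatrix, metric_name: str, species_pool: str = "union"
) -> TurnoverProfile:
    """One composition metric evaluated for each consecutive pair of years."""
    if metric_name not in TURNOVER_METRICS:
        raise ValueError(f"unknown turnover metric {metric_name!r}; use {TURNOVER_METRICS}")
    if matrix.n_years < 2:
        raise ValueError("turnover needs at least two years")
    pairs = list(zip(matrix.years[:-1], matrix.years[1:]))
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        x = matrix.values[:, k]
        y = matrix.values[:, k + 1]
        try:
            if metric_name == "BrayCurtis":
                out[k] = bray_curtis(x, y)
            else:
                out[k] = mean_rank_shift(x, y, species_pool=species_pool)
        except ValueError as exc:
            raise ValueError(f"year pair ({a}, {b}): {exc}") from exc
    return TurnoverProfile(metric_name, pairs, out)
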