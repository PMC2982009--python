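"""Asynchrony randomization test.

Do species abundances covary through time?  The statistic is the median
Pearson correlation over all unordered species pairs (computed across
years).  Its null distribution is built by independently shuffling each
species' abundances among years — which preserves every marginal abundance
distribution while destroying temporal association — and recomputing the
median.  The observed median is reported next to the null 2.5% / 97.5%
quantiles; interpretation is left to the caller.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .io import AbundanceMatrix

__all__ = ["AsynchronyReport", "pairwise_median_r", "shuffle_null", "asynchrony_test"]


@dataclass(frozen=True)
class AsynchronyReport:
    observed_median_r: float
    null_q025: float
    null_q975: float
    n_replicates: int
    n_pairs_used: int
    n_pairs_dropped: int
    seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _median_r(values: np.ndarray) -> tuple[float, int, int]:
    """Median pairwise Pearson r over rows; zero-variance rows dropped.

    Returns (median, n_pairs_used, n_pairs_dropped).  Pearson r is
    undefined when either series is constant, so all pairs touching a
    constant row are dropped and counted rather than imputed as 0.
    """
    n = values.shape[0]
    total_pairs = n * (n - 1) // 2
    usable = values.std(axis=1) > 0
    k = int(usable.sum())
    used = k * (k - 1) // 2
    if used < 1:
        raise ValueError(
            "no usable species pairs: fewer than two species with non-zero variance"
        )
    corr = np.corrcoef(values[usable])
    iu = np.triu_indices(k, 1)
    median = float(np.median(corr[iu]))
    return median, used, total_pairs - used


def pairwise_median_r(matrix: AbundanceMatrix) -> tuple[float, int, int]:
    """Observed median pairwise Pearson r with (used, dropped) pair counts."""
    if matrix.n_species < 2 or matrix.n_years < 3:
        raise ValueError("pairwise correlations need >=2 species and >=3 years")
    return _median_r(matrix.values)


def shuffle_null(
    matrix: AbundanceMatrix, n_replicates: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Null distribution of the median pairwise r under year-shuffling.

    Each replicate permutes every species' abundances among years with an
    independent permutation per species, then recomputes the median
    pairwise correlation.  Returns the ``n_replicates`` null medians.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.n_species < 2 or matrix.n_years < 3:
        raise ValueError("pairwise correlations need >=2 species and >=3 years")
    rng = np.random.default_rng(seed)
    values = matrix.values
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        perm = np.argsort(rng.random(values.shape), axis=1)
        shuffled = np.take_along_axis(values, perm, axis=1)
        out[r], _, _ = _median_r(shuffled)
    return out


def asynchrony_test(
    matrix: AbundanceMatrix, n_replicates: int = 1000, seed: int | None = None
) -> AsynchronyReport:
    """Observed median pairwise r against its shuffle-among-years null.

    Null quantiles are empirical order-statistic quantiles (linear
    interpolation) of the replicate medians; the observed median is not
    pooled into the null, and both pair counts are reported so either
    p-value convention can be recovered by the caller.
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    observed, used, dropped = pairwise_median_r(matrix)
    nulls = shuffle_null(matrix, n_replicates=n_replicates, seed=seed)
    q025, q975 = np.quantile(nulls, [0.025, 0.975])
    return AsynchronyReport(
        observed_median_r=observed,
        null_q025=float(q025),
        null_q975=float(q975),
        n_replicates=n_replicates,
        n_pairs_used=used,
        n_pairs_dropped=dropped,
        seed=seed,
    )
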