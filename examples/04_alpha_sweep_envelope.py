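"""Which year-to-year autocorrelation levels reproduce the observed
assemblage?  A reduced alpha sweep with envelope comparison.

Every species is simulated as Y_t = alpha*Y_{t-1} + Z_t around its
empirical mean, alpha swept over a grid; each metric's predicted mean is
compared with the 95% confidence band of the observed annual values.
"""

import numpy as np

from ecoturnover import (
    SimulationConfig,
    SyntheticConfig,
    compare_to_envelope,
    diversity_series,
    empirical_limits,
    generate_assemblage,
    alpha_sweep,
    select_core,
    species_profiles,
    turnover_series,
)

matrix, truth = generate_assemblage(SyntheticConfig(seed=1))
core = select_core(matrix)
profiles = species_profiles(core)

# coarse grid and modest replication keep this example quick
config = SimulationConfig(
    alpha_grid=np.round(np.arange(-1.0, 1.01, 0.1), 2), n_replicates=100, seed=1
)
metrics = ("N1", "N2", "Ninf", "MRS", "BrayCurtis")
sweep = alpha_sweep(profiles, config, metric_names=metrics)

limits = {}
for name in metrics:
    series = (
        diversity_series(core, name)
        if name in ("N1", "N2", "Ninf")
        else turnover_series(core, name)
    )
    limits[name] = empirical_limits(series.values)

for name, report in compare_to_envelope(sweep, limits).items():
    lo, hi = report.lower_limit, report.upper_limit
    print(
        f"{name:10s} empirical 95% band ({lo:6.2f}, {hi:6.2f})   "
        f"matching alpha interval: {report.matching_interval}"
    )
print(f"(generating autocorrelation was alpha_true = {truth.alpha_true})")

# Diversity metrics match over a broad alpha range: many turnover regimes
# produce the same diversity profile.  The identity-tracking metrics (MRS,
# Bray-Curtis) match on a narrower, positively-skewed range around the true
# autocorrelation - they carry more information about turnover.
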