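"""Do species covary through time?  The asynchrony randomization test.

The observed median pairwise Pearson correlation (across years) is
compared with a null built by independently shuffling each species'
abundances among years, which destroys temporal association while keeping
every species' abundance distribution.
"""

from ecoturnover import (
    SyntheticConfig,
    asynchrony_test,
    generate_assemblage,
    generate_shared_driver_assemblage,
    select_core,
)

matrix, _ = generate_assemblage(SyntheticConfig(seed=1))
report = asynchrony_test(select_core(matrix), n_replicates=1000, seed=1)
print("independent species (core subset):")
print(f"  observed median r = {report.observed_median_r:+.4f}")
print(f"  null 95% interval = [{report.null_q025:+.4f}, {report.null_q975:+.4f}]")
inside = report.null_q025 <= report.observed_median_r <= report.null_q975
print(f"  observed inside null interval: {inside}")

driven, _ = generate_shared_driver_assemblage(SyntheticConfig(seed=1), 3.0)
report2 = asynchrony_test(select_core(driven), n_replicates=1000, seed=1)
print("shared environmental driver (negative control):")
print(f"  observed median r = {report2.observed_median_r:+.4f}")
print(f"  null 95% interval = [{report2.null_q025:+.4f}, {report2.null_q975:+.4f}]")

# With independent dynamics the observed median sits inside the null
# interval (asynchrony); a strong common driver pushes it far above the
# 97.5% quantile, which is how synchronous forcing would be detected.
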