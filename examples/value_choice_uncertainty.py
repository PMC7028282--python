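"""Monte Carlo over normalization and weighting value choices.

Normalization and weighting factors are value choices; this example samples
synthetic factor pools with the published structure (4 footprint sets x 4
handprint sets x 26 weighting sub-sets x 3 handprint variants = 1248
combinations), 10,000 iterations, and compares the sampled RSBR spread with
the exact exhaustive enumeration.
"""

from rsbr import (
    MonteCarloConfig,
    builtin_case,
    enumerate_combinations,
    paper_shaped_pools,
    run_monte_carlo,
)

case = builtin_case("sth_vietnam")
pools = paper_shaped_pools(seed=0, case_name="sth_vietnam")
print(f"pool structure: {pools.combination_count} combinations")

summary = run_monte_carlo(case, MonteCarloConfig(pools=pools, iterations=10_000, seed=0))
s = summary.combined_rsbr
print(
    f"combined RSBR over 10,000 iterations: median {s.median:.1f}% "
    f"(min {s.min:.1f}%, max {s.max:.1f}%), n defined = {s.n}"
)

table = enumerate_combinations(case, pools)
print(
    f"exact enumeration of all {len(table)} combinations: "
    f"median {table['combined_rsbr'].median():.1f}% "
    f"(min {table['combined_rsbr'].min():.1f}%, max {table['combined_rsbr'].max():.1f}%)"
)
print(
    "-> the sampled spread sits inside the enumerated extremes; the sign of"
    " the benefit is robust to the value choices in these pools."
)
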