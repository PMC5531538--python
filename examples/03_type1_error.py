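"""Empirical type-I error of one-stage vs two-stage filtered screening.

Simulates summary statistics for 200,000 independent null variants
(no GxS: beta1 = beta2 = 0, MAF 0.05, 100,000 individuals per stratum)
and tabulates the share of difference tests significant at the nominal
5% level for each screening approach, next to the exact value from
2-D Gaussian integration.
"""

from stratdiff import (
    ApproachSpec,
    EffectScenario,
    SimulationConfig,
    conditional_type1_oracle,
    estimate_type1,
)

cfg = SimulationConfig(n_variants=200_000, maf=0.05, seed=123)
null_sc = EffectScenario(0.0, 0.0, 1, 100_000, 100_000)

print(f"{'approach':<28s} {'empirical %':>12s} {'exact %':>9s}")
for filt, layout in [
    ("none", "one_stage"),
    ("overall", "one_stage"),
    ("strat", "one_stage"),
    ("joint", "one_stage"),
    ("overall", "two_stage"),
    ("strat", "two_stage"),
    ("joint", "two_stage"),
]:
    spec = ApproachSpec(filter=filt, alpha_filter=0.05, layout=layout)
    res = estimate_type1(cfg, spec)
    if layout == "one_stage":
        exact = conditional_type1_oracle(filt, 0.05, null_sc)
    else:
        exact = 0.05  # filtering on an independent stage restores the level
    name = f"[{filt} -> diff] {layout}"
    print(f"{name:<28s} {100 * res.rate:12.2f} {100 * exact:9.2f}")

# Only the one-stage stratified and joint filters violate the 5% level
# (~43% and ~50%): their filter statistics are correlated with the
# difference statistic, so conditioning on passing distorts its null
# distribution.  The overall filter is orthogonal to the difference test
# and any filter is safe when applied to an independent first stage.
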