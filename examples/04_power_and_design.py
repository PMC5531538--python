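"""Analytical power and design calculations.

Prints the minimum detectable per-allele effects for two reference
designs, then the power of the four recommended approaches for the three
GxS types at balanced strata of 100,000, and a small table of unfiltered
difference-test power against strata imbalance f = n2/n1.
"""

from stratdiff import (
    ApproachSpec,
    EffectScenario,
    min_detectable_beta,
    ncp,
    power_approach,
    power_z,
)

print("minimum detectable per-allele effect (80% power, two-sided 5%):")
for n, maf in [(200_000, 0.05), (200_000, 0.30), (100_000, 0.05), (100_000, 0.30)]:
    print(f"  n = {n:,}, MAF = {maf:.2f}: beta = {min_detectable_beta(n, maf):.3f}")

scenarios = {
    "pure (R1^2=0.058%)": EffectScenario(0.00058, 0.0, 0),
    "qualitative (R1^2=R2^2=0.014%)": EffectScenario(0.00014, 0.00014, -1),
    "quantitative (R1^2=0.167%, R2=R1/2)": EffectScenario(0.00167, 0.00167 / 4, 1),
}
approaches = {
    "[Diff 5e-8]": ApproachSpec(filter="none"),
    "[Overall 1e-5 -> Diff]": ApproachSpec(filter="overall", alpha_filter=1e-5),
    "[Strat 1e-5] -> [Diff]": ApproachSpec(filter="strat", alpha_filter=1e-5,
                                           layout="two_stage"),
    "[Joint 1e-5] -> [Diff]": ApproachSpec(filter="joint", alpha_filter=1e-5,
                                           layout="two_stage"),
}

# M: expected number of lead variants the filter passes, supplied by the
# analyst (from a pilot screen or a variant-count model); 115 here
M = 115
print(f"\npower by GxS type (balanced 2 x 100,000, M = {M}):")
for sc_name, sc in scenarios.items():
    print(f"  {sc_name}")
    for ap_name, spec in approaches.items():
        res = power_approach(spec, sc, M=M)
        flag = " (approximate)" if res.approximate else ""
        print(f"    {ap_name:<24s} {100 * res.power_approach:6.1f}%{flag}")

print("\nunfiltered difference-test power vs imbalance (pure GxS, n = 200,000):")
n_total = 200_000
for f in (0.2, 0.5, 1.0, 2.0, 5.0):
    n1 = int(round(n_total / (1 + f)))
    sc = EffectScenario(0.00058, 0.0, 0, n1, n_total - n1)
    print(f"  f = {f:4.1f}: power = {100 * power_z(ncp('diff', sc), 5e-8):5.1f}%")

# The genome-wide difference test is best for opposite-direction effects;
# overall-association filtering is best when the effect is confined to, or
# larger in, one stratum.  Difference-test power peaks at f = 1 and is
# symmetric in f <-> 1/f.
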