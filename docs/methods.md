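# Methods

## Model and assumptions

Each stratum's GWAS fits, per variant, the linear model
Y = α + βG + E with a continuous phenotype standardized to unit
variance within study and stratum, additive genotype coding
G ∈ {0,1,2}, and genotype variance σ_G² = 2·MAF·(1−MAF) assumed equal
across studies and strata (the variant is not associated with the
stratum variable). Study estimates are pooled within stratum by
fixed-effect inverse-variance weighting; with similar populations the
pooled (β̂ᵢ, seᵢ) are asymptotically those of a single mega-study of
nᵢ individuals, which is the approximation the whole framework runs
on. Between-study heterogeneity, binary outcomes, unequal phenotype
variances between strata, and allele-frequency differences between
strata are out of scope.

Under these assumptions seᵢ ≈ √(1−βᵢ²σ_G²)/(σ_G√nᵢ) and the four test
statistics are (non)central normal/χ² with the noncentralities given in
the README; all tests are two-sided, matching genome-wide convention
(5×10⁻⁸ = 0.05/10⁶ independent variants).

## Why the one-stage overall filter is valid and the others are not

For independent strata, (Z_Diff, Z_Overall) is an orthogonal rotation
of (Z₁, Z₂), so C_Joint = Z_Diff² + Z_Overall² identically and
Z_Overall ⟂ Z_Diff under any null. Filtering on overall association
therefore leaves the null distribution of the difference test intact.
Z₁ and Z₂ each correlate with Z_Diff (corr(Z_Diff, Z₁) =
se₁/√(se₁²+se₂²), = 1/√2 for equal strata), so selecting on them — or
on C_Joint — selects extreme difference statistics too.
`power.conditional_type1_oracle` quantifies this exactly by integrating
the bivariate normal density of (Z₁, Z₂) over the filter-pass and
difference-reject regions on a 2401² grid spanning ±9 SD (quadrature
error < 1e-4, verified against the closed-form 5% for the overall
filter); the simulation harness reproduces the same rates to Monte
Carlo error.

## Screening conventions

* **Stratified filter**: pass if either stratum has two-sided
  p < α_Filter/2 (a Bonferroni split across the two strata, so the
  filter's marginal pass rate under the global null is
  1−(1−α_Filter/2)² ≈ α_Filter). This convention reproduces both the
  reference filtered-variant counts and the ~43% one-stage inflation;
  the uncorrected either-stratum rule is available via
  `strat_filter_bonferroni=False`.
* **Lead variants**: greedy distance pruning — repeatedly take the
  smallest filter p-value as a lead and drop remaining variants within
  ±500 kb (inclusive) on the same chromosome. Ties break on smaller p,
  then smaller position, then marker id; the result is independent of
  input order. No LD information is used. Variants without positions
  are each their own lead.
* **α_Diff**: 5×10⁻⁸ without filtering, else 0.05/M over the M leads.
  M = 0 yields an empty report rather than a division by zero.
* **Two-stage**: the filter sees only stage-1 estimates, the
  difference test only stage-2 estimates of stage-1 leads (never the
  pooled ones — pooling would reintroduce the dependence the split
  exists to remove).
* **GxS type labels**: qualitative = opposite signs with both strata
  nominally significant (p < 0.05, configurable); pure = exactly one
  stratum nominally significant or one beta exactly zero;
  quantitative = same sign, both significant. These labels are a
  convention for reporting, not part of any test.

## Harmonization conventions

Join key is marker id (chr:pos joining via flag); coordinates are
1-based with inclusive windows. Stratum 2 is aligned to stratum 1's
effect allele: swapped-allele records get β → −β and eaf → 1−eaf;
allele pairs matching neither orientation are dropped and counted.
Palindromic A/T and C/G variants cannot be strand-checked from allele
labels alone, so they are flagged and passed through rather than
silently flipped. Rows with missing/non-numeric beta or se ≤ 0 are
dropped and counted at read time. Variants present in only one stratum
are excluded from difference testing.

## Simulation engines

The default engine samples summary statistics directly:
β̂ᵢ ~ N(βᵢ, seᵢ²) with the closed-form seᵢ above, bivariate with
correlation r when requested, seeded through a single
`numpy.random.default_rng` stream per configuration. The reported se is
the true value, not a per-variant estimate: at n ≥ 50,000 per stratum
the sampling noise of the se estimate is negligible. The
individual-level engine (Binomial(2, MAF) genotypes, OLS per variant,
estimated se) exists to validate that claim at small n; a two-sample
Kolmogorov–Smirnov check at n = 2,000 per stratum and 2,000 variants
confirms the two engines produce matching (β̂, Z) distributions.
Monomorphic genotype draws (possible at small n·MAF) are skipped with a
warning.

Simulated variants are independent and carry no genomic positions, so
every filtered variant is its own lead and the type-I-error harness
judges each difference test at the fixed nominal 5% level — the
convention under which the rates are tabulated. Default conditions are
10⁶ variants, MAF 0.05 or 0.30, and 200,000 individuals split into two
strata (halved again per stage in two-stage layouts); at that scale one
configuration simulates in under two seconds, so no scaling down was
needed. Non-null "no GxS" scenarios (β₁ = β₂ = β ≠ 0) set β to the
exact, unrounded minimum detectable effect for the design, since the
filtered-variant counts are sensitive to rounding β to 3 decimals.

What the simulations do *not* emulate: LD between variants (so lead
pruning is never stressed under realistic correlation), effect
heterogeneity between studies, phenotype measurement error, or
allele-frequency differences between strata. Passing tests show the
statistics and screening logic are correct under the stated model, not
that distance-based pruning is a good LD proxy on real data.

## Power calculations

`power_approach` multiplies filter power and difference power
(Power_Approach = Power_Filter · Power_Diff), exact when the factors
are independent — the overall filter, or any filter across two stages —
and flagged `approximate` for one-stage stratified/joint filters (which
are invalid screens anyway). Two-stage layouts evaluate the filter at
stage-1 sample sizes and the difference test at stage-2 sizes (each
stratum halved). The expected lead count M is a required caller input:
it depends on the true genome-wide effect distribution, which a
per-variant calculation cannot know. M ≈ 115 at α_Filter = 10⁻⁵
reproduces the reference filtered-approach powers for 2×100,000
designs (see `examples/04_power_and_design.py`).

Numerical choices: `power_z` keeps both normal tails (the far tail is
~10⁻⁶ at conventional levels and irrelevant at genome-wide ones, kept
for correctness at ncp ≈ 0), so the minimum-detectable-effect round
trip reproduces the target power to ~1e-6 rather than bit-exactly.
Noncentral χ² power uses `scipy.stats.ncx2` and was cross-checked
against Monte Carlo sampling of two shifted normals. p-values can be
taken on the −log10 scale (`neglog10_p_from_z`) where the two-sided
normal tail underflows double precision (|Z| ≳ 38). The (1−R²)
residual-variance factor is kept in the simulator's se but dropped in
the scenario algebra, where R² ≤ 0.2% makes it a < 10⁻³ relative
effect — below Monte Carlo resolution in every comparison made here.

Quantitative/qualitative scenario grids use exact ratios
(R₂ = R₁/2, R₁/4, …); displayed values like 0.042% are rounded forms
of R₁²/4 and using the rounded numbers instead shifts third-digit
power values.

## Design decisions that were genuinely open

* Whether the stratified filter Bonferroni-splits α_Filter across
  strata is not derivable from the test definitions; the split variant
  was adopted because it matches the reference pass counts and
  inflation rates, with the uncorrected rule kept as an option.
* λ_GC uses the median definition (median observed 1-df χ² divided by
  0.4549); the between-strata correlation estimator uses all
  harmonized variants by default (no LD pruning, no MAF floor — both
  available as options) since the estimand is a genome-wide nuisance
  correlation, not an effect.
* Relatedness enters power only through effective sample sizes
  supplied by the caller and through r in the difference-test variance;
  the package computes no kinship.

## Known limitations

Distance-based pruning only (no LD clumping); fixed-effect pooling
only (no heterogeneity statistics, no overlap correction between
studies within a stratum); no FDR alternative to Bonferroni; the GxS
type labels are heuristics. Real-data applications should treat the
flagged palindromic variants with an external strand check.
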