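"""Per-variant test statistics for stratified GWAMA results.

A stratified genome-wide association meta-analysis (GWAMA) yields, for
every variant, a pooled per-allele effect estimate and standard error in
each of two strata (e.g. men/women, smokers/non-smokers).  Four tests can
be computed from these two pairs alone:

* the **difference test** ``Z_Diff`` — the definitive test for a
  between-strata difference of the genetic effect (GxS);
* the **overall association test** ``Z_Overall`` — the inverse-variance
  combination of both strata, statistically independent of the difference
  test;
* the **stratified association tests** ``Z_1``/``Z_2`` — per-stratum Wald
  tests;
* the **alternative joint test** ``C_Joint`` — the sum of squared
  stratum statistics, chi-square with 2 df, equivalent to jointly testing
  main and interaction effects for a dichotomous stratum factor.

All functions accept scalars or NumPy arrays and broadcast; p-values are
two-sided.  When strata share related individuals the per-variant effect
estimates are correlated across strata; ``z_diff`` accepts the
between-strata correlation ``r`` (estimable genome-wide via
:func:`estimate_correlation`) and corrects the variance of the difference,
which makes the statistic more extreme (never less) for r > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "StrataCorrelation",
    "z_diff",
    "z_overall",
    "z_strat",
    "c_joint",
    "estimate_correlation",
    "lambda_gc",
    "qq_points",
    "neglog10_p_from_z",
]

#: median of the chi-square distribution with 1 df, reference point for
#: the genomic-control inflation factor
CHI2_1DF_MEDIAN = float(stats.chi2.median(1))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one of the stratified GWAMA tests.

    ``statistic`` is a Z score for the 1-df tests and the chi-square value
    C for the joint test; ``p_value`` is the two-sided tail probability.
    Fields hold arrays when the inputs were arrays.
    """

    test: str
    statistic: np.ndarray | float
    p_value: np.ndarray | float
    df: int = 1


@dataclass(frozen=True)
class StrataCorrelation:
    """Genome-wide Pearson correlation of the two strata's effect estimates."""

    r: float
    n_variants_used: int
    boundary: bool = False  # |r| numerically at 1: degenerate input


def _two_sided_normal_p(z):
    return 2.0 * stats.norm.sf(np.abs(z))


def neglog10_p_from_z(z):
    """-log10 of the two-sided normal p-value, safe far below 1e-308."""
    # logsf keeps precision where sf underflows
    return -(stats.norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)


def z_diff(beta1, se1, beta2, se2, r: float = 0.0) -> TestResult:
    """Difference test for a between-strata effect difference.

    Z = (b1 - b2) / sqrt(se1^2 + se2^2 - 2*r*se1*se2), where ``r`` is the
    between-strata correlation of the estimates (0 for strata with no
    shared/related individuals, in which case the uncorrected difference
    test is recovered exactly).
    """
    beta1, se1 = np.asarray(beta1, float), np.asarray(se1, float)
    beta2, se2 = np.asarray(beta2, float), np.asarray(se2, float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    var = se1**2 + se2**2 - 2.0 * r * se1 * se2
    if np.any(var <= 0):
        raise ValueError(
            "non-positive variance of the effect difference; |r| must be < 1"
        )
    z = (beta1 - beta2) / np.sqrt(var)
    return TestResult("diff", z[()] if z.ndim == 0 else z, _two_sided_normal_p(z))


def z_overall(beta1, se1, beta2, se2) -> TestResult:
    """Overall association test: IVW combination of the two strata.

    Z = (b1/se1^2 + b2/se2^2) / sqrt(1/se1^2 + 1/se2^2); identical to the
    IVW-pooled beta divided by its pooled standard error.  Orthogonal to
    the difference test under the null.
    """
    beta1, se1 = np.asarray(beta1, float), np.asarray(se1, float)
    beta2, se2 = np.asarray(beta2, float), np.asarray(se2, float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    w1, w2 = se1**-2, se2**-2
    z = (beta1 * w1 + beta2 * w2) / np.sqrt(w1 + w2)
    return TestResult("overall", z[()] if z.ndim == 0 else z, _two_sided_normal_p(z))


def z_strat(beta, se, stratum: int = 1) -> TestResult:
    """Stratified association test for one stratum: Z = beta / se."""
    beta, se = np.asarray(beta, float), np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z = beta / se
    return TestResult(
        f"strat{stratum}", z[()] if z.ndim == 0 else z, _two_sided_normal_p(z)
    )


def c_joint(beta1, se1, beta2, se2) -> TestResult:
    """Alternative joint test: C = Z1^2 + Z2^2, chi-square with 2 df.

    Under the null of no effect in either stratum C is central
    chi-square(2); for independent strata the identity
    C = Z_Diff^2 + Z_Overall^2 holds for any input.
    """
    beta1, se1 = np.asarray(beta1, float), np.asarray(se1, float)
    beta2, se2 = np.asarray(beta2, float), np.asarray(se2, float)
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise ValueError("standard errors must be positive")
    c = (beta1 / se1) ** 2 + (beta2 / se2) ** 2
    p = stats.chi2.sf(c, 2)
    return TestResult("joint", c[()] if c.ndim == 0 else c, p, df=2)


def estimate_correlation(records, min_variants: int = 10) -> StrataCorrelation:
    """Between-strata correlation of effect estimates across variants.

    Computed as the Pearson correlation of the per-variant (beta1, beta2)
    pairs over all variants with both strata present.  A nonzero value
    indicates relatedness or sample overlap across strata and should be
    passed to :func:`z_diff`.

    ``records`` may be a harmonized DataFrame with ``beta1``/``beta2``
    columns or any pair-convertible two-column array.
    """
    if isinstance(records, pd.DataFrame):
        sub = records[["beta1", "beta2"]].dropna()
        b1 = sub["beta1"].to_numpy(float)
        b2 = sub["beta2"].to_numpy(float)
    else:
        arr = np.asarray(records, float)
        mask = ~np.isnan(arr).any(axis=1)
        b1, b2 = arr[mask, 0], arr[mask, 1]
    n = b1.size
    if n < min_variants:
        raise ValueError(
            f"only {n} complete variants (< {min_variants}); too few to "
            "estimate the between-strata correlation — consider r = 0"
        )
    r = float(np.corrcoef(b1, b2)[0, 1])
    boundary = bool(abs(r) >= 1.0 - 1e-12)
    return StrataCorrelation(r=r, n_variants_used=n, boundary=boundary)


def lambda_gc(p_values=None, z_scores=None, chi2_stats=None) -> float:
    """Genomic-control inflation factor.

    Median of the implied 1-df chi-square statistics divided by the
    chi-square(1) median (0.4549...).  Exactly one input kind is required.
    """
    given = [x is not None for x in (p_values, z_scores, chi2_stats)]
    if sum(given) != 1:
        raise ValueError("provide exactly one of p_values, z_scores, chi2_stats")
    if chi2_stats is not None:
        chi2 = np.asarray(chi2_stats, float)
    elif z_scores is not None:
        chi2 = np.asarray(z_scores, float) ** 2
    else:
        p = np.asarray(p_values, float)
        chi2 = stats.chi2.isf(p, 1)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite statistics supplied")
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def qq_points(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p-values for a QQ plot.

    Observed p-values are sorted ascending; the i-th expected quantile is
    i/(n+1).  Returns a DataFrame with ``expected`` and ``observed``
    columns of -log10 p.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = obs.size
    exp = np.arange(1, n + 1) / (n + 1.0)
    return pd.DataFrame(
        {"expected": -np.log10(exp), "observed": -np.log10(obs)}
    )
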