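"""Synthetic stratified GWAMA results and empirical type-I error.

The default engine samples summary statistics directly: for a variant with
true per-allele effect beta_i in stratum i (phenotype-SD units, phenotype
variance 1, genotype variance sigma_G^2 = 2*MAF*(1-MAF)), the pooled
estimate from n_i individuals has standard error

    se_i = sqrt(1 - beta_i^2 * sigma_G^2) / (sigma_G * sqrt(n_i))

and beta-hat_i is drawn normal around beta_i with that sd.  At GWAMA
sample sizes (n_i >= 50,000) this is indistinguishable from an
individual-level simulation followed by per-stratum least squares — an
individual-level generator is retained for small-scale cross-validation.
A nonzero between-strata correlation ``r`` (relatedness across strata)
makes the pair (beta-hat_1, beta-hat_2) bivariate normal.

Simulated variants are independent and carry no genomic positions, so
lead-variant pruning degenerates to the identity: every variant passing a
filter is its own lead.  The type-I-error harness accordingly reports the
share of difference tests nominally significant at the 5% level among all
difference tests conducted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association_tests import c_joint, z_diff, z_overall, z_strat
from .screening import ApproachSpec

__all__ = [
    "SimulationConfig",
    "SummaryStatsSim",
    "TypeIErrorResult",
    "simulate_summary",
    "simulate_individual",
    "estimate_type1",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation scenario.

    Defaults mirror the reference design: one million independent
    variants, 200,000 individuals split into two equally sized strata.
    ``layout='two_stage'`` halves each stratum per stage, emulating a
    data set split into two independent study waves.
    """

    n_variants: int = 1_000_000
    maf: float = 0.05
    beta1: float = 0.0
    beta2: float = 0.0
    n1: int = 100_000
    n2: int = 100_000
    layout: str = "one_stage"
    r: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("stratum sizes must be >= 2")
        if self.layout not in ("one_stage", "two_stage"):
            raise ValueError("layout must be 'one_stage' or 'two_stage'")
        if not (-1.0 < self.r < 1.0):
            raise ValueError("|r| must be < 1")

    @property
    def sigma_g(self) -> float:
        return float(np.sqrt(2.0 * self.maf * (1.0 - self.maf)))


@dataclass
class SummaryStatsSim:
    """Simulated per-stratum pooled estimates (one stage)."""

    beta1: np.ndarray
    se1: float
    beta2: np.ndarray
    se2: float
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        n = self.beta1.size
        return pd.DataFrame({
            "marker": [f"sim{i}" for i in range(n)],
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
        })


@dataclass
class TypeIErrorResult:
    """Empirical difference-test rejection rate at the nominal 5% level."""

    n_tested: int
    n_significant: int
    rate: float
    undefined: bool = False


def _true_se(beta: float, sigma_g: float, n: int) -> float:
    resid = 1.0 - beta**2 * sigma_g**2
    if resid <= 0:
        raise ValueError(
            f"effect beta={beta} explains >= 100% of phenotype variance at this MAF"
        )
    return float(np.sqrt(resid) / (sigma_g * np.sqrt(n)))


def simulate_summary(config: SimulationConfig, rng: np.random.Generator | None = None
                     ) -> SummaryStatsSim | tuple[SummaryStatsSim, SummaryStatsSim]:
    """Draw summary-level stratified GWAMA results.

    Returns one :class:`SummaryStatsSim` for the one-stage layout, or a
    (stage1, stage2) pair with per-stage sample sizes n_i/2 for the
    two-stage layout.  Reproducible from ``config.seed`` when no ``rng``
    is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.layout == "two_stage":
        half = replace(
            config, layout="one_stage", n1=config.n1 // 2, n2=config.n2 // 2
        )
        return simulate_summary(half, rng), simulate_summary(half, rng)

    se1 = _true_se(config.beta1, config.sigma_g, config.n1)
    se2 = _true_se(config.beta2, config.sigma_g, config.n2)
    m = config.n_variants
    if config.r == 0.0:
        b1 = rng.normal(config.beta1, se1, m)
        b2 = rng.normal(config.beta2, se2, m)
    else:
        z1 = rng.normal(size=m)
        z2 = config.r * z1 + np.sqrt(1.0 - config.r**2) * rng.normal(size=m)
        b1 = config.beta1 + se1 * z1
        b2 = config.beta2 + se2 * z2
    return SummaryStatsSim(b1, se1, b2, se2, config)


def simulate_individual(config: SimulationConfig, rng: np.random.Generator | None = None
                        ) -> SummaryStatsSim:
    """Individual-level generator: genotypes, phenotypes, per-stratum OLS.

    Genotypes are Binomial(2, maf); phenotypes Y = beta*G + E with E normal
    such that Var(Y) = 1.  Returns per-variant least-squares slopes and
    their estimated standard errors (unlike :func:`simulate_summary`, the
    reported se varies by variant).  Intended for small n as a
    cross-validation of the summary-level engine; monomorphic genotype
    draws are reported as NaN with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n1 < 3 or config.n2 < 3:
        raise ValueError("individual-level simulation needs n >= 3 per stratum")
    out = {}
    for stratum, beta, n in ((1, config.beta1, config.n1), (2, config.beta2, config.n2)):
        resid_var = 1.0 - beta**2 * config.sigma_g**2
        if resid_var <= 0:
            raise ValueError("effect explains >= 100% of phenotype variance")
        bhat = np.empty(config.n_variants)
        sehat = np.empty(config.n_variants)
        n_mono = 0
        for v in range(config.n_variants):
            g = rng.binomial(2, config.maf, n).astype(float)
            y = beta * g + rng.normal(0.0, np.sqrt(resid_var), n)
            gc = g - g.mean()
            ssg = float(gc @ gc)
            if ssg == 0.0:
                bhat[v] = np.nan
                sehat[v] = np.nan
                n_mono += 1
                continue
            slope = float(gc @ y) / ssg
            resid = y - y.mean() - slope * gc
            s2 = float(resid @ resid) / (n - 2)
            bhat[v] = slope
            sehat[v] = np.sqrt(s2 / ssg)
        if n_mono:
            import warnings

            warnings.warn(
                f"{n_mono} monomorphic genotype draws skipped in stratum {stratum}"
            )
        out[stratum] = (bhat, sehat)
    return SummaryStatsSim(
        out[1][0], out[1][1], out[2][0], out[2][1], config
    )


def estimate_type1(config: SimulationConfig, spec: ApproachSpec,
                   alpha_diff: float = 0.05) -> TypeIErrorResult:
    """Empirical type-I error of one screening approach under no GxS.

    Requires ``config.beta1 == config.beta2`` (the null of no difference).
    Variants are independent, so every filtered variant is its own lead;
    the difference test is judged at the fixed nominal ``alpha_diff``
    (default 5%), matching how type-I error is tabulated.
    """
    if config.beta1 != config.beta2:
        raise ValueError("type-I error requires the null beta1 == beta2")
    cfg = replace(config, layout="two_stage" if spec.layout == "two_stage" else "one_stage")
    sim = simulate_summary(cfg)
    if spec.layout == "two_stage":
        stage1, stage2 = sim
    else:
        stage1 = stage2 = sim

    mask = _filter_mask(stage1, spec)
    n_tested = int(mask.sum())
    if n_tested == 0:
        return TypeIErrorResult(0, 0, float("nan"), undefined=True)
    p = z_diff(stage2.beta1[mask], stage2.se1, stage2.beta2[mask], stage2.se2,
               r=cfg.r).p_value
    n_sig = int((p < alpha_diff).sum())
    return TypeIErrorResult(n_tested, n_sig, n_sig / n_tested)


def _filter_mask(sim: SummaryStatsSim, spec: ApproachSpec) -> np.ndarray:
    if spec.filter == "none":
        return np.ones(sim.beta1.size, dtype=bool)
    if spec.filter == "overall":
        p = z_overall(sim.beta1, sim.se1, sim.beta2, sim.se2).p_value
        return p < spec.alpha_filter
    if spec.filter == "joint":
        p = c_joint(sim.beta1, sim.se1, sim.beta2, sim.se2).p_value
        return p < spec.alpha_filter
    if spec.filter == "strat":
        p1 = z_strat(sim.beta1, sim.se1, 1).p_value
        p2 = z_strat(sim.beta2, sim.se2, 2).p_value
        scale = 0.5 if spec.strat_filter_bonferroni else 1.0
        return np.minimum(p1, p2) < spec.alpha_filter * scale
    raise ValueError(f"unknown filter {spec.filter!r}")
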