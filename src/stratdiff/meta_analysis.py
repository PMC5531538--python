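"""Fixed-effect inverse-variance-weighted (IVW) meta-analysis.

Stratified GWAMA pools study-specific estimates separately within each
stratum; a fixed-effect model is assumed throughout (equal genetic effects
across studies — identification, not quantification, is the goal).  When
the screening is run in two stages, the per-stage pooled estimates can
themselves be IVW-combined into a single pooled result; IVW pooling is
associative, so stage-wise pooling equals one-shot pooling over studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["StudyEstimate", "PooledEstimate", "ivw_pool", "pool_stages"]


@dataclass(frozen=True)
class StudyEstimate:
    """One study's per-stratum GWAS estimate for a variant."""

    study_id: str
    stratum: int  # 1 or 2
    beta: float  # per-allele effect, phenotype-SD units
    se: float
    n: int
    stage: int | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"se must be > 0 (study {self.study_id})")
        if self.n < 1:
            raise ValueError(f"n must be >= 1 (study {self.study_id})")
        if self.stratum not in (1, 2):
            raise ValueError("stratum must be 1 or 2")


@dataclass(frozen=True)
class PooledEstimate:
    """IVW-pooled effect for one stratum (optionally one stage)."""

    beta: float
    se: float
    n: int
    n_studies: int


def ivw_pool(estimates: Sequence[StudyEstimate] | Iterable[StudyEstimate]) -> PooledEstimate:
    """Pool study estimates for a single stratum by inverse-variance weighting.

    beta = sum(b_k / se_k^2) / sum(1 / se_k^2); se = 1 / sqrt(sum 1/se_k^2).
    """
    ests = list(estimates)
    if not ests:
        raise ValueError("cannot pool an empty collection of estimates")
    strata = {e.stratum for e in ests}
    if len(strata) > 1:
        raise ValueError(f"mixed strata in one pool: {sorted(strata)}")
    w = np.array([e.se**-2 for e in ests])
    b = np.array([e.beta for e in ests])
    wsum = w.sum()
    return PooledEstimate(
        beta=float((w * b).sum() / wsum),
        se=float(wsum**-0.5),
        n=int(sum(e.n for e in ests)),
        n_studies=len(ests),
    )


def pool_stages(stage1: PooledEstimate, stage2: PooledEstimate | None) -> PooledEstimate:
    """Combine two stage-wise pooled estimates into one (IVW again).

    With ``stage2`` absent the stage-1 estimate is returned unchanged.
    """
    if stage2 is None:
        return stage1
    w1, w2 = stage1.se**-2, stage2.se**-2
    wsum = w1 + w2
    return PooledEstimate(
        beta=float((w1 * stage1.beta + w2 * stage2.beta) / wsum),
        se=float(wsum**-0.5),
        n=stage1.n + stage2.n,
        n_studies=stage1.n_studies + stage2.n_studies,
    )
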