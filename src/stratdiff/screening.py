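"""Screening approaches for between-strata effect differences (GxS).

Seven approaches are supported: the genome-wide difference test without
filtering, and three filtering tests (overall, stratified, joint) each in
a one-stage or two-stage layout.  A filtering step keeps variants whose
filter p-value falls below ``alpha_filter``, prunes them to lead variants
(smallest filter p within +/- ``window_bp`` base positions per
chromosome), and then tests the M leads for difference at the
Bonferroni-corrected level 0.05/M.  Without filtering the difference test
runs genome-wide at 5e-8.

One-stage layouts filter and difference-test the same meta-analysis
results; this is only valid for the overall filter, which is
statistically independent of the difference test.  The stratified and
joint filters are correlated with the difference test and inflate its
type-I error unless the filtering is done on an independent first-stage
meta-analysis (two-stage layout), with the difference test on the
second stage only.

The stratified filter applies a Bonferroni split across the two strata:
a variant passes when either stratum has two-sided p < alpha_filter / 2.
Set ``strat_filter_bonferroni=False`` for the uncorrected either-stratum
rule at alpha_filter per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_tests import c_joint, z_diff, z_overall, z_strat

__all__ = ["ApproachSpec", "ScreenReport", "apply_filter", "extract_leads",
           "run_approach", "classify_gxs"]

GENOME_WIDE_ALPHA = 5e-8
FILTERS = ("none", "overall", "strat", "joint")


@dataclass(frozen=True)
class ApproachSpec:
    """One of the seven screening approaches.

    ``filter='none'`` forces the one-stage layout and a fixed genome-wide
    difference level of 5e-8; any other filter uses 0.05/M where M is the
    number of lead variants passing the filter.
    """

    filter: str = "none"
    alpha_filter: float = 1e-5
    layout: str = "one_stage"
    window_bp: int = 500_000
    strat_filter_bonferroni: bool = True

    def __post_init__(self):
        if self.filter not in FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}; expected one of {FILTERS}")
        if self.layout not in ("one_stage", "two_stage"):
            raise ValueError("layout must be 'one_stage' or 'two_stage'")
        if self.filter == "none" and self.layout != "one_stage":
            raise ValueError("the unfiltered difference test has no two-stage form")
        if not (0.0 < self.alpha_filter <= 1.0):
            raise ValueError("alpha_filter must lie in (0, 1]")

    @property
    def alpha_diff_policy(self) -> str:
        return "fixed" if self.filter == "none" else "bonferroni"


@dataclass
class ScreenReport:
    """Result of running one screening approach."""

    spec: ApproachSpec
    filtered_variants: pd.DataFrame
    lead_variants: pd.DataFrame
    M: int
    alpha_diff: float
    significant: pd.DataFrame
    r: float = 0.0
    r_stage2: float = 0.0


def _filter_pvalues(records: pd.DataFrame, filter: str, r: float = 0.0,
                    strat_bonferroni: bool = True):
    """Per-variant filter p-value (min over strata for the stratified filter)."""
    b1 = records["beta1"].to_numpy(float)
    s1 = records["se1"].to_numpy(float)
    b2 = records["beta2"].to_numpy(float)
    s2 = records["se2"].to_numpy(float)
    if filter == "overall":
        return z_overall(b1, s1, b2, s2).p_value, 1.0
    if filter == "joint":
        return c_joint(b1, s1, b2, s2).p_value, 1.0
    if filter == "strat":
        p1 = z_strat(b1, s1, 1).p_value
        p2 = z_strat(b2, s2, 2).p_value
        # Bonferroni across the two strata: either stratum may trigger at
        # alpha/2, i.e. compare min(p1, p2) against alpha_filter * scale
        scale = 0.5 if strat_bonferroni else 1.0
        return np.minimum(p1, p2), scale
    raise ValueError(f"unknown filter {filter!r}")


def apply_filter(records: pd.DataFrame, filter: str, alpha_filter: float,
                 r: float = 0.0, strat_filter_bonferroni: bool = True) -> pd.DataFrame:
    """Keep variants whose filter test p-value falls below the threshold.

    Returns a copy of the passing rows with a ``p_filter`` column added
    (for ``filter='none'`` all rows pass with p_filter = NaN).
    """
    if filter == "none":
        out = records.copy()
        out["p_filter"] = np.nan
        return out
    p, scale = _filter_pvalues(records, filter, r, strat_filter_bonferroni)
    out = records.loc[p < alpha_filter * scale].copy()
    out["p_filter"] = p[p < alpha_filter * scale]
    return out


def extract_leads(filtered: pd.DataFrame, window_bp: int = 500_000) -> pd.DataFrame:
    """Prune filtered variants to lead variants.

    Greedy: repeatedly take the remaining variant with the smallest filter
    p-value as a lead and remove all remaining variants on the same
    chromosome within +/- ``window_bp`` (inclusive).  Ties break on
    smaller p, then smaller position, then marker id.  Variants without
    chromosome/position are each their own lead.  The outcome does not
    depend on the input row order.
    """
    if filtered.empty:
        return filtered.copy()
    has_pos = (
        "chr" in filtered and "pos" in filtered
        and filtered["chr"].notna().all() and filtered["pos"].notna().all()
    )
    if not has_pos:
        return filtered.copy()

    marker = filtered["marker"].astype(str) if "marker" in filtered else filtered.index.astype(str)
    order_df = pd.DataFrame({
        "p": filtered["p_filter"].to_numpy(float),
        "pos": pd.to_numeric(filtered["pos"]).to_numpy(float),
        "chr": filtered["chr"].astype(str).to_numpy(),
        "marker": marker.to_numpy(),
        "_row": np.arange(len(filtered)),
    }).sort_values(["p", "pos", "marker"], kind="mergesort")

    lead_rows: list[int] = []
    removed = np.zeros(len(filtered), dtype=bool)
    pos = order_df["pos"].to_numpy()
    chrom = order_df["chr"].to_numpy()
    rows = order_df["_row"].to_numpy()
    for i in range(len(order_df)):
        ri = rows[i]
        if removed[ri]:
            continue
        lead_rows.append(ri)
        nearby = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        removed[rows[nearby]] = True
    return filtered.iloc[sorted(lead_rows)].copy()


def classify_gxs(beta1, se1, beta2, se2, nominal_alpha: float = 0.05) -> str:
    """Label the type of a significant between-strata difference.

    * ``qualitative`` — opposite directions, both strata nominally
      significant;
    * ``pure`` — the effect is nominally present in exactly one stratum
      (or one beta is exactly zero);
    * ``quantitative`` — same direction, both strata nominally
      significant (the difference test has already established that the
      magnitudes differ).
    """
    sig1 = z_strat(beta1, se1, 1).p_value < nominal_alpha
    sig2 = z_strat(beta2, se2, 2).p_value < nominal_alpha
    if beta1 == 0.0 or beta2 == 0.0:
        return "pure"
    if sig1 != sig2:
        return "pure"
    if not (sig1 and sig2):
        return "pure"
    return "qualitative" if np.sign(beta1) != np.sign(beta2) else "quantitative"


def run_approach(
    records_stage1: pd.DataFrame,
    records_stage2: pd.DataFrame | None,
    spec: ApproachSpec,
    r: float = 0.0,
    r_stage2: float | None = None,
) -> ScreenReport:
    """Run one screening approach end to end.

    One-stage: filter and difference test on ``records_stage1``.
    Two-stage: filter on stage 1, difference test on the stage-2 estimates
    of the stage-1 lead variants (matched by marker).  ``r`` (and
    ``r_stage2`` for two-stage) is the between-strata estimate correlation
    used by the corrected difference test.
    """
    if spec.layout == "two_stage" and records_stage2 is None:
        raise ValueError("two_stage layout requires stage-2 records")
    if r_stage2 is None:
        r_stage2 = r

    filtered = apply_filter(records_stage1, spec.filter, spec.alpha_filter, r,
                            spec.strat_filter_bonferroni)
    if spec.filter == "none":
        leads = filtered
        alpha_diff = GENOME_WIDE_ALPHA
        test_set, r_test = leads, r
    else:
        leads = extract_leads(filtered, spec.window_bp)
        M = len(leads)
        if M == 0:
            empty = leads.iloc[0:0]
            return ScreenReport(spec, filtered, leads, 0, np.nan, empty, r, r_stage2)
        alpha_diff = 0.05 / M
        if spec.layout == "two_stage":
            test_set = records_stage2[
                records_stage2["marker"].isin(set(leads["marker"]))
            ].copy()
            r_test = r_stage2
        else:
            test_set, r_test = leads, r

    res = z_diff(
        test_set["beta1"].to_numpy(float), test_set["se1"].to_numpy(float),
        test_set["beta2"].to_numpy(float), test_set["se2"].to_numpy(float),
        r=r_test,
    )
    test_set = test_set.copy()
    test_set["z_diff"] = res.statistic
    test_set["p_diff"] = res.p_value
    sig = test_set.loc[test_set["p_diff"] < alpha_diff].copy()
    if not sig.empty:
        sig["gxs_type"] = [
            classify_gxs(row.beta1, row.se1, row.beta2, row.se2)
            for row in sig.itertuples()
        ]
    else:
        sig["gxs_type"] = pd.Series(dtype=str)
    M = len(leads) if spec.filter != "none" else len(records_stage1)
    return ScreenReport(spec, filtered, leads, M, alpha_diff, sig, r, r_stage2)
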