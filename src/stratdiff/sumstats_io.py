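"""Reading, validating and harmonizing per-stratum GWAMA summary statistics.

Input files are tab- or whitespace-delimited text (gzip-transparent) with
METAL-style columns; column names are remappable.  Internally a stratum's
statistics live in a pandas DataFrame with canonical columns

    marker, chr, pos, effect_allele, other_allele, eaf, beta, se, n

and a harmonized two-strata table carries ``beta1/se1/eaf1/n1`` and
``beta2/se2/eaf2/n2`` side by side, both referring to the *same* effect
allele.  Harmonization flips the stratum-2 sign (and eaf -> 1-eaf) when its
alleles are recorded in the opposite orientation.  Strand-ambiguous
palindromic variants (A/T, C/G) are never silently strand-flipped; they
pass through with ``palindromic=True`` so the caller can decide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "StratumStats",
    "StratifiedVariantRecord",
    "SumstatsTable",
    "HarmonizedTable",
    "METAL_COLUMNS",
    "read_sumstats",
    "harmonize",
    "write_results",
]

#: default mapping from canonical names to METAL-style file headers
METAL_COLUMNS = {
    "marker": "MarkerName",
    "chr": "Chr",
    "pos": "Pos",
    "effect_allele": "Effect_allele",
    "other_allele": "Other_allele",
    "eaf": "EAF",
    "beta": "Beta",
    "se": "SE",
    "n": "N",
}

_REQUIRED = ("marker", "effect_allele", "other_allele", "beta", "se")
_CANONICAL_ORDER = [
    "marker", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "n",
]


@dataclass(frozen=True)
class VariantKey:
    marker_id: str
    chromosome: str
    position: int  # 1-based
    effect_allele: str
    other_allele: str

    def __post_init__(self):
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass(frozen=True)
class StratumStats:
    beta: float
    se: float
    n: int
    eaf: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("se must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError("eaf must lie strictly between 0 and 1")


@dataclass(frozen=True)
class StratifiedVariantRecord:
    key: VariantKey
    stratum1: StratumStats | None
    stratum2: StratumStats | None


@dataclass
class SumstatsTable:
    """One stratum's summary statistics plus QC bookkeeping."""

    data: pd.DataFrame
    n_dropped: int = 0

    def __len__(self):
        return len(self.data)


@dataclass
class HarmonizedTable:
    """Two strata joined on marker, alleles aligned to stratum 1."""

    data: pd.DataFrame
    n_allele_mismatch: int = 0
    n_unmatched: int = 0

    def __len__(self):
        return len(self.data)


def read_sumstats(path, column_map: dict | None = None) -> SumstatsTable:
    """Read one stratum's summary-statistics file.

    ``column_map`` maps canonical names (keys of :data:`METAL_COLUMNS`) to
    the file's header names; unmapped canonical names fall back to the
    METAL defaults.  Rows with non-numeric beta/se or se <= 0 are dropped
    and counted in ``n_dropped``; file order is preserved.  Missing mapped
    columns and empty files are hard errors.
    """
    cmap = dict(METAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty summary-statistics file: {path}") from None
    for canon in _REQUIRED:
        if cmap[canon] not in df.columns:
            raise ValueError(
                f"required column '{cmap[canon]}' (for '{canon}') not found in {path}"
            )
    out = pd.DataFrame(index=df.index)
    for canon in _CANONICAL_ORDER:
        col = cmap.get(canon)
        if col is not None and col in df.columns:
            out[canon] = df[col]
    if df.empty:
        raise ValueError(f"summary-statistics file has no data rows: {path}")

    for col in ("beta", "se", "eaf"):
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("pos", "n"):
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
    out["marker"] = out["marker"].astype(str)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper()
    if "chr" in out:
        out["chr"] = out["chr"].astype(str)

    ok = out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    n_dropped = int((~ok).sum())
    return SumstatsTable(data=out[ok].reset_index(drop=True), n_dropped=n_dropped)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    comp = oa.str.translate(_COMPLEMENT)
    return ea == comp


def harmonize(
    stratum1: SumstatsTable | pd.DataFrame,
    stratum2: SumstatsTable | pd.DataFrame,
    join_on: str = "marker",
) -> HarmonizedTable:
    """Inner-join two strata on marker and align stratum-2 to stratum-1 alleles.

    When stratum 2 reports the swapped allele pair its beta is negated and
    its eaf replaced by 1 - eaf.  Allele pairs matching neither orientation
    are dropped and counted.  ``join_on='chrpos'`` joins on chromosome and
    position instead of marker id.  Duplicate keys within either input are
    a hard error.
    """
    d1 = stratum1.data if isinstance(stratum1, SumstatsTable) else stratum1.copy()
    d2 = stratum2.data if isinstance(stratum2, SumstatsTable) else stratum2.copy()
    if join_on == "marker":
        keys = ["marker"]
    elif join_on == "chrpos":
        keys = ["chr", "pos"]
    else:
        raise ValueError("join_on must be 'marker' or 'chrpos'")
    for name, d in (("stratum 1", d1), ("stratum 2", d2)):
        dup = d[keys].duplicated()
        if dup.any():
            dups = d.loc[dup, keys[0]].astype(str).unique()[:10].tolist()
            raise ValueError(f"duplicate keys in {name} input: {dups}")

    merged = d1.merge(d2, on=keys, how="inner", suffixes=("1", "2"))
    n_unmatched = (len(d1) - len(merged)) + (len(d2) - len(merged))

    ea1, oa1 = merged["effect_allele1"], merged["other_allele1"]
    ea2, oa2 = merged["effect_allele2"], merged["other_allele2"]
    same = (ea1 == ea2) & (oa1 == oa2)
    swapped = (ea1 == oa2) & (oa1 == ea2)
    keep = same | swapped
    n_mismatch = int((~keep).sum())
    merged = merged[keep].copy()
    swapped = swapped[keep]

    merged.loc[swapped, "beta2"] = -merged.loc[swapped, "beta2"]
    if "eaf2" in merged:
        merged.loc[swapped, "eaf2"] = 1.0 - merged.loc[swapped, "eaf2"]

    out = pd.DataFrame()
    out["marker"] = merged["marker1"] if "marker1" in merged else merged["marker"]
    for col in ("chr", "pos"):
        for cand in (col, f"{col}1"):
            if cand in merged:
                out[col] = merged[cand]
                break
    out["effect_allele"] = merged["effect_allele1"]
    out["other_allele"] = merged["other_allele1"]
    for i in "12":
        for col in ("beta", "se", "eaf", "n"):
            src = f"{col}{i}"
            if src in merged:
                out[src] = merged[src]
    out["palindromic"] = _is_palindromic(out["effect_allele"], out["other_allele"])
    return HarmonizedTable(
        data=out.reset_index(drop=True),
        n_allele_mismatch=n_mismatch,
        n_unmatched=int(n_unmatched),
    )


def write_results(report: pd.DataFrame, path) -> None:
    """Write a results table as tab-delimited text with 'NA' for missing.

    Column order follows the input frame and is preserved on round-trip;
    floats are written with 17 significant digits so a read-back reproduces
    values to full double precision.
    """
    try:
        report.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
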