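"""Reading, writing, validation and allele harmonization of GWAS summary statistics.

A summary-statistic table holds one association per SNP: the estimated
per-allele effect (``beta``), its standard error, the effect/other allele
pair the sign refers to, the effect-allele frequency, and a two-sided
p-value. Tables carry an effect-scale label (``linear``, ``log-odds`` or
``SMD``) in their metadata so that downstream arithmetic on betas can refuse
to mix incompatible units.

Harmonization (:func:`align_tables`) intersects two tables on SNP id and
re-expresses the second table's effects for the first table's effect allele,
flipping signs and frequencies where the allele labels are swapped and
resolving or dropping strand-ambiguous (A/T, C/G) palindromic variants via
allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order used on disk and in memory
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: columns that must be present (or mapped) in any input file
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: recognised effect-scale labels
VALID_SCALES = ("linear", "log-odds", "SMD")

_BASES = frozenset("ACGT")
_PALINDROMES = (frozenset("AT"), frozenset("CG"))

# smallest positive double: p-values are clipped here so p stays in (0, 1]
_TINY_P = 5e-324


def recompute_pvalue(beta, se):
    """Two-sided normal p-value from an effect estimate and its SE.

    ``p = 2 * (1 - Phi(|beta/se|))``, clipped into ``(0, 1]``. Accepts
    scalars or arrays; raises ``ValueError`` if any ``se <= 0``.
    """
    beta_arr = np.asarray(beta, dtype=float)
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise ValueError("standard errors must be strictly positive")
    p = 2.0 * stats.norm.sf(np.abs(beta_arr / se_arr))
    p = np.clip(p, _TINY_P, 1.0)
    if np.isscalar(beta) and np.isscalar(se):
        return float(p)
    return p


@dataclass
class SumstatTable:
    """A validated GWAS summary-statistic table plus effect-scale metadata.

    Parameters
    ----------
    df
        One row per SNP with (at least) the canonical columns.
    scale
        Effect-size scale label: ``linear``, ``log-odds`` or ``SMD``.
    trait
        Free-text phenotype label.
    n_case, n_total
        Case/total counts for binary traits analysed with a linear model;
        consumed by :func:`gwsub.scaling.linear_to_logodds`.
    """

    df: pd.DataFrame
    scale: str = "linear"
    trait: str | None = None
    n_case: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(
                f"unknown effect scale {self.scale!r}; expected one of {VALID_SCALES}"
            )
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame, **meta) -> "SumstatTable":
        """Copy of this table with a new frame and optionally new metadata."""
        return replace(self, df=df.reset_index(drop=True), **meta)


def _coerce_numeric(df: pd.DataFrame, col: str) -> int:
    """Coerce a column to float in place; return the number of newly-NaN cells."""
    before = df[col].isna().sum()
    df[col] = pd.to_numeric(df[col], errors="coerce")
    return int(df[col].isna().sum() - before)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Enforce per-record invariants, dropping offending rows.

    Returns the clean frame (canonical columns, canonical dtypes) and a
    ``{reason: count}`` tally of dropped rows. Hard-errors only if a
    mandatory column is absent entirely.
    """
    df = df.copy()
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} is missing")
    for col in ("chrom", "pos", "eaf", "pvalue", "n"):
        if col not in df.columns:
            df[col] = np.nan

    drops: dict[str, int] = {}
    n_unparseable = 0
    for col in ("beta", "se", "eaf", "pvalue", "n"):
        n_unparseable += _coerce_numeric(df, col)
    if n_unparseable:
        drops["unparseable_numeric"] = n_unparseable

    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype("string")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
            df = df[~mask]

    _drop(~(np.isfinite(df["beta"]) & np.isfinite(df["se"])), "missing_beta_se")
    _drop(df["se"] <= 0, "nonpositive_se")
    _drop(
        ~(
            df["effect_allele"].isin(_BASES)
            & df["other_allele"].isin(_BASES)
        ),
        "non_single_base_allele",
    )
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")
    _drop((df["eaf"] < 0) | (df["eaf"] > 1), "eaf_out_of_range")
    _drop((df["pvalue"] <= 0) | (df["pvalue"] > 1), "pvalue_out_of_range")
    _drop(df["snp_id"].duplicated(keep=False), "duplicate_snp_id")

    missing_p = df["pvalue"].isna()
    if missing_p.any():
        df.loc[missing_p, "pvalue"] = recompute_pvalue(
            df.loc[missing_p, "beta"].to_numpy(),
            df.loc[missing_p, "se"].to_numpy(),
        )

    if drops:
        logger.warning("validate_records dropped rows: %s", drops)
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    return df[CANONICAL_COLUMNS + extra].reset_index(drop=True), drops


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    scale: str = "linear",
    sep: str = "\t",
    trait: str | None = None,
) -> SumstatTable:
    """Read a delimited summary-statistic file into a validated table.

    ``column_map`` maps source headers to canonical names (e.g. ``{"BETA":
    "beta"}``); headers that already match a canonical name case-insensitively
    are accepted without a map. Rows violating record invariants are dropped
    with a logged tally; a missing mandatory column is a hard error.
    """
    raw = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype=str)
    rename = {}
    cmap = {k: v for k, v in (column_map or {}).items()}
    lower_canon = {c.lower(): c for c in CANONICAL_COLUMNS}
    for col in raw.columns:
        if col in cmap:
            rename[col] = cmap[col]
        elif col.lower() in lower_canon:
            rename[col] = lower_canon[col.lower()]
    raw = raw.rename(columns=rename)
    clean, _ = validate_records(raw)
    return SumstatTable(clean, scale=scale, trait=trait)


def write_sumstats(table: SumstatTable, path: str | Path) -> Path:
    """Write a table as tab-separated text with ``NA`` for missing values.

    Floats are serialized with shortest round-tripping repr, so
    ``read_sumstats(write_sumstats(t))`` reproduces every field exactly.
    """
    path = Path(path)
    table.df[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return ((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A")) | (
        (ea == "C") & (oa == "G")
    ) | ((ea == "G") & (oa == "C"))


def align_tables(
    ref: SumstatTable,
    other: SumstatTable,
    palindrome_policy: str = "infer",
    ambiguity_band: float = 0.30,
) -> pd.DataFrame:
    """Harmonize ``other`` onto ``ref``'s effect alleles.

    Returns one row per SNP retained, with ``beta_a/se_a/eaf_a`` from ``ref``
    and ``beta_b/se_b/eaf_b`` from ``other`` re-expressed for ``ref``'s
    effect allele. Where ``other`` lists the alleles swapped, ``beta_b`` is
    sign-flipped and ``eaf_b`` replaced by ``1 - eaf_b``.

    Palindromic (A/T, C/G) SNPs cannot be strand-resolved from allele labels:
    with ``palindrome_policy="drop"`` they are removed; with ``"infer"`` they
    are kept only when both allele frequencies lie outside the ambiguity band
    ``(band, 1 - band)`` and fall on the same side of 0.5 — otherwise dropped
    (including when either frequency is missing).

    The result's ``attrs`` carry both scale labels; a warning is logged when
    they differ. Raises ``ValueError`` on an empty intersection or when every
    SNP is dropped.
    """
    if palindrome_policy not in ("infer", "drop"):
        raise ValueError("palindrome_policy must be 'infer' or 'drop'")
    if not 0 < ambiguity_band < 0.5:
        raise ValueError("ambiguity_band must lie in (0, 0.5)")
    if ref.scale != other.scale:
        logger.warning(
            "aligning tables on different effect scales: %s vs %s",
            ref.scale,
            other.scale,
        )

    a = ref.df[CANONICAL_COLUMNS]
    b = other.df[
        ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]
    ]
    merged = a.merge(b, on="snp_id", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise ValueError("no SNPs shared between the two tables")

    drops: dict[str, int] = {}
    same = (merged["effect_allele_a"] == merged["effect_allele_b"]) & (
        merged["other_allele_a"] == merged["other_allele_b"]
    )
    swapped = (merged["effect_allele_a"] == merged["other_allele_b"]) & (
        merged["other_allele_a"] == merged["effect_allele_b"]
    )
    mismatch = ~(same | swapped)
    if mismatch.any():
        drops["mismatch"] = int(mismatch.sum())
        logger.warning(
            "dropping %d SNPs with incompatible alleles", drops["mismatch"]
        )
    merged = merged[~mismatch]
    swapped = swapped[~mismatch]

    merged = merged.assign(swapped=swapped.to_numpy())
    flip = merged["swapped"].to_numpy()
    merged.loc[flip, "beta_b"] = -merged.loc[flip, "beta_b"]
    merged.loc[flip, "eaf_b"] = 1.0 - merged.loc[flip, "eaf_b"]

    pal = _is_palindromic(merged["effect_allele_a"], merged["other_allele_a"])
    merged = merged.assign(palindromic=pal.to_numpy(), inferred=False)
    if pal.any():
        if palindrome_policy == "drop":
            drops["palindrome"] = int(pal.sum())
            merged = merged[~merged["palindromic"]]
        else:
            eaf_a = merged["eaf_a"]
            eaf_b = merged["eaf_b"]
            missing = merged["palindromic"] & (eaf_a.isna() | eaf_b.isna())
            lo, hi = ambiguity_band, 1.0 - ambiguity_band
            outside = ((eaf_a <= lo) | (eaf_a >= hi)) & (
                (eaf_b <= lo) | (eaf_b >= hi)
            )
            same_side = (eaf_a < 0.5) == (eaf_b < 0.5)
            keep = merged["palindromic"] & ~missing & outside & same_side
            drop_pal = merged["palindromic"] & ~keep & ~missing
            if missing.any():
                drops["missing"] = int(missing.sum())
            if drop_pal.any():
                drops["palindrome"] = int(drop_pal.sum())
            merged.loc[keep, "inferred"] = True
            merged = merged[~merged["palindromic"] | keep]

    if drops:
        logger.warning("align_tables dropped SNPs: %s", drops)
    if merged.empty:
        raise ValueError("no SNPs left after harmonization")

    out = merged.rename(
        columns={
            "effect_allele_a": "effect_allele",
            "other_allele_a": "other_allele",
        }
    )[
        [
            "snp_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "eaf_a",
            "beta_a",
            "se_a",
            "n_a",
            "eaf_b",
            "beta_b",
            "se_b",
            "n_b",
            "swapped",
            "palindromic",
            "inferred",
        ]
    ].reset_index(drop=True)
    out.attrs["scale_a"] = ref.scale
    out.attrs["scale_b"] = other.scale
    return out
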