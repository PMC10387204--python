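"""Two-sample Mendelian-randomization validation of a derived GWAS.

The validation protocol mirrors standard two-sample MR practice: select
instruments from the exposure GWAS at a p-value threshold, correct their
effect sizes for winner's curse (FIQT), prune them to approximate linkage
independence (greedy clumping against an LD source), harmonize with the
outcome GWAS, and combine the per-SNP Wald ratios with an inverse-variance
weighted meta-analysis under multiplicative random effects. Instrument
strength is summarised by the mean F statistic, ``mean((beta/se)^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import SumstatTable, align_tables, recompute_pvalue

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (5e-6, 5e-7, 5e-8)
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000.0


class LDSource:
    """Pairwise r-squared lookup between SNPs.

    Subclasses implement ``__contains__`` (is this SNP known to the source?)
    and :meth:`r2`. SNPs unknown to the source are handled by the clumping
    missing-SNP policy.
    """

    def __contains__(self, snp_id: str) -> bool:  # pragma: no cover - interface
        raise NotImplementedError

    def r2(self, snp_a: str, snp_b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class PanelLD(LDSource):
    """LD from a reference genotype panel.

    ``genotypes`` is a samples-by-SNPs frame of allele counts; r-squared is
    the squared Pearson correlation of the two columns.
    """

    def __init__(self, genotypes: pd.DataFrame):
        self._geno = genotypes
        self._sd = genotypes.std(ddof=0)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._geno.columns

    def r2(self, snp_a: str, snp_b: str) -> float:
        if self._sd[snp_a] == 0 or self._sd[snp_b] == 0:
            return 0.0
        r = np.corrcoef(self._geno[snp_a], self._geno[snp_b])[0, 1]
        return float(r * r)


class TableLD(LDSource):
    """LD from a precomputed long-format table (snp_a, snp_b, r2).

    Pairs absent from the table (but whose SNPs are listed) are taken as
    r2 = 0.
    """

    def __init__(self, pairs: pd.DataFrame):
        for col in ("snp_a", "snp_b", "r2"):
            if col not in pairs.columns:
                raise ValueError(f"LD table is missing column {col!r}")
        self._r2 = {}
        for a, b, r2 in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            key = (a, b) if a <= b else (b, a)
            self._r2[key] = float(r2)
        self._snps = set(pairs["snp_a"]) | set(pairs["snp_b"])

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "TableLD":
        return cls(pd.read_csv(path, sep=sep))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._snps

    def r2(self, snp_a: str, snp_b: str) -> float:
        key = (snp_a, snp_b) if snp_a <= snp_b else (snp_b, snp_a)
        return self._r2.get(key, 0.0)


def select_instruments(table: SumstatTable, p_threshold: float) -> SumstatTable:
    """Subset to SNPs with p below the threshold, preserving order."""
    keep = table.df["pvalue"] < p_threshold
    if not keep.any():
        raise ValueError(f"no SNPs pass the p < {p_threshold:g} threshold")
    return table.with_df(table.df[keep])


def fiqt_adjust(table: SumstatTable) -> SumstatTable:
    """Winner's-curse correction by FDR inverse quantile transformation.

    Each SNP's z-score is replaced by the normal quantile of its
    Benjamini-Hochberg-adjusted two-sided p-value::

        p      = 2 * (1 - Phi(|z|))
        p_adj  = BH(p)  over all m SNPs in the table
        z_adj  = sign(z) * InvPhi(1 - p_adj / 2)
        beta'  = z_adj * se        (se unchanged)

    Because ``p_adj >= p``, the adjustment only ever shrinks |z| and
    preserves its rank order. Apply genome-wide, before instrument
    selection, so the multiplicity ``m`` reflects the full scan. The
    ``pvalue`` column keeps the unadjusted p (used for thresholding); the
    BH-adjusted p is exposed as ``p_fdr``.
    """
    if len(table) == 0:
        raise ValueError("cannot FIQT-adjust an empty table")
    df = table.df.copy()
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    p = recompute_pvalue(df["beta"].to_numpy(float), df["se"].to_numpy(float))
    p_adj = multipletests(p, method="fdr_bh")[1]
    z_adj = np.sign(z) * stats.norm.isf(np.minimum(p_adj, 1.0) / 2.0)
    df["beta"] = z_adj * df["se"].to_numpy(float)
    df["pvalue"] = p
    df["p_fdr"] = p_adj
    return table.with_df(df)


def clump(
    table: SumstatTable,
    ld: LDSource,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
    missing_policy: str = "permissive",
) -> SumstatTable:
    """Greedy LD clumping: keep index SNPs, remove their correlated neighbours.

    Repeatedly takes the remaining SNP with the smallest p-value (ties broken
    by chromosome, position, then SNP id) as an index SNP and removes every
    remaining SNP on the same chromosome within ``window_kb`` whose r-squared
    with the index exceeds ``r2_threshold``.

    SNPs unknown to the LD source are treated as independent with a warning
    (``missing_policy="permissive"``); with ``"strict"`` any unknown SNP is a
    hard error.
    """
    if missing_policy not in ("permissive", "strict"):
        raise ValueError("missing_policy must be 'permissive' or 'strict'")
    df = table.df
    if df.empty:
        raise ValueError("cannot clump an empty table")
    if df["chrom"].isna().any() or df["pos"].isna().any():
        raise ValueError("clumping requires chrom and pos for every SNP")

    missing = [s for s in df["snp_id"] if s not in ld]
    if missing:
        if missing_policy == "strict":
            raise ValueError(
                f"{len(missing)} SNPs absent from the LD source (strict policy)"
            )
        logger.warning(
            "%d SNPs absent from the LD source; treated as independent",
            len(missing),
        )
    known = set(df["snp_id"]) - set(missing)

    order = df.sort_values(
        ["pvalue", "chrom", "pos", "snp_id"], kind="mergesort"
    )
    window_bp = window_kb * 1000.0
    alive = dict.fromkeys(order["snp_id"], True)
    rows = list(order[["snp_id", "chrom", "pos"]].itertuples(index=False))
    kept: list[str] = []
    for idx_snp, idx_chrom, idx_pos in rows:
        if not alive[idx_snp]:
            continue
        kept.append(idx_snp)
        alive[idx_snp] = False
        for snp, chrom, pos in rows:
            if not alive[snp] or chrom != idx_chrom:
                continue
            if abs(float(pos) - float(idx_pos)) > window_bp:
                continue
            if idx_snp in known and snp in known and ld.r2(idx_snp, snp) > r2_threshold:
                alive[snp] = False
    kept_set = set(kept)
    return table.with_df(df[df["snp_id"].isin(kept_set)])


@dataclass
class MRResult:
    """IVW multiplicative-random-effects estimate and diagnostics."""

    beta: float
    se: float
    pvalue: float
    n_snps: int
    q: float
    sigma: float
    mean_f: float | None = None
    threshold: float | None = None


def ivw_mre(pairs: pd.DataFrame) -> MRResult:
    """Inverse-variance weighted MR with multiplicative random effects.

    ``pairs`` is a harmonized frame with exposure effects in ``beta_a`` and
    outcome effects/SEs in ``beta_b``/``se_b``. The estimate is the weighted
    least-squares slope of outcome on exposure betas through the origin with
    weights ``1/se_b^2``::

        beta  = sum(w bx by) / sum(w bx^2)
        Q     = sum(w (by - beta bx)^2)
        sigma^2 = max(1, Q/(k-1))     (fixed at 1 when k = 1)
        se    = sigma * sqrt(1 / sum(w bx^2))

    The residual scale is floored at 1, so overdispersion inflates the SE but
    underdispersion earns no credit; with the floor active the estimate
    coincides with fixed-effect IVW. With a single SNP this reduces exactly
    to the Wald ratio ``by/bx`` with SE ``se_b/|bx|``.
    """
    if len(pairs) == 0:
        raise ValueError("no instruments supplied to ivw_mre")
    bx = pairs["beta_a"].to_numpy(float)
    by = pairs["beta_b"].to_numpy(float)
    sey = pairs["se_b"].to_numpy(float)
    if np.any(sey <= 0):
        raise ValueError("outcome standard errors must be positive")
    k = len(bx)
    if k == 1 and bx[0] == 0:
        raise ValueError("single instrument with zero exposure effect")
    w = 1.0 / sey**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - beta * bx) ** 2))
    sigma = 1.0 if k == 1 else float(np.sqrt(max(1.0, q / (k - 1))))
    se = sigma * float(np.sqrt(1.0 / denom))
    return MRResult(
        beta=beta,
        se=se,
        pvalue=recompute_pvalue(beta, se),
        n_snps=k,
        q=q,
        sigma=sigma,
    )


def mean_f(table: SumstatTable | pd.DataFrame) -> float:
    """Mean instrument F statistic, ``mean((beta/se)^2)``."""
    df = table.df if isinstance(table, SumstatTable) else table
    if len(df) == 0:
        raise ValueError("cannot compute mean F of an empty instrument set")
    z = df["beta"].to_numpy(float) / df["se"].to_numpy(float)
    return float(np.mean(z**2))


def run_mr(
    exposure: SumstatTable,
    outcome: SumstatTable,
    ld: LDSource,
    thresholds=DEFAULT_THRESHOLDS,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_kb: float = DEFAULT_CLUMP_KB,
    band: float = 0.30,
    palindrome_policy: str = "infer",
    apply_fiqt: bool = True,
    select_on_adjusted: bool = False,
) -> tuple[dict[float, MRResult], dict[float, str]]:
    """Full MR validation pipeline, one analysis per p-value threshold.

    Pipeline: FIQT-adjust the exposure genome-wide, select instruments at
    each threshold (on unadjusted p by default; ``select_on_adjusted``
    switches to the FDR-adjusted p), clump, harmonize with the outcome, and
    run :func:`ivw_mre`. Mean F is computed on the instruments actually
    carried into the estimate (FIQT-adjusted betas, post-clumping and
    harmonization).

    Returns ``(results, failures)``; a threshold whose stage errors out is
    reported in ``failures`` while the others still run.
    """
    exp = fiqt_adjust(exposure) if apply_fiqt else exposure
    if select_on_adjusted and apply_fiqt:
        exp = exp.with_df(exp.df.assign(pvalue=exp.df["p_fdr"]))
    results: dict[float, MRResult] = {}
    failures: dict[float, str] = {}
    for thr in thresholds:
        try:
            sel = select_instruments(exp, thr)
            sel = clump(sel, ld, r2_threshold=clump_r2, window_kb=clump_kb)
            pairs = align_tables(
                sel, outcome, palindrome_policy=palindrome_policy, ambiguity_band=band
            )
            res = ivw_mre(pairs)
            res.mean_f = mean_f(
                pd.DataFrame({"beta": pairs["beta_a"], "se": pairs["se_a"]})
            )
            res.threshold = thr
            results[thr] = res
        except ValueError as exc:
            logger.warning("MR at threshold %g failed: %s", thr, exc)
            failures[thr] = str(exc)
    return results, failures


def mr_results_table(results: dict[float, MRResult]) -> pd.DataFrame:
    """Tidy frame of per-threshold MR results (for reporting / CLI output)."""
    rows = [
        {
            "threshold": thr,
            "n_snps": r.n_snps,
            "mean_f": r.mean_f,
            "beta": r.beta,
            "se": r.se,
            "pvalue": r.pvalue,
            "q": r.q,
            "sigma": r.sigma,
        }
        for thr, r in sorted(results.items(), reverse=True)
    ]
    return pd.DataFrame(rows)
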