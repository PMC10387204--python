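"""The GWAS-by-subtraction weighted linear model and QC of the derived GWAS.

A child's per-allele genetic effect is the average of the parental effects,
and a child's genotype correlates 0.5 with each parent's genotype. Writing
``b_CG_CP`` for the association of the child's genotype with the child's own
phenotype, ``b_CG_MP`` with the maternal phenotype and ``b_CG_FP`` with the
paternal phenotype, those two facts combine into the weighted linear model

    b_CG_FP = b_CG_CP - b_CG_MP

with, by propagation of error for independent estimates,

    se(b_CG_FP) = sqrt(se(b_CG_CP)^2 + se(b_CG_MP)^2).

:func:`subtract_gwas` applies this per SNP to a harmonized pair of GWASs on
a common (SMD) scale; :func:`genomic_inflation` and :func:`qq_manhattan`
provide the standard inflation-factor and plot diagnostics of the derived
summary statistics.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import CANONICAL_COLUMNS, SumstatTable, recompute_pvalue

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

#: conventional genome-wide significance threshold used in the Manhattan plot
GENOME_WIDE_P = 5e-8


def subtract_gwas(
    pairs: pd.DataFrame,
    require_smd: bool = True,
    trait: str | None = None,
) -> SumstatTable:
    """Derive the paternal-phenotype GWAS from aligned child/maternal effects.

    ``pairs`` is the output of :func:`gwsub.sumstats.align_tables` with the
    child (index-person) GWAS as the reference (``_a``) side and the maternal
    GWAS as the ``_b`` side, both on the SMD scale. Per SNP::

        beta = beta_a - beta_b
        se   = sqrt(se_a**2 + se_b**2)
        p    = 2 * (1 - Phi(|beta/se|))

    Alleles and allele frequency are carried from the child table (the
    genotype the derived effect refers to); the headline sample size is
    ``min(n_a, n_b)`` with both inputs kept in ``n_child``/``n_maternal``.
    SNPs with non-finite derived values are dropped with a logged count.
    """
    if pairs.empty:
        raise ValueError("no harmonized SNPs to subtract")
    scales = (pairs.attrs.get("scale_a"), pairs.attrs.get("scale_b"))
    if require_smd and scales != ("SMD", "SMD"):
        raise ValueError(
            f"subtraction requires both inputs on the SMD scale, got {scales}; "
            "rescale first or pass require_smd=False"
        )

    beta = pairs["beta_a"].to_numpy(float) - pairs["beta_b"].to_numpy(float)
    se = np.sqrt(
        pairs["se_a"].to_numpy(float) ** 2 + pairs["se_b"].to_numpy(float) ** 2
    )
    ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    if not ok.all():
        logger.warning(
            "dropping %d SNPs with non-finite derived values", int((~ok).sum())
        )
    kept = pairs[ok]
    beta, se = beta[ok], se[ok]
    if len(kept) == 0:
        raise ValueError("all derived records were non-finite")

    df = pd.DataFrame(
        {
            "snp_id": kept["snp_id"].to_numpy(),
            "chrom": kept["chrom"].to_numpy(),
            "pos": kept["pos"].to_numpy(),
            "effect_allele": kept["effect_allele"].to_numpy(),
            "other_allele": kept["other_allele"].to_numpy(),
            "eaf": kept["eaf_a"].to_numpy(float),
            "beta": beta,
            "se": se,
            "pvalue": recompute_pvalue(beta, se),
            "n": np.fmin(
                kept["n_a"].to_numpy(float), kept["n_b"].to_numpy(float)
            ),
            "n_child": kept["n_a"].to_numpy(float),
            "n_maternal": kept["n_b"].to_numpy(float),
        }
    )
    return SumstatTable(df, scale="SMD", trait=trait)


def genomic_inflation(table: SumstatTable) -> float:
    """Genomic-control inflation factor: median z^2 over the chi2(1) median.

    Values near 1 indicate test statistics consistent with the null for the
    bulk of SNPs; values above ~1.05 suggest residual confounding or
    polygenicity.
    """
    if len(table) == 0:
        raise ValueError("cannot compute lambda_GC on an empty table")
    z = table.df["beta"].to_numpy(float) / table.df["se"].to_numpy(float)
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except (TypeError, ValueError):
        return (10**6, str(chrom))


def qq_manhattan(table: SumstatTable, out_prefix: str | Path) -> dict[str, Path]:
    """Write QQ and Manhattan plots for a summary-statistic table.

    Returns a mapping of plot kind to written path. The Manhattan plot needs
    chromosome/position; if they are missing it is skipped with a warning and
    the QQ plot is still produced.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValueError("cannot plot an empty table")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    p = np.clip(table.df["pvalue"].to_numpy(float), 5e-324, 1.0)
    obs = -np.log10(np.sort(p))
    m = len(p)
    exp = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(exp, obs, ".", ms=3, color="#1f77b4")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], "-", color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title("QQ plot")
    qq_path = out_prefix.with_name(out_prefix.name + "_qq.png")
    fig.savefig(qq_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written["qq"] = qq_path

    has_pos = table.df["chrom"].notna() & table.df["pos"].notna()
    if not has_pos.any():
        logger.warning("chrom/pos missing: Manhattan plot skipped")
        return written

    df = table.df[has_pos].copy()
    df["_key"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_key", "pos"])
    fig, ax = plt.subplots(figsize=(9, 4))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(df.groupby("_key", sort=True)):
        x = grp["pos"].to_numpy(float) + offset
        y = -np.log10(np.clip(grp["pvalue"].to_numpy(float), 5e-324, 1.0))
        ax.plot(x, y, ".", ms=3, color=("#1f77b4", "#ff7f0e")[i % 2])
        ticks.append(x.mean())
        labels.append(str(grp["chrom"].iloc[0]))
        offset = x.max() + 1
    ax.axhline(-np.log10(GENOME_WIDE_P), color="red", lw=1, ls="--")
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("$-\\log_{10} p$")
    ax.set_title("Manhattan plot")
    man_path = out_prefix.with_name(out_prefix.name + "_manhattan.png")
    fig.savefig(man_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written["manhattan"] = man_path
    return written
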