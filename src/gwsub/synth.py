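"""Synthetic trio-structured GWAS data for exercising the whole pipeline.

Generates individual-level genotypes for child/mother/father trios under
Mendelian transmission (the child's genotype is the sum of one transmitted
haplotype from each parent; each parent additionally carries an independent
non-transmitted haplotype), additive phenotypes with per-SNP weights and
Gaussian noise, an optional binary paternal outcome causally downstream of
the paternal phenotype, per-SNP association scans, and a self-contained
benchmark bundle (child GWAS, maternal GWAS, outcome GWAS, LD table, truth
file) written as plain TSV.

Linkage disequilibrium is optional: adjacent SNPs within a block copy the
block-head allele with a given probability on each haplotype, producing a
head-member genotype correlation equal to the copy probability. Allele
frequency is held constant within a block so that the marginal (LD-leaked)
per-SNP effects have a simple closed form, recorded in the truth file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sumstats import SumstatTable, recompute_pvalue

logger = logging.getLogger(__name__)

_DEFAULT_SPACING_BP = 10_000
_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class TrioGenomes:
    """Allele-count matrices (individuals x SNPs) for child, mother, father."""

    child: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    snps: pd.DataFrame  # snp_id, chrom, pos, effect_allele, other_allele, maf
    maf: np.ndarray
    block_size: int
    block_r: np.ndarray | float

    @property
    def n(self) -> int:
        return self.child.shape[0]

    @property
    def m_snps(self) -> int:
        return self.child.shape[1]


def _block_heads(m: int, block_size: int) -> np.ndarray:
    return (np.arange(m) // block_size) * block_size


def _draw_haplotype(
    rng: np.random.Generator,
    n: int,
    maf: np.ndarray,
    block_size: int,
    block_r: np.ndarray | float,
) -> np.ndarray:
    """One haplotype matrix (n x m, 0/1), with optional within-block copying.

    Bernoulli draws threshold 16-bit uniform integers against
    ``floor(p * 2**16)``, so realised frequencies are exact to within
    2**-16 of the requested ones; this keeps the random-bit budget at one
    16-bit draw per allele. A member of a block with copy probability ``r``
    (``block_r`` may vary per block) copies its head allele with probability
    ``r`` and is otherwise a fresh Bernoulli(maf) draw, implemented as a
    single threshold that depends on the head allele:
    ``P(1 | head=1) = r + (1-r) maf`` and ``P(1 | head=0) = (1-r) maf``.
    """
    m = len(maf)
    maf = np.asarray(maf, float)
    if block_size <= 1 or np.all(np.asarray(block_r) == 0):
        thresh = np.floor(maf * 65536.0).astype(np.uint16)
        return (
            rng.integers(0, 65536, (n, m), dtype=np.uint16) < thresh
        ).astype(np.int8)

    nb = -(-m // block_size)  # ceil: pad a partial trailing block
    m_pad = nb * block_size
    maf_pad = np.concatenate([maf, np.full(m_pad - m, 0.5)])
    r_block = np.broadcast_to(np.asarray(block_r, float), (nb,))
    head_maf = maf_pad[0::block_size]
    t_head = np.floor(head_maf * 65536.0).astype(np.uint16)
    out = np.empty((n, m_pad), dtype=np.int8)
    head = rng.integers(0, 65536, (n, nb), dtype=np.uint16) < t_head
    out[:, 0::block_size] = head
    for off in range(1, block_size):
        p0 = (1.0 - r_block) * maf_pad[off::block_size]
        t0 = np.floor(p0 * 65536.0).astype(np.uint16)
        t1 = np.floor((r_block + p0) * 65536.0).clip(max=65535).astype(np.uint16)
        thresh = np.where(head, t1, t0)
        out[:, off::block_size] = (
            rng.integers(0, 65536, (n, nb), dtype=np.uint16) < thresh
        )
    return out[:, :m]


def _snp_frame(
    rng: np.random.Generator,
    maf: np.ndarray,
    snps_per_chrom: int,
    spacing_bp: int,
    palindrome_fraction: float,
) -> pd.DataFrame:
    m = len(maf)
    idx = np.arange(m)
    is_pal = rng.random(m) < palindrome_fraction
    pal = np.array(_PALINDROMIC_PAIRS)[rng.integers(len(_PALINDROMIC_PAIRS), size=m)]
    nonpal = np.array(_NONPALINDROMIC_PAIRS)[
        rng.integers(len(_NONPALINDROMIC_PAIRS), size=m)
    ]
    pairs = np.where(is_pal[:, None], pal, nonpal)
    return pd.DataFrame(
        {
            "snp_id": np.char.add("snp", np.char.zfill((idx + 1).astype(str), 6)),
            "chrom": (1 + idx // snps_per_chrom).astype(str),
            "pos": (idx % snps_per_chrom + 1) * spacing_bp,
            "effect_allele": pairs[:, 0],
            "other_allele": pairs[:, 1],
            "maf": maf,
        }
    )


def generate_trio_genomes(
    m_snps: int,
    n: int,
    maf_spec=None,
    seed: int = 0,
    block_size: int = 1,
    block_r: np.ndarray | float = 0.0,
    snps_per_chrom: int | None = None,
    spacing_bp: int = _DEFAULT_SPACING_BP,
    palindrome_fraction: float = 0.05,
) -> TrioGenomes:
    """Simulate trio genotypes at ``m_snps`` independent (or block-LD) loci.

    ``maf_spec`` is a scalar, a per-SNP array, or ``None`` to draw
    frequencies uniformly from [0.05, 0.5]. With ``block_size > 1`` and
    ``block_r > 0``, SNPs within a block share the head SNP's frequency and
    each haplotype copies the head allele with probability ``block_r``
    (head-member genotype correlation ``block_r``, member-member
    ``block_r**2``); ``block_r`` may be a scalar or a per-block array
    (length ``ceil(m_snps / block_size)``), so LD can be confined to chosen
    regions while the rest of the genome stays independent. SNPs are laid
    out at fixed spacing on synthetic chromosomes. Deterministic given
    ``seed``.
    """
    if m_snps < 1 or n < 1:
        raise ValueError("m_snps and n must be >= 1")
    block_r = np.asarray(block_r, float) if np.ndim(block_r) else float(block_r)
    if np.any(np.asarray(block_r) < 0) or np.any(np.asarray(block_r) >= 1):
        raise ValueError("block_r must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if maf_spec is None:
        maf = rng.uniform(0.05, 0.5, m_snps)
    else:
        maf = np.broadcast_to(np.asarray(maf_spec, float), (m_snps,)).copy()
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if block_size > 1:
        maf = maf[_block_heads(m_snps, block_size)]  # constant within block
    if snps_per_chrom is None:
        snps_per_chrom = -(-m_snps // 22)  # spread over at most 22 chromosomes

    f_t = _draw_haplotype(rng, n, maf, block_size, block_r)
    m_t = _draw_haplotype(rng, n, maf, block_size, block_r)
    f_nt = _draw_haplotype(rng, n, maf, block_size, block_r)
    m_nt = _draw_haplotype(rng, n, maf, block_size, block_r)
    child = f_t + m_t
    mother = m_t + m_nt
    father = f_t + f_nt
    snps = _snp_frame(rng, maf, snps_per_chrom, spacing_bp, palindrome_fraction)
    return TrioGenomes(child, mother, father, snps, maf, block_size, block_r)


@dataclass
class Phenotypes:
    """Continuous phenotypes for the trio, plus an optional binary outcome."""

    c_p: np.ndarray
    m_p: np.ndarray
    f_p: np.ndarray
    outcome: np.ndarray | None = None


def generate_phenotypes(
    genomes: TrioGenomes,
    w_child: np.ndarray,
    w_parental: np.ndarray | None = None,
    noise_sd: float = 1.0,
    outcome_gamma: float | None = None,
    outcome_prevalence: float = 0.3,
    seed: int = 0,
) -> Phenotypes:
    """Additive-genetic phenotypes with Gaussian noise; optional binary outcome.

    Each phenotype is the genotype-weighted sum plus ``N(0, noise_sd^2)``
    noise; the child uses ``w_child`` and the parents ``w_parental``
    (defaulting to ``w_child`` — same trait architecture in both
    generations). When ``outcome_gamma`` is given, a binary paternal outcome
    is drawn as ``Bernoulli(logistic(alpha + gamma * F_p))`` with ``alpha``
    set so that the expected prevalence is ``outcome_prevalence`` — a
    disease caused by the paternal phenotype, as lung cancer is by smoking.
    """
    w_child = np.asarray(w_child, float)
    if len(w_child) != genomes.m_snps:
        raise ValueError("w_child length must equal the number of SNPs")
    w_parental = w_child if w_parental is None else np.asarray(w_parental, float)
    if len(w_parental) != genomes.m_snps:
        raise ValueError("w_parental length must equal the number of SNPs")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = genomes.n

    def score(g: np.ndarray, w: np.ndarray) -> np.ndarray:
        return (g.astype(np.float32) @ w.astype(np.float32)).astype(np.float64)

    noise = lambda: rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    c_p = score(genomes.child, w_child) + noise()
    m_p = score(genomes.mother, w_parental) + noise()
    f_p = score(genomes.father, w_parental) + noise()

    outcome = None
    if outcome_gamma is not None:
        if not 0 < outcome_prevalence < 1:
            raise ValueError("outcome_prevalence must lie in (0, 1)")
        # solve the intercept so the population prevalence is hit exactly
        # (a plug-in logit intercept undershoots by Jensen's inequality)
        from scipy.optimize import brentq
        from scipy.special import expit, logit

        lp = outcome_gamma * f_p
        base = float(logit(outcome_prevalence) - lp.mean())
        alpha = brentq(
            lambda a: expit(a + lp).mean() - outcome_prevalence,
            base - 20.0,
            base + 20.0,
        )
        prob = expit(alpha + lp)
        outcome = (rng.random(n) < prob).astype(np.int8)
    return Phenotypes(np.asarray(c_p, float), np.asarray(m_p, float), np.asarray(f_p, float), outcome)


def gwas_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    snps: pd.DataFrame,
    scale: str = "linear",
    trait: str | None = None,
    chunk: int = 2_000,
) -> SumstatTable:
    """Per-SNP simple OLS of a phenotype on allele counts (with intercept).

    Returns a summary-statistic table with the observed effect-allele
    frequency and sample size; monomorphic SNPs are dropped with a warning.
    A perfectly fitting SNP would have zero residual SE; its SE is floored
    at the smallest positive double so the record stays representable.
    """
    y = np.asarray(phenotype, float)
    n, m = genotypes.shape
    if len(y) != n:
        raise ValueError("phenotype length must match the genotype rows")
    if len(snps) != m:
        raise ValueError("snps frame must describe every genotype column")
    yc = y - y.mean()
    syy = float(yc @ yc)
    beta = np.empty(m)
    se = np.empty(m)
    eaf = np.empty(m)
    mono = np.zeros(m, dtype=bool)
    yc32 = yc.astype(np.float32)
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        x = genotypes[:, start:stop].astype(np.float32)
        xm = x.mean(axis=0, dtype=np.float64)
        xc = x - xm.astype(np.float32)
        sxx = np.einsum("ij,ij->j", xc, xc, dtype=np.float64)
        mono_chunk = sxx == 0
        sxx_safe = np.where(mono_chunk, 1.0, sxx)
        b = np.einsum("i,ij->j", yc32, xc, dtype=np.float64) / sxx_safe
        rss = np.maximum(syy - b**2 * sxx_safe, 0.0)
        sigma2 = rss / max(n - 2, 1)
        beta[start:stop] = b
        se[start:stop] = np.sqrt(
            np.maximum(sigma2 / sxx_safe, np.finfo(float).tiny)
        )
        eaf[start:stop] = xm / 2.0
        mono[start:stop] = mono_chunk
    if mono.any():
        logger.warning("dropping %d monomorphic SNPs from the scan", int(mono.sum()))
    keep = ~mono
    df = pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy()[keep],
            "chrom": snps["chrom"].to_numpy()[keep],
            "pos": snps["pos"].to_numpy()[keep],
            "effect_allele": snps["effect_allele"].to_numpy()[keep],
            "other_allele": snps["other_allele"].to_numpy()[keep],
            "eaf": eaf[keep],
            "beta": beta[keep],
            "se": se[keep],
            "pvalue": recompute_pvalue(beta[keep], se[keep]),
            "n": float(n),
        }
    )
    return SumstatTable(df, scale=scale, trait=trait)


def _banded_r2_table(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    max_lag: int,
    min_r2: float,
) -> pd.DataFrame:
    """Pairwise r2 between SNPs up to ``max_lag`` columns apart, same chromosome."""
    x = genotypes.astype(np.float32)
    x -= x.mean(axis=0)
    norm = np.sqrt(np.einsum("ij,ij->j", x, x))
    norm[norm == 0] = np.inf
    x /= norm
    chrom = snps["chrom"].to_numpy()
    ids = snps["snp_id"].to_numpy()
    rows = []
    m = x.shape[1]
    for lag in range(1, min(max_lag, m - 1) + 1):
        r = np.einsum("ij,ij->j", x[:, :-lag], x[:, lag:])
        r2 = r.astype(np.float64) ** 2
        ok = (r2 >= min_r2) & (chrom[:-lag] == chrom[lag:])
        for i in np.nonzero(ok)[0]:
            rows.append((ids[i], ids[i + lag], r2[i]))
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


@dataclass
class BenchmarkBundle:
    """Paths and ground truth for one generated benchmark data set."""

    directory: Path
    child_gwas: Path
    maternal_gwas: Path
    outcome_gwas: Path
    ld_table: Path
    truth: Path
    meta: dict


def make_benchmark_bundle(
    out_dir: str | Path,
    seed: int = 0,
    scenario: str = "causal",
    n: int = 6_000,
    m_snps: int = 20_000,
    n_causal: int = 6,
    w_low: float = 1.1,
    w_high: float = 1.6,
    gamma: float = 0.15,
    prevalence: float = 0.30,
    noise_sd: float = 1.0,
    block_size: int = 5,
    block_r: float = 0.9,
    ld_max_lag: int = 20,
    ld_min_r2: float = 1e-3,
    ld_panel_rows: int = 6_000,
) -> BenchmarkBundle:
    """Write a self-contained benchmark data set emulating the real inputs.

    Simulates ``3 * n`` trios and scans three *disjoint* subcohorts of ``n``
    trios each — child phenotype, maternal phenotype and binary paternal
    outcome, all regressed on the index person's genotype, linear scale —
    so the three GWASs have independent estimation errors, as the SE
    propagation of the subtraction and the two-sample MR design assume.
    Also writes a banded LD r-squared table from the father genotype panel,
    a per-SNP truth file and a metadata YAML.

    ``n_causal`` well-separated block-head SNPs carry weights of magnitude
    uniform in [w_low, w_high] with random sign, shared between generations;
    their allele frequencies are drawn from [0.2, 0.5]; remaining SNPs are
    null. The default weights are deliberately large for the cohort size —
    they put the causal SNPs' derived-GWAS z-scores near 10, i.e. clearly
    past the instrument-selection thresholds, where the winner's-curse
    correction operates in its mild regime and MR parameter recovery is
    identifiable at desk scale. Under
    ``scenario="causal"`` the binary outcome depends on the paternal
    phenotype with logistic coefficient ``gamma`` per phenotype unit; under
    ``"null"`` the outcome is drawn at the same prevalence but independently
    of the paternal phenotype.

    The truth file records each SNP's marginal weight ``eff_w`` (the causal
    weight leaked through block LD), the estimand ``0.5 * eff_w`` of the
    subtracted GWAS in raw phenotype units, and its SMD-scale counterpart.
    The metadata stores the population phenotype SD (for rescaling, playing
    the role of an externally supplied trait SD) and the generator-implied
    causal slope of the outcome per SD of the paternal phenotype on the
    log-odds scale (for checking MR recovery).
    """
    if scenario not in ("causal", "null"):
        raise ValueError("scenario must be 'causal' or 'null'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_023]))
    n_total = 3 * n

    # causal weights on well-separated block heads
    n_blocks = -(-m_snps // block_size)
    if n_causal > n_blocks:
        raise ValueError("more causal SNPs than LD blocks")
    causal_blocks = np.linspace(0, n_blocks - 1, n_causal).astype(int)
    causal_idx = causal_blocks * block_size

    maf = rng.uniform(0.05, 0.5, m_snps)
    maf[causal_idx] = rng.uniform(0.2, 0.5, n_causal)

    # LD is confined to the causal blocks plus a random tenth of the null
    # blocks: clumping and truth-leakage are exercised, while the bulk of
    # the genome stays independent so the null z's carry full information
    # (lambda_GC's sampling SD grows with LD-induced loss of effective SNPs)
    r_per_block = np.zeros(n_blocks)
    decoys = rng.random(n_blocks) < 0.10
    r_per_block[decoys] = block_r
    r_per_block[causal_blocks] = block_r

    genomes = generate_trio_genomes(
        m_snps,
        n_total,
        maf_spec=maf,
        seed=int(rng.integers(2**31)),
        block_size=block_size,
        block_r=r_per_block,
    )

    w = np.zeros(m_snps)
    magnitude = rng.uniform(w_low, w_high, n_causal)
    sign = rng.choice([-1.0, 1.0], n_causal)
    w[causal_idx] = magnitude * sign

    # marginal per-SNP weight: LD leaks a causal head onto its block members
    eff_w = w.copy()
    heads = _block_heads(m_snps, block_size)
    member = np.arange(m_snps) != heads
    r_per_snp = r_per_block[np.arange(m_snps) // block_size]
    eff_w[member] = (r_per_snp * w[heads])[member]

    # population phenotype SD (same construction for all three phenotypes)
    var_genetic = float(np.sum(w**2 * 2 * genomes.maf * (1 - genomes.maf)))
    pheno_sd = float(np.sqrt(var_genetic + noise_sd**2))

    phenos = generate_phenotypes(
        genomes,
        w_child=w,
        noise_sd=noise_sd,
        outcome_gamma=gamma if scenario == "causal" else 0.0,
        outcome_prevalence=prevalence,
        seed=int(rng.integers(2**31)),
    )

    from .sumstats import write_sumstats  # local to avoid cycles at import time

    sub_a = slice(0, n)  # child-phenotype GWAS cohort
    sub_b = slice(n, 2 * n)  # maternal-phenotype GWAS cohort
    sub_c = slice(2 * n, n_total)  # paternal-outcome GWAS cohort
    child_tab = gwas_scan(
        genomes.child[sub_a], phenos.c_p[sub_a], genomes.snps, trait="child phenotype"
    )
    maternal_tab = gwas_scan(
        genomes.child[sub_b], phenos.m_p[sub_b], genomes.snps, trait="maternal phenotype"
    )
    outcome_tab = gwas_scan(
        genomes.child[sub_c],
        phenos.outcome[sub_c].astype(float),
        genomes.snps,
        trait="paternal outcome",
    )
    paths = {
        "child_gwas": out_dir / "child_gwas.tsv",
        "maternal_gwas": out_dir / "maternal_gwas.tsv",
        "outcome_gwas": out_dir / "outcome_gwas.tsv",
    }
    write_sumstats(child_tab, paths["child_gwas"])
    write_sumstats(maternal_tab, paths["maternal_gwas"])
    write_sumstats(outcome_tab, paths["outcome_gwas"])

    ld = _banded_r2_table(
        genomes.father[: min(ld_panel_rows, n_total)],
        genomes.snps,
        ld_max_lag,
        ld_min_r2,
    )
    ld_path = out_dir / "ld.tsv"
    ld.to_csv(ld_path, sep="\t", index=False)

    truth = genomes.snps[["snp_id", "chrom", "pos"]].copy()
    truth["w"] = w
    truth["eff_w"] = eff_w
    truth["beta_paternal_true"] = 0.5 * eff_w
    truth["beta_paternal_true_smd"] = 0.5 * eff_w / pheno_sd
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    y = phenos.outcome[sub_c].astype(float)
    ncase = int(y.sum())
    ntotal = int(len(y))
    pbar = ncase / ntotal
    # generator-implied causal slope on the scale the MR pipeline estimates:
    # log-odds of outcome per SD of the paternal phenotype
    fp_c = phenos.f_p[sub_c] - phenos.f_p[sub_c].mean()
    slope_lin = float((fp_c @ (y - pbar)) / (fp_c @ fp_c))
    implied_slope = slope_lin / (pbar * (1 - pbar)) * pheno_sd

    meta = {
        "seed": seed,
        "scenario": scenario,
        "n": n,
        "n_total": n_total,
        "m_snps": m_snps,
        "n_causal": n_causal,
        "gamma": gamma if scenario == "causal" else 0.0,
        "prevalence": prevalence,
        "ncase": ncase,
        "ntotal": ntotal,
        "pheno_sd": pheno_sd,
        "implied_mr_slope": implied_slope,
        "block_size": block_size,
        "block_r": block_r,
    }
    with open(out_dir / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    return BenchmarkBundle(
        directory=out_dir,
        child_gwas=paths["child_gwas"],
        maternal_gwas=paths["maternal_gwas"],
        outcome_gwas=paths["outcome_gwas"],
        ld_table=ld_path,
        truth=truth_path,
        meta=meta,
    )
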