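"""Rescaling GWAS effect sizes onto a common standardized-mean-difference scale.

Subtracting betas only makes sense when both GWASs report effects in the
same units. The pipeline therefore converts each input onto the SMD scale
(per standard deviation of the phenotype):

* a continuous trait analysed on its raw scale is divided by the phenotype
  SD (:func:`standardize_continuous`);
* a 0/1 trait analysed with a linear model is first converted to log odds
  ratios by dividing by ``p(1-p)`` with ``p`` the trait prevalence
  (:func:`linear_to_logodds`), then to SMD by dividing by the logistic-
  distribution scale factor ``pi/sqrt(3)`` (:func:`logodds_to_smd`).

Every conversion divides beta and SE by the same constant, so z-scores and
p-values are untouched; allele frequencies and sample sizes pass through.
"""

from __future__ import annotations

import logging
import math

from .sumstats import SumstatTable

logger = logging.getLogger(__name__)

#: SD of the standard logistic distribution: divides log odds to give SMD
LOGISTIC_SD = math.pi / math.sqrt(3.0)


def _check_scale(table: SumstatTable, expected: str, force: bool, op: str) -> None:
    if table.scale != expected:
        msg = f"{op} expects a table on the {expected!r} scale, got {table.scale!r}"
        if not force:
            raise ValueError(msg)
        logger.warning("%s (proceeding because force=True)", msg)


def _divide(table: SumstatTable, divisor: float, new_scale: str, **meta) -> SumstatTable:
    df = table.df.copy()
    df["beta"] = df["beta"] / divisor
    df["se"] = df["se"] / divisor
    return table.with_df(df, scale=new_scale, **meta)


def standardize_continuous(
    table: SumstatTable, phenotype_sd: float, force: bool = False
) -> SumstatTable:
    """Divide betas and SEs of a continuous-trait GWAS by the phenotype SD.

    The result is on the SMD scale (effect per phenotype SD per allele).
    """
    if not phenotype_sd > 0:
        raise ValueError("phenotype_sd must be > 0")
    _check_scale(table, "linear", force, "standardize_continuous")
    return _divide(table, phenotype_sd, "SMD")


def linear_to_logodds(
    table: SumstatTable,
    ncase: int | None = None,
    ntotal: int | None = None,
    force: bool = False,
) -> SumstatTable:
    """Convert linear-model effects on a 0/1 trait to log odds ratios.

    Divides beta and SE by ``p(1-p)`` where ``p = ncase/ntotal`` is the
    trait prevalence (the first-order link between a linear-probability
    slope and a logistic coefficient). Counts default to the table's
    ``n_case``/``n_total`` metadata.
    """
    ncase = table.n_case if ncase is None else ncase
    ntotal = table.n_total if ntotal is None else ntotal
    if ncase is None or ntotal is None:
        raise ValueError("ncase and ntotal are required (no counts in metadata)")
    if not 0 < ncase < ntotal:
        raise ValueError("need 0 < ncase < ntotal for a non-degenerate prevalence")
    _check_scale(table, "linear", force, "linear_to_logodds")
    p = ncase / ntotal
    return _divide(table, p * (1.0 - p), "log-odds", n_case=ncase, n_total=ntotal)


def logodds_to_smd(table: SumstatTable, force: bool = False) -> SumstatTable:
    """Convert log odds ratios to standardized mean differences.

    Divides beta and SE by ``pi/sqrt(3)`` (the SD of the standard logistic
    distribution underlying the binary trait).
    """
    _check_scale(table, "log-odds", force, "logodds_to_smd")
    return _divide(table, LOGISTIC_SD, "SMD")


def binary_to_smd(
    table: SumstatTable,
    ncase: int | None = None,
    ntotal: int | None = None,
    force: bool = False,
) -> SumstatTable:
    """Both binary-trait steps in sequence: linear -> log-odds -> SMD."""
    return logodds_to_smd(linear_to_logodds(table, ncase, ntotal, force=force))
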