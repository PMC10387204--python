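import numpy as np
import pandas as pd
import pytest

import gwsub


@pytest.fixture
def small_table():
    """A tiny valid summary-statistic table on the linear scale."""
    df = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "chrom": ["1", "1", "2"],
            "pos": [1000, 2000, 1000],
            "effect_allele": ["A", "C", "T"],
            "other_allele": ["G", "T", "G"],
            "eaf": [0.2, 0.4, 0.1],
            "beta": [0.1, -0.2, 0.05],
            "se": [0.02, 0.05, 0.01],
            "pvalue": [1e-6, 6.3e-5, 5.7e-7],
            "n": [5000.0, 5000.0, 5000.0],
        }
    )
    return gwsub.SumstatTable(df, scale="linear")


def _table_from_rows(rows, scale="SMD"):
    df = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se"],
    )
    df["pvalue"] = gwsub.recompute_pvalue(df["beta"].to_numpy(), df["se"].to_numpy())
    df["n"] = 1000.0
    return gwsub.SumstatTable(df, scale=scale)


@pytest.fixture
def table_factory():
    return _table_from_rows


@pytest.fixture(scope="session")
def causal_bundle(tmp_path_factory):
    """Full-size benchmark bundle with a causal paternal-phenotype -> outcome effect."""
    out = tmp_path_factory.mktemp("bundle_causal")
    return gwsub.make_benchmark_bundle(out, seed=1, scenario="causal")


@pytest.fixture(scope="session")
def null_bundle(tmp_path_factory):
    """Full-size benchmark bundle with no paternal-phenotype -> outcome effect."""
    out = tmp_path_factory.mktemp("bundle_null")
    return gwsub.make_benchmark_bundle(out, seed=2, scenario="null")


def derive_paternal(bundle):
    """Standardize the bundle's child and maternal GWASs and subtract them."""
    child = gwsub.read_sumstats(bundle.child_gwas, scale="linear")
    maternal = gwsub.read_sumstats(bundle.maternal_gwas, scale="linear")
    sd = bundle.meta["pheno_sd"]
    pairs = gwsub.align_tables(
        gwsub.standardize_continuous(child, sd),
        gwsub.standardize_continuous(maternal, sd),
    )
    return gwsub.subtract_gwas(pairs)


@pytest.fixture(scope="session")
def causal_paternal(causal_bundle):
    return derive_paternal(causal_bundle)


@pytest.fixture(scope="session")
def null_paternal(null_bundle):
    return derive_paternal(null_bundle)


def ols_slope_se(x, y):
    """Independent closed-form simple-regression helper for assertions."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    sxx = xc @ xc
    slope = (xc @ y) / sxx
    resid = y - y.mean() - slope * xc
    se = np.sqrt((resid @ resid) / (len(x) - 2) / sxx)
    return slope, se
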