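"""Instrument selection, winner's-curse correction, clumping and IVW estimation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import gwsub


def _table(betas, ses, positions=None, chroms=None, ids=None, eaf=0.3):
    k = len(betas)
    df = pd.DataFrame(
        {
            "snp_id": ids or [f"rs{i}" for i in range(k)],
            "chrom": chroms or ["1"] * k,
            "pos": positions or list(np.arange(1, k + 1) * 1000),
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "eaf": eaf,
            "beta": betas,
            "se": ses,
            "n": 1000.0,
        }
    )
    df["pvalue"] = gwsub.recompute_pvalue(df["beta"].to_numpy(), df["se"].to_numpy())
    return gwsub.SumstatTable(df, scale="SMD")


class TestSelectInstruments:
    def test_filters_on_threshold(self):
        table = _table([0.55, 0.45], [0.1, 0.1])  # p ~ 3.8e-8 and 6.8e-6
        out = gwsub.select_instruments(table, 5e-6)
        assert list(out.df["snp_id"]) == ["rs0"]

    def test_threshold_one_keeps_everything(self):
        table = _table([0.5, 0.1, 0.0], [0.1, 0.1, 0.1])
        assert len(gwsub.select_instruments(table, 1.1)) == 3

    def test_empty_selection_names_threshold(self):
        table = _table([0.1], [0.1])
        with pytest.raises(ValueError, match="5e-08"):
            gwsub.select_instruments(table, 5e-8)


def _fiqt_oracle(z):
    """Brute-force BH-then-quantile winner's-curse correction."""
    z = np.asarray(z, float)
    m = len(z)
    p = 2 * stats.norm.sf(np.abs(z))
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.sign(z) * stats.norm.isf(adj / 2)


class TestFiqt:
    def test_single_snp_unchanged(self):
        table = _table([0.5], [0.1])
        out = gwsub.fiqt_adjust(table)
        assert out.df.loc[0, "beta"] == pytest.approx(0.5, rel=1e-12)

    def test_equal_pvalues_unchanged(self):
        table = _table([0.3, -0.3, 0.3], [0.1, 0.1, 0.1])
        out = gwsub.fiqt_adjust(table)
        np.testing.assert_allclose(out.df["beta"], table.df["beta"], rtol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        z = np.concatenate([[5.0, 1.0], rng.standard_normal(40) * 2])
        se = rng.uniform(0.05, 0.2, len(z))
        table = _table(z * se, se)
        out = gwsub.fiqt_adjust(table)
        np.testing.assert_allclose(
            out.df["beta"] / out.df["se"], _fiqt_oracle(z), rtol=1e-10
        )

    def test_shrinkage_and_rank_preservation(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(200) * 3
        se = np.full(200, 0.1)
        out = gwsub.fiqt_adjust(_table(z * se, se))
        z_adj = (out.df["beta"] / out.df["se"]).to_numpy()
        assert (np.abs(z_adj) <= np.abs(z) + 1e-12).all()
        # rank order of |z| preserved (weakly: BH can tie neighbours)
        ordered = np.abs(z_adj)[np.argsort(np.abs(z))]
        assert (np.diff(ordered) >= -1e-12).all()

    def test_selection_pvalue_stays_unadjusted(self):
        table = _table([0.5, 0.1], [0.1, 0.1])
        out = gwsub.fiqt_adjust(table)
        np.testing.assert_allclose(out.df["pvalue"], table.df["pvalue"], rtol=1e-12)
        assert (out.df["p_fdr"] >= out.df["pvalue"] - 1e-15).all()


class _FakeLD(gwsub.TableLD):
    def __init__(self, pairs_r2):
        self._r2 = {tuple(sorted(k)): v for k, v in pairs_r2.items()}
        self._snps = {s for pair in pairs_r2 for s in pair}


class TestPanelLD:
    def test_r2_is_squared_pearson_correlation_of_allele_counts(self):
        rng = np.random.default_rng(31)
        geno = pd.DataFrame(
            {
                "rs0": rng.integers(0, 3, 500),
                "rs1": rng.integers(0, 3, 500),
                "rs2": 1,  # monomorphic
            }
        )
        geno["rs1"] = (geno["rs0"] + geno["rs1"]) // 2  # induce correlation
        ld = gwsub.PanelLD(geno)
        expected = np.corrcoef(geno["rs0"], geno["rs1"])[0, 1] ** 2
        assert ld.r2("rs0", "rs1") == pytest.approx(expected, rel=1e-12)
        assert ld.r2("rs0", "rs2") == 0.0
        assert "rs0" in ld and "rs9" not in ld


class TestClump:
    def test_single_snp_kept(self):
        table = _table([0.5], [0.1])
        out = gwsub.clump(table, _FakeLD({("rs0", "rs0"): 1.0}))
        assert list(out.df["snp_id"]) == ["rs0"]

    def test_correlated_neighbour_removed(self):
        table = _table([0.6, 0.45], [0.1, 0.1], positions=[1000, 6000])
        ld = _FakeLD({("rs0", "rs1"): 1.0})
        out = gwsub.clump(table, ld, r2_threshold=0.001, window_kb=10_000)
        assert list(out.df["snp_id"]) == ["rs0"]

    def test_distant_snps_survive_any_r2(self):
        table = _table([0.6, 0.45], [0.1, 0.1], positions=[1000, 20_000_001_000])
        ld = _FakeLD({("rs0", "rs1"): 1.0})
        out = gwsub.clump(table, ld, window_kb=10_000)
        assert len(out) == 2

    def test_different_chromosomes_never_clump(self):
        table = _table([0.6, 0.45], [0.1, 0.1], positions=[1000, 2000], chroms=["1", "2"])
        ld = _FakeLD({("rs0", "rs1"): 1.0})
        assert len(gwsub.clump(table, ld)) == 2

    def test_missing_snp_policies(self):
        table = _table([0.6, 0.45], [0.1, 0.1])
        empty = _FakeLD({})
        assert len(gwsub.clump(table, empty, missing_policy="permissive")) == 2
        with pytest.raises(ValueError, match="strict"):
            gwsub.clump(table, empty, missing_policy="strict")

    def test_output_is_maximal_independent_set(self):
        """No two survivors conflict; every removed SNP conflicts with a
        smaller-p survivor."""
        rng = np.random.default_rng(10)
        k = 30
        z = rng.uniform(4, 8, k)
        se = np.full(k, 0.1)
        pos = list(rng.choice(np.arange(1, 2_000_001, 1000), size=k, replace=False))
        table = _table(z * se, se, positions=pos)
        pairs = {}
        ids = list(table.df["snp_id"])
        for i in range(k):
            for j in range(i + 1, k):
                if rng.random() < 0.15:
                    pairs[(ids[i], ids[j])] = rng.uniform(0.5, 1.0)
        ld = _FakeLD(pairs)
        out = gwsub.clump(table, ld, r2_threshold=0.001, window_kb=10_000)
        kept = set(out.df["snp_id"])
        info = table.df.set_index("snp_id")

        def conflicts(a, b):
            same_chrom = info.loc[a, "chrom"] == info.loc[b, "chrom"]
            close = abs(int(info.loc[a, "pos"]) - int(info.loc[b, "pos"])) <= 10_000_000
            return same_chrom and close and ld.r2(a, b) > 0.001

        for a in kept:
            for b in kept:
                assert a == b or not conflicts(a, b)
        for snp in set(ids) - kept:
            assert any(
                conflicts(snp, s) and info.loc[s, "pvalue"] <= info.loc[snp, "pvalue"]
                for s in kept
            )


class TestIvwMre:
    @staticmethod
    def _pairs(bx, by, sey):
        df = pd.DataFrame({"beta_a": bx, "se_a": 0.05, "beta_b": by, "se_b": sey})
        return df

    def test_single_snp_is_wald_ratio(self):
        res = gwsub.ivw_mre(self._pairs([0.5], [0.2], [0.1]))
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.2)
        assert res.sigma == 1.0

    def test_perfect_fit_floors_sigma(self):
        bx = np.array([0.2, 0.4, 0.6])
        res = gwsub.ivw_mre(self._pairs(bx, 2 * bx, [0.1, 0.2, 0.1]))
        assert res.beta == pytest.approx(2.0, rel=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.sigma == 1.0

    @pytest.mark.parametrize("k", [3, 7, 20])
    def test_matches_weighted_least_squares_oracle(self, k):
        rng = np.random.default_rng(k)
        bx = rng.normal(0, 0.3, k)
        by = 1.5 * bx + rng.normal(0, 0.05, k)
        sey = rng.uniform(0.02, 0.1, k)
        res = gwsub.ivw_mre(self._pairs(bx, by, sey))
        fit = sm.WLS(by, bx, weights=1 / sey**2).fit()
        sigma_oracle = max(1.0, np.sqrt(fit.scale))
        assert res.beta == pytest.approx(fit.params[0], rel=1e-10)
        assert res.se == pytest.approx(
            fit.bse[0] / np.sqrt(fit.scale) * sigma_oracle, rel=1e-10
        )

    def test_se_never_below_fixed_effect(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0, 0.3, 10)
        by = 0.8 * bx + rng.normal(0, 0.3, 10)
        sey = np.full(10, 0.05)
        res = gwsub.ivw_mre(self._pairs(bx, by, sey))
        fixed_se = np.sqrt(1.0 / np.sum(bx**2 / sey**2))
        assert res.se >= fixed_se - 1e-15

    def test_empty_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gwsub.ivw_mre(self._pairs([], [], []))
        with pytest.raises(ValueError):
            gwsub.ivw_mre(self._pairs([0.0], [0.1], [0.1]))


class TestMeanF:
    def test_definition_on_one_snp(self):
        assert gwsub.mean_f(_table([0.5], [0.1])) == pytest.approx(25.0)

    def test_mean_of_squared_z(self):
        assert gwsub.mean_f(_table([0.3, 0.4], [0.1, 0.1])) == pytest.approx(12.5)

    def test_expectation_is_noncentrality_plus_one(self):
        """Observed z = true z + noise, so E[F] = z_true^2 + 1."""
        rng = np.random.default_rng(15)
        z_true = 6.0
        z = z_true + rng.standard_normal(20_000)
        se = np.full(len(z), 0.1)
        f = gwsub.mean_f(_table(z * se, se))
        assert f == pytest.approx(z_true**2 + 1, rel=0.02)


class TestRunMr:
    def test_exposure_as_its_own_outcome_recovers_unit_slope(self):
        rng = np.random.default_rng(16)
        z = rng.uniform(5, 9, 30)
        se = np.full(30, 0.05)
        pos = list(np.arange(1, 31) * 20_000_000_000)  # far apart: no clumping
        exposure = _table(z * se, se, positions=pos)
        results, failures = gwsub.run_mr(
            exposure, exposure, _FakeLD({}), thresholds=(5e-6,), apply_fiqt=False
        )
        assert not failures
        res = results[5e-6]
        assert res.beta == pytest.approx(1.0, rel=1e-10)
        assert res.sigma == 1.0

    def test_per_threshold_failures_are_isolated(self):
        exposure = _table([0.48, 0.1], [0.1, 0.1])  # p ~ 1.6e-6 only
        results, failures = gwsub.run_mr(
            exposure, exposure, _FakeLD({}), thresholds=(5e-6, 5e-8), apply_fiqt=False
        )
        assert 5e-6 in results
        assert 5e-8 in failures
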