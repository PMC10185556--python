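import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admeth import ewas
from admeth.core_io import MethylationMatrix
from admeth.ewas import (
    bh_fdr,
    control_probe_pcs,
    filter_sites,
    ivw_meta,
    quantile_normalize,
    replication_gate,
    sensitivity_refit,
    site_association,
)


def _matrix(betas: np.ndarray, prefix="s"):
    cols = [f"{prefix}{j}" for j in range(betas.shape[1])]
    bdf = pd.DataFrame(betas, index=[f"cg{i}" for i in range(betas.shape[0])], columns=cols)
    sites = pd.DataFrame({"chrom": "chr1", "start": np.arange(betas.shape[0]) * 10_000 + 10},
                         index=bdf.index)
    sheet = pd.DataFrame({"cohort": "c", "depot": "subc", "participant": cols, "case": 0},
                         index=pd.Index(cols, name="sample"))
    return MethylationMatrix(bdf, sites, sheet)


class TestFilterSites:
    def test_removes_listed_sites(self, sim):
        m = sim.cohorts["discovery"]
        excl = list(m.site_ids[:3])
        out = filter_sites(m, excl)
        assert out.n_sites == m.n_sites - 3
        assert not set(excl) & set(out.site_ids)

    def test_idempotent_and_tolerant_of_unknown_ids(self, sim):
        m = sim.cohorts["discovery"]
        once = filter_sites(m, ["cg0000000", "not_a_site"])
        twice = filter_sites(once, ["cg0000000", "not_a_site"])
        assert list(once.site_ids) == list(twice.site_ids)

    def test_empty_list_warns_and_passes_through(self, sim):
        with pytest.warns(UserWarning):
            out = filter_sites(sim.cohorts["discovery"], [])
        assert out.n_sites == sim.cohorts["discovery"].n_sites


class TestQuantileNormalize:
    def test_identical_samples_are_fixed_point(self):
        col = np.array([0.1, 0.5, 0.9, 0.3])
        m = _matrix(np.column_stack([col, col]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.betas.to_numpy(), m.betas.to_numpy())

    def test_order_statistic_means_hand_example(self):
        # samples (.1,.2,.3) and (.4,.5,.6) -> both (.25,.35,.45)
        m = _matrix(np.array([[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]]))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.betas.to_numpy(),
                                   np.array([[0.25, 0.25], [0.35, 0.35], [0.45, 0.45]]))

    def test_monotone_transform_invariance(self):
        # a column and its strictly monotone transform share ranks, so they
        # must normalise to identical values
        rng = np.random.default_rng(0)
        a = rng.random(50)
        out = quantile_normalize(_matrix(np.column_stack([a, a**2, rng.random(50)])))
        np.testing.assert_allclose(out.betas.iloc[:, 0], out.betas.iloc[:, 1])

    def test_all_missing_sample_rejected(self):
        X = np.random.default_rng(0).random((10, 2))
        X[:, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(_matrix(X))


class TestControlProbePCs:
    def test_rank_one_matrix_needs_single_pc(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        v = rng.normal(size=12)
        controls = pd.DataFrame(np.outer(u, v), columns=[f"s{j}" for j in range(12)])
        pcs = control_probe_pcs(controls)
        assert pcs.shape == (12, 1)

    def test_isotropic_noise_needs_most_pcs(self):
        rng = np.random.default_rng(1)
        controls = pd.DataFrame(rng.normal(size=(200, 20)),
                                columns=[f"s{j}" for j in range(20)])
        pcs = control_probe_pcs(controls, var_target=0.95)
        assert pcs.shape[1] >= int(0.8 * 19)  # white spectrum: k near 0.95 x min(dim)

    def test_scores_are_uncorrelated_and_centred(self, sim):
        pcs = control_probe_pcs(sim.controls["discovery"])
        np.testing.assert_allclose(pcs.mean(axis=0), 0, atol=1e-8)
        corr = np.corrcoef(pcs.to_numpy().T)
        np.testing.assert_allclose(corr - np.diag(np.diag(corr)), 0, atol=1e-8)

    def test_incomplete_matrix_rejected(self):
        controls = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            control_probe_pcs(controls)


class TestSiteAssociation:
    def test_matches_normal_equations_exactly(self):
        rng = np.random.default_rng(3)
        n = 20
        betas = rng.random((15, n))
        m = _matrix(betas)
        pheno = (np.arange(n) < n // 2).astype(float)
        covars = pd.DataFrame({"age": rng.normal(50, 5, n)}, index=m.betas.columns)
        res = site_association(m, pd.Series(pheno, index=m.betas.columns), covars)
        X = np.column_stack([np.ones(n), pheno, covars["age"]])
        for i, site in enumerate(m.site_ids):
            beta_hat = np.linalg.solve(X.T @ X, X.T @ betas[i])
            assert res.loc[site, "effect"] == pytest.approx(beta_hat[1], abs=1e-10)

    def test_planted_effect_recovery(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pheno = np.repeat([1.0, 0.0], 48)
            y = 0.5 - 0.06 * pheno + rng.normal(0, 0.05, 96)
            m = _matrix(np.clip(y, 0, 1)[None, :])
            res = site_association(m, pd.Series(pheno, index=m.betas.columns))
            hits += abs(res["effect"].iloc[0] + 0.06) <= 2 * res["se"].iloc[0]
        assert hits / n_seeds >= 0.90

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        n_sites, n = 2000, 60
        m = _matrix(np.clip(rng.normal(0.5, 0.05, (n_sites, n)), 0, 1))
        pheno = pd.Series((np.arange(n) < n // 2).astype(float), index=m.betas.columns)
        res = site_association(m, pheno)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_collinear_covariate_rejected(self):
        m = _matrix(np.random.default_rng(0).random((5, 10)))
        pheno = pd.Series(np.repeat([1.0, 0.0], 5), index=m.betas.columns)
        covars = pd.DataFrame({"copy": pheno}, index=m.betas.columns)
        with pytest.raises(ValueError, match="collinearity"):
            site_association(m, pheno, covars)

    def test_missing_betas_listwise_deleted(self):
        rng = np.random.default_rng(1)
        X = rng.random((3, 12))
        X[1, 0] = np.nan
        m = _matrix(X)
        pheno = pd.Series(np.repeat([1.0, 0.0], 6), index=m.betas.columns)
        res = site_association(m, pheno)
        assert res["n"].tolist() == [12, 11, 12]


class TestIvwMeta:
    def test_equal_weights_average(self):
        a = pd.DataFrame({"effect": [1.0], "se": [1.0]}, index=["cg0"])
        b = pd.DataFrame({"effect": [3.0], "se": [1.0]}, index=["cg0"])
        out = ivw_meta(a, b)
        assert out.loc["cg0", "effect"] == pytest.approx(2.0)
        assert out.loc["cg0", "se"] == pytest.approx(1 / np.sqrt(2))

    def test_unequal_weights_closed_form(self):
        a = pd.DataFrame({"effect": [1.0], "se": [1.0]}, index=["cg0"])
        b = pd.DataFrame({"effect": [1.0], "se": [2.0]}, index=["cg0"])
        out = ivw_meta(a, b)
        assert out.loc["cg0", "effect"] == pytest.approx(1.0)
        assert out.loc["cg0", "se"] == pytest.approx(np.sqrt(1 / 1.25))
        assert out.loc["cg0", "Q"] == pytest.approx(0.0)

    def test_self_meta_halves_variance(self, assoc_pair):
        disc, _ = assoc_pair
        out = ivw_meta(disc, disc)
        np.testing.assert_allclose(out["se"], disc.loc[out.index, "se"] / np.sqrt(2))
        np.testing.assert_allclose(out["I2"], 0.0)

    def test_unshared_sites_excluded(self):
        a = pd.DataFrame({"effect": [1.0, 2.0], "se": [1.0, 1.0]}, index=["cg0", "cg1"])
        b = pd.DataFrame({"effect": [1.0], "se": [1.0]}, index=["cg0"])
        assert list(ivw_meta(a, b).index) == ["cg0"]


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_order_equivariant(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestReplicationGate:
    def _frame(self, q, effect, p=None):
        return pd.DataFrame({"q": q, "effect": effect,
                             "p": p if p is not None else q}, index=["cg0"])

    def test_all_gates_pass(self):
        disc = self._frame([0.005], [-0.1])
        repl = self._frame([0.005], [-0.08])
        meta = pd.DataFrame({"p": [5e-8]}, index=["cg0"])
        out = replication_gate(disc, repl, meta)
        assert out["sites"] == ["cg0"]
        assert (out["n_consistent"], out["n_discovery_significant"]) == (1, 1)

    def test_opposite_sign_fails_but_counts(self):
        disc = self._frame([0.005], [-0.1])
        repl = self._frame([0.005], [0.08])
        meta = pd.DataFrame({"p": [5e-8]}, index=["cg0"])
        out = replication_gate(disc, repl, meta)
        assert out["sites"] == []
        assert (out["n_consistent"], out["n_discovery_significant"]) == (0, 1)

    def test_gate_monotone_in_thresholds(self, sim, assoc_pair):
        disc, repl = assoc_pair
        meta = ivw_meta(disc, repl)
        loose = set(replication_gate(disc, repl, meta, 0.05, 0.05, 1e-5)["sites"])
        tight = set(replication_gate(disc, repl, meta, 0.01, 0.01, 1e-7)["sites"])
        assert tight <= loose

    def test_recovers_planted_sites(self, sim, assoc_pair):
        disc, repl = assoc_pair
        meta = ivw_meta(disc, repl)
        out = replication_gate(disc, repl, meta)
        passing = set(out["sites"])
        planted = set(sim.truth.sites.index)
        assert passing  # strong planted effects exist
        assert len(passing - planted) / max(len(passing), 1) <= 0.03  # empirical FDR
        # direction concordance among discovery-significant sites is strong
        assert out["n_consistent"] / out["n_discovery_significant"] > 0.9


class TestSensitivityRefit:
    def test_noise_covariate_leaves_effects(self, sim):
        m = sim.cohorts["discovery"].subset_sites(sim.truth.sites.index[:20])
        sheet = m.sample_sheet.loc[m.betas.columns]
        rng = np.random.default_rng(0)
        extra = pd.DataFrame({"noise": rng.normal(size=m.n_samples)}, index=m.betas.columns)
        out = sensitivity_refit(m, sheet["case"].astype(float), None, extra)
        assert abs(np.nanmedian(out["attenuation"])) < 0.1

    def test_true_confounder_attenuates_fully(self):
        rng = np.random.default_rng(5)
        n = 80
        conf = rng.normal(size=n)
        pheno = (conf + rng.normal(0, 0.3, n) > 0).astype(float)
        betas = np.clip(0.5 + 0.05 * conf + rng.normal(0, 0.005, (10, n)), 0, 1)
        m = _matrix(betas)
        extra = pd.DataFrame({"conf": conf}, index=m.betas.columns)
        out = sensitivity_refit(m, pd.Series(pheno, index=m.betas.columns), None, extra)
        assert np.nanmedian(out["attenuation"]) > 0.7

    def test_duplicated_covariate_errors(self, sim):
        m = sim.cohorts["discovery"].subset_sites(sim.cohorts["discovery"].site_ids[:5])
        sheet = m.sample_sheet.loc[m.betas.columns]
        cov = pd.DataFrame({"age": sheet["age"]})
        with pytest.raises(ValueError, match="collinearity"):
            sensitivity_refit(m, sheet["case"].astype(float), cov,
                              cov.rename(columns={"age": "age2"}))
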