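"""Module eigengene, perturbation scoring, p-value combination, ORA."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cropscreen import modscore, synth


def make_adata(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return ad.AnnData(X=X, var=pd.DataFrame(index=genes))


class TestModuleEigengene:
    def test_two_perfectly_correlated_genes(self, rng):
        base = rng.poisson(20, size=200).astype(float)
        X = np.column_stack([base, base, rng.poisson(5, 200)])
        adata = make_adata(X)
        eig = modscore.module_eigengene(adata, ["g0", "g1"])
        # log-normalization is monotone; the eigengene matches either gene's
        # standardized profile up to normalization noise
        norm = np.log1p(X[:, 0] / X.sum(axis=1) * 1e4)
        z = (norm - norm.mean()) / norm.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) > 0.99

    def test_sign_fixed_to_mean_module_expression(self, rng):
        X = rng.poisson(10, size=(150, 4)).astype(float)
        adata = make_adata(X)
        eig = modscore.module_eigengene(adata, ["g0", "g1", "g2"])
        norm = np.log1p(X / X.sum(axis=1, keepdims=True) * 1e4)
        mean_module = norm[:, :3].mean(axis=1)
        assert np.corrcoef(eig, mean_module)[0, 1] > 0

    def test_matches_svd_oracle_on_toy_matrix(self):
        X = np.array([[1, 2, 3], [4, 0, 1], [2, 2, 2], [0, 5, 4]], dtype=float)
        adata = make_adata(X)
        eig = modscore.module_eigengene(adata, ["g0", "g1", "g2"])
        # independent oracle: eigendecomposition of the correlation matrix of
        # standardized log-normalized expression
        norm = np.log1p(X / X.sum(axis=1, keepdims=True) * 1e4)
        z = (norm - norm.mean(axis=0)) / norm.std(axis=0)
        w, v = np.linalg.eigh(z.T @ z)
        pc = z @ v[:, np.argmax(w)]
        if np.corrcoef(pc, z.mean(axis=1))[0, 1] < 0:
            pc = -pc
        pc = (pc - pc.mean()) / pc.std(ddof=1)
        assert np.allclose(eig, pc, atol=1e-8)

    def test_invariant_to_gene_order_and_scaling(self, rng):
        X = rng.poisson(15, size=(100, 5)).astype(float)
        adata = make_adata(X)
        eig1 = modscore.module_eigengene(adata, ["g0", "g1", "g2"])
        eig2 = modscore.module_eigengene(adata, ["g2", "g0", "g1"])
        assert np.allclose(eig1, eig2)

    def test_unit_variance_output(self, rng):
        X = rng.poisson(15, size=(80, 4)).astype(float)
        eig = modscore.module_eigengene(make_adata(X), ["g0", "g1", "g2"])
        assert eig.mean() == pytest.approx(0, abs=1e-10)
        assert eig.std(ddof=1) == pytest.approx(1.0)

    def test_constant_module_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="variance"):
            modscore.module_eigengene(make_adata(X), ["g0", "g1"])

    def test_too_few_genes_rejected(self, rng):
        X = rng.poisson(5, (10, 3)).astype(float)
        with pytest.raises(ValueError, match="two module genes"):
            modscore.module_eigengene(make_adata(X), ["g0"])


class TestPerturbationScore:
    def test_equals_pooled_variance_t_test(self, rng):
        eig = rng.normal(size=120)
        perts = pd.Series(["geneA"] * 40 + ["ctrl_1"] * 80)
        out = modscore.perturbation_score(eig, perts, ["ctrl_1"])
        t = stats.ttest_ind(eig[:40], eig[40:], equal_var=True)
        assert out.loc["geneA", "p"] == pytest.approx(t.pvalue, rel=1e-9)
        assert out.loc["geneA", "effect"] == pytest.approx(eig[:40].mean() - eig[40:].mean())

    def test_planted_shift_recovered(self, rng):
        effects = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            eig = np.concatenate([r.normal(1.0, 1.0, 200), r.normal(0.0, 1.0, 200)])
            perts = pd.Series(["geneA"] * 200 + ["ctrl_1"] * 200)
            out = modscore.perturbation_score(eig, perts, ["ctrl_1"])
            effects.append(out.loc["geneA", "effect"])
            assert out.loc["geneA", "p"] < 0.01
        assert np.mean(effects) == pytest.approx(1.0, abs=0.05)  # unbiased

    def test_tiny_perturbation_skipped_with_warning(self, rng):
        eig = rng.normal(size=11)
        perts = pd.Series(["geneA"] * 1 + ["ctrl_1"] * 10)
        with pytest.warns(UserWarning, match="fewer than 2 cells"):
            out = modscore.perturbation_score(eig, perts, ["ctrl_1"])
        assert "geneA" not in out.index


class TestPerGeneDE:
    def test_identical_groups_null_result(self):
        X = np.tile(np.arange(1.0, 7.0)[:, None], (2, 3))
        adata = make_adata(X)
        perts = pd.Series(["geneA"] * 6 + ["ctrl_1"] * 6)
        out = modscore.per_gene_de(adata, perts, ["ctrl_1"], ["g0", "g1"], "geneA")
        assert np.allclose(out["log2fc"], 0.0)
        assert (out["p"] == 1.0).all()

    def test_planted_twofold_shift(self, small_library):
        truth = synth.PlantedTruth.null(small_library, modules=["m"])
        truth.module_effects.loc["gene001", "m"] = 1.0
        a = synth.simulate_screen(small_library, truth, 4000, 1, seed=61)
        modules = {"m": ["mgA", "mgB", "mgC"]}
        adata = synth.simulate_expression(a, modules, truth, n_genes_total=130, seed=62)
        ctrl = sorted({p for p in adata.obs["perturbation"] if p.startswith("ctrl_")})
        out = modscore.per_gene_de(
            adata, adata.obs["perturbation"], ctrl, modules["m"], "gene001"
        )
        assert out["log2fc"].mean() == pytest.approx(1.0, abs=0.25)
        assert (out["p"] < 0.01).all()

    def test_absent_gene_recorded_not_scored(self):
        adata = make_adata(np.random.default_rng(0).poisson(5, (8, 2)).astype(float))
        perts = pd.Series(["geneA"] * 4 + ["ctrl_1"] * 4)
        out = modscore.per_gene_de(adata, perts, ["ctrl_1"], ["g0", "nope"], "geneA")
        assert not out.loc["nope", "present"]
        assert np.isnan(out.loc["nope", "p"])

    @pytest.mark.parametrize("n_a,n_b", [(4, 4), (5, 7), (8, 6)])
    def test_rank_sum_p_matches_exact_enumeration(self, rng, n_a, n_b):
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b)
        p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        # brute-force oracle: enumerate all group assignments of the pooled
        # sample and count U statistics at least as extreme
        pooled = np.concatenate([a, b])
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n = len(pooled)
        mu = n_a * n_b / 2
        count = total = 0
        for idx in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, bool)
            mask[list(idx)] = True
            u = stats.mannwhitneyu(pooled[mask], pooled[~mask], alternative="two-sided").statistic
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-9)


class TestFisherCombine:
    def test_single_p_identity(self):
        assert modscore.fisher_combine([0.37]) == pytest.approx(0.37, rel=1e-12)

    def test_closed_form_half_half(self):
        # X2 = -2(ln 0.5 + ln 0.5) = 2.7726, df 4
        expected = stats.chi2.sf(-2 * 2 * np.log(0.5), df=4)
        assert modscore.fisher_combine([0.5, 0.5]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5966, abs=5e-4)

    def test_all_ones_combine_to_one(self):
        assert modscore.fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_scipy_combine(self, rng):
        p = rng.uniform(0.001, 1.0, size=9)
        expected = stats.combine_pvalues(p, method="fisher").pvalue
        assert modscore.fisher_combine(p) == pytest.approx(expected, rel=1e-12)

    def test_zero_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = modscore.fisher_combine([0.0, 0.5])
        assert 0 < p < 1e-10

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            modscore.fisher_combine([1.5])
        with pytest.raises(ValueError):
            modscore.fisher_combine([])


class TestBH:
    def test_order_preserving(self, rng):
        p = pd.Series(rng.uniform(size=30))
        adj = modscore.bh_adjust(p)
        assert (adj.loc[p.sort_values().index].diff().dropna() >= -1e-12).all()


class TestClusterModuleProfiles:
    def test_planted_blocks_recovered(self, rng):
        high = rng.normal(2.0, 0.1, size=(10, 6))
        low = rng.normal(-2.0, 0.1, size=(10, 6))
        high[:, 3:] *= -1
        low[:, 3:] *= -1
        profiles = pd.DataFrame(
            np.vstack([high, low]), index=[f"p{i}" for i in range(20)]
        )
        labels, _ = modscore.cluster_module_profiles(profiles, k=2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_n_gives_singletons(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(5, 4)))
        labels, _ = modscore.cluster_module_profiles(profiles, k=5)
        assert labels.nunique() == 5

    def test_k_out_of_range_rejected(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError):
            modscore.cluster_module_profiles(profiles, k=5)

    def test_planted_expansion_difference_detected(self, rng):
        # blocks must differ in profile *shape*: row scaling removes level
        high = rng.normal(1.5, 0.2, size=(20, 6))
        low = rng.normal(1.5, 0.2, size=(20, 6))
        high[:, :3] *= -1
        low[:, 3:] *= -1
        profiles = pd.DataFrame(np.vstack([high, low]), index=[f"p{i}" for i in range(40)])
        expansion = pd.Series(
            np.concatenate([rng.normal(1.0, 1.0, 20), rng.normal(0.0, 1.0, 20)]),
            index=profiles.index,
        )
        labels, tests = modscore.cluster_module_profiles(profiles, k=2, expansion=expansion)
        assert tests["p"].iloc[0] < 0.05


class TestExpansionModel:
    def test_noiseless_linear_signal_r_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), index=[f"p{i}" for i in range(40)])
        beta = rng.normal(size=5)
        y = pd.Series(X.to_numpy() @ beta + 0.3, index=X.index)
        fit = modscore.expansion_model(X, y)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert not fit.used_ridge
        assert np.allclose(fit.predict(X), y)

    def test_pure_noise_matches_analytic_in_sample_null(self, rng):
        # in-sample R^2 of OLS noise regression has mean p/(n-1)
        n, p = 40, 5
        X = pd.DataFrame(rng.normal(size=(n, p)), index=[f"p{i}" for i in range(n)])
        r2 = []
        for _ in range(300):
            y = pd.Series(rng.normal(size=n), index=X.index)
            r2.append(modscore.expansion_model(X, y).pearson_r ** 2)
        expected = p / (n - 1)
        se = np.std(r2) / np.sqrt(len(r2))
        assert np.mean(r2) == pytest.approx(expected, abs=4 * se)

    def test_collinear_predictors_fall_back_to_ridge(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"p{i}" for i in range(20)])
        X[3] = X[0] + X[1]  # exact collinearity
        y = pd.Series(rng.normal(size=20), index=X.index)
        with pytest.warns(UserWarning, match="ridge"):
            fit = modscore.expansion_model(X, y)
        assert fit.used_ridge

    def test_calibrated_signal_recovers_expected_correlation(self):
        # 25 module-gene predictors over 150 perturbations with noise set for
        # R^2 = 0.46 should give fitted-vs-observed r near 0.68
        n, p, r2_target = 150, 25, 0.68**2
        # in-sample R^2 of an OLS fit inflates the population R^2 by the
        # p/(n-1) null contribution; invert that to set the noise level
        r2_pop = (r2_target - p / (n - 1)) / (1 - p / (n - 1))
        rs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(n, p)))
            beta = r.normal(size=p) / 5
            signal = X.to_numpy() @ beta
            noise_sd = signal.std() * np.sqrt((1 - r2_pop) / r2_pop)
            y = pd.Series(signal + r.normal(0, noise_sd, n), index=X.index)
            rs.append(modscore.expansion_model(X, y).pearson_r)
        assert np.mean(rs) == pytest.approx(0.68, abs=0.05)


class TestORA:
    def test_degenerate_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        odds, p = modscore.ora_fisher(universe, universe, universe)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        # 2x2 table (10, 90 / 5, 895): one-sided p = P(overlap >= 10)
        universe = [f"g{i}" for i in range(1000)]
        gene_set = universe[:15]  # 10 in hits + 5 out
        hits = universe[:10] + universe[15:105]
        odds, p = modscore.ora_fisher(hits, gene_set, universe)
        expected = stats.hypergeom.sf(9, 1000, 15, 100)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_disjoint_sets_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        _, p = modscore.ora_fisher(universe[:10], universe[50:60], universe)
        assert p == pytest.approx(1.0)

    def test_subset_validation_and_bh_table(self):
        with pytest.raises(ValueError, match="universe"):
            modscore.ora_fisher(["x"], ["a"], ["a", "b"])
        universe = [f"g{i}" for i in range(50)]
        table = modscore.ora_table(
            universe[:10], {"s1": universe[:10], "s2": universe[40:]}, universe
        )
        assert table.loc["s1", "p"] < table.loc["s2", "p"]
        assert "p_adj" in table
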