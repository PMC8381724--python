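"""Prediction models: Gibbs samplers vs closed-form oracles, invariances."""

import numpy as np
import pytest

import tetragp as tg
from tetragp.gp_models import (
    GibbsConfig,
    blup_kernel,
    fit_bayes_marker,
    fit_kernel_gblup,
    fit_rkhs_ml,
    reml_1kernel,
)
from tetragp.kinship import KinshipMatrix, additive_G, dominance_G, squared_distance
from conftest import additive_trait

CFG = GibbsConfig(n_iter=2000, burn_in=600, seed=1)


def sub_kernel(K, idx):
    return KinshipMatrix([K.individuals[i] for i in idx],
                         K.values[np.ix_(idx, idx)], K.flavor, K.n_markers, K.theta)


class TestKernelGibbs:
    def test_matches_closed_form_blup(self, small_pop):
        """Posterior-mean genotypic values agree with REML-BLUP (r > 0.99) and
        the residual-variance posterior mean sits within Monte Carlo error of
        the REML estimate."""
        dm, _ = small_pop
        _, y = additive_trait(dm, h2=0.5, seed=2)
        GA = additive_G(dm)
        fit = fit_kernel_gblup(y, [GA], CFG)
        null = reml_1kernel(y, GA.values)
        oracle = blup_kernel(y, GA.values, null["sig2g"], null["sig2e"])
        assert np.corrcoef(fit.gvalues, oracle)[0, 1] > 0.99
        mcse = fit.varcomps_sd["residual"] / np.sqrt(max(fit.ess["residual"], 1.0))
        assert abs(fit.varcomps["residual"] - null["sig2e"]) < 4 * mcse + 0.05

    def test_constant_phenotype_collapses(self, small_pop):
        dm, _ = small_pop
        GA = additive_G(dm)
        y = np.full(len(dm.individuals), 3.0)
        fit = fit_kernel_gblup(y, [GA], CFG)
        assert fit.varcomps["additive"] < 1e-6
        assert np.std(fit.gvalues) < 1e-3

    def test_scale_equivariance(self, small_pop):
        """Doubling y doubles posterior-mean genetic values and quadruples
        the variance components (same RNG stream)."""
        dm, _ = small_pop
        _, y = additive_trait(dm, h2=0.5, seed=3)
        GA = additive_G(dm)
        f1 = fit_kernel_gblup(y, [GA], CFG)
        f2 = fit_kernel_gblup(2 * y, [GA], CFG)
        assert np.allclose(f2.gvalues, 2 * f1.gvalues, rtol=1e-8, atol=1e-10)
        assert np.isclose(f2.varcomps["additive"], 4 * f1.varcomps["additive"],
                          rtol=1e-8)

    def test_dominance_variance_ratio_recovered(self):
        """Equal simplex-dominance and additive truth: the posterior ratio
        sigma_d^2/sigma_a^2 has median within [0.5, 2] over seeds."""
        cfg = tg.SimulationConfig(n_individuals=120, n_markers=600, seed=8)
        dm, _ = tg.simulate_dosages(cfg)
        GA, GD = additive_G(dm), dominance_G(dm)
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = dm.dosages
            qa = rng.choice(600, 200, replace=False)
            qd = rng.choice(600, 200, replace=False)
            ga = (X[:, qa] - X[:, qa].mean(0)) @ rng.standard_normal(200)
            dsgn = np.where(X[:, qd] >= 1, 4.0, 0.0)
            gd = (dsgn - dsgn.mean(0)) @ rng.standard_normal(200)
            ga, gd = ga / ga.std(), gd / gd.std()
            y = ga + gd + rng.normal(0, 1, 120)
            fit = fit_kernel_gblup(y, [GA, GD],
                                   GibbsConfig(1500, 500, 1, seed))
            ratios.append(fit.varcomps["dominance_digenic"]
                          / fit.varcomps["additive"])
        assert 0.5 <= float(np.median(ratios)) <= 2.0

    def test_kernel_mismatch_raises(self, small_pop):
        dm, _ = small_pop
        GA = additive_G(dm)
        with pytest.raises(ValueError, match="individuals"):
            fit_kernel_gblup(np.zeros(10), [GA], CFG)


class TestRidgeEquivalence:
    def test_ridge_matches_kernel_blup(self, small_pop):
        """Marker-effect ridge regression with penalty sig2e/sig2a * sum(4pq)
        reproduces additive kernel BLUP on training individuals to 1e-6."""
        dm, _ = small_pop
        _, y = additive_trait(dm, h2=0.6, seed=5)
        GA = additive_G(dm)
        null = reml_1kernel(y, GA.values)
        g_blup = blup_kernel(y, GA.values, null["sig2g"], null["sig2e"])
        p = dm.allele_freq
        Xc = dm.dosages - 4 * p
        c = float(np.sum(4 * p * (1 - p)))
        lam = null["sig2e"] / null["sig2g"] * c
        n = len(y)
        V = null["sig2g"] * GA.values + null["sig2e"] * np.eye(n)
        Vi = np.linalg.inv(V)
        mu = float(np.sum(Vi @ y) / np.sum(Vi))
        b = np.linalg.solve(Xc.T @ Xc + lam * np.eye(Xc.shape[1]),
                            Xc.T @ (y - mu))
        assert np.allclose(Xc @ b, g_blup, atol=1e-6)


class TestBayesMarker:
    def test_null_trait_shrinks(self, small_pop):
        """Pure-noise trait: effects shrink below single-marker OLS and the
        median inclusion proportion (1 - pi) stays below one half.  pi is only
        weakly identified under the null, so the pi check uses the median
        over a few seeds with a longer chain."""
        dm, _ = small_pop
        Xc = dm.dosages - 4 * dm.allele_freq
        pis = []
        for seed in range(5):
            y = np.random.default_rng(seed).standard_normal(len(dm.individuals))
            fit = fit_bayes_marker(y, Xc, "BayesCpi",
                                   GibbsConfig(4000, 1000, 1, seed))
            pis.append(fit.pi)
            ols = np.abs(Xc.T @ y) / np.einsum("ij,ij->j", Xc, Xc)
            assert np.mean(np.abs(fit.marker_effects)) < np.mean(ols)
        assert (1.0 - float(np.median(pis))) < 0.5

    def test_oligogenic_qtl_ranked_top(self):
        """10 QTL among 2000 markers at h2=0.7: BayesCpi puts the causal
        markers in the top 5% by |posterior effect| in most seeds."""
        cfg = tg.SimulationConfig(n_individuals=150, n_markers=2000, seed=9)
        dm, _ = tg.simulate_dosages(cfg)
        Xc = np.ascontiguousarray(dm.dosages - 4 * dm.allele_freq)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            qtl = rng.choice(2000, 10, replace=False)
            g = Xc[:, qtl] @ rng.standard_normal(10)
            g = g / g.std() * np.sqrt(0.7)
            y = g + rng.normal(0, np.sqrt(0.3), 150)
            fit = fit_bayes_marker(y, Xc, "BayesCpi",
                                   GibbsConfig(1200, 400, 1, seed))
            rank = np.argsort(-np.abs(fit.marker_effects))
            top = set(rank[:100])
            hits += np.mean([q in top for q in qtl]) >= 0.5
        assert hits >= int(0.8 * n_seeds)

    def test_location_invariance(self, small_pop):
        """Shifting y by a constant shifts mu by that constant and leaves the
        marker-effect chain untouched (identical RNG stream)."""
        dm, _ = small_pop
        _, y = additive_trait(dm, h2=0.4, seed=7)
        Xc = dm.dosages - 4 * dm.allele_freq
        f0 = fit_bayes_marker(y, Xc, "BayesA", CFG)
        f1 = fit_bayes_marker(y + 5.0, Xc, "BayesA", CFG)
        assert np.allclose(f1.marker_effects, f0.marker_effects, atol=1e-10)
        assert np.isclose(f1.mu - f0.mu, 5.0, atol=1e-8)

    @pytest.mark.parametrize("prior", ["BayesA", "BayesCpi", "BayesL"])
    def test_all_priors_recover_signal(self, small_pop, prior):
        dm, _ = small_pop
        g, y = additive_trait(dm, h2=0.7, seed=8, n_qtl=20)
        Xc = dm.dosages - 4 * dm.allele_freq
        fit = fit_bayes_marker(y, Xc, prior, CFG)
        assert np.corrcoef(Xc @ fit.marker_effects, g)[0, 1] > 0.5

    def test_nonfinite_phenotype_rejected(self, small_pop):
        dm, _ = small_pop
        y = np.zeros(len(dm.individuals))
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_bayes_marker(y, dm.dosages, "BayesA", CFG)


class TestRKHS:
    def test_bandwidth_recovered_within_one_grid_step(self):
        """Data generated from a kernel at theta* in the grid: the profile
        likelihood picks theta within one grid step in most seeds.  The
        surface is nearly flat below theta* (for small theta the kernel is
        approximately 1 - theta*D, so theta trades off against the genetic
        variance), hence recovery is assessed at a bandwidth where the
        likelihood has curvature and with a strong genetic signal."""
        n = 200
        cfg = tg.SimulationConfig(n_individuals=n, n_markers=300, seed=10)
        dm, _ = tg.simulate_dosages(cfg)
        grid = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        theta_true = 2.0
        K = np.exp(-theta_true * squared_distance(dm.dosages))
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            g = L @ rng.standard_normal(n)
            y = g + rng.normal(0, 0.3 * g.std(), n)
            fit = fit_rkhs_ml(y, dm, theta_grid=grid)
            hits += abs(np.log2(fit.theta / theta_true)) <= 1.0
        assert hits >= 12

    def test_profile_likelihood_finite_everywhere(self, small_pop):
        dm, _ = small_pop
        _, y = additive_trait(dm, h2=0.5, seed=11)
        grid = np.array([1e-6, 0.1, 1.0, 10.0])
        with pytest.warns(UserWarning, match="all-ones"):
            fit = fit_rkhs_ml(y, dm, theta_grid=grid)
        assert np.isfinite(fit.varcomps["rkhs"])

    def test_no_signal_predicts_grand_mean(self, small_pop):
        dm, _ = small_pop
        rng = np.random.default_rng(12)
        y = rng.standard_normal(len(dm.individuals))
        fit = fit_rkhs_ml(y, dm)
        assert np.var(fit.gvalues) / np.var(y) < 0.05

    def test_empty_grid_rejected(self, small_pop):
        dm, _ = small_pop
        with pytest.raises(ValueError):
            fit_rkhs_ml(np.zeros(100), dm, theta_grid=np.array([]))
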