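"""REML engine, genotype BLUEs and heritability."""

import numpy as np
import pandas as pd
import pytest

import tetragp as tg
from tetragp.fieldtrial import (
    _reml_loglik,
    blues_across_trials,
    blues_within_trial,
    fit_lmm_reml,
    heritability,
)
from tetragp.simulate import FieldLayoutSpec, SimulationConfig, TraitSpec


def one_way(g, r, var_g, var_e, seed):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(var_g), g)
    y = (u[:, None] + rng.normal(0, np.sqrt(var_e), (g, r))).ravel()
    Z = np.kron(np.eye(g), np.ones((r, 1)))
    return y, Z


class TestREML:
    def test_matches_balanced_anova_closed_form(self):
        """Balanced one-way random model: REML equals the (MSB-MSW)/r and MSW
        textbook closed forms to high precision."""
        g, r = 10, 5
        y, Z = one_way(g, r, 4.0, 1.0, seed=3)
        vc, _, _ = fit_lmm_reml(y, np.ones((g * r, 1)), {"grp": Z})
        ybar = y.reshape(g, r).mean(axis=1)
        msb = r * np.var(ybar, ddof=1)
        msw = np.sum((y.reshape(g, r) - ybar[:, None]) ** 2) / (g * (r - 1))
        assert abs(vc["grp"] - (msb - msw) / r) < 1e-6
        assert abs(vc["residual"] - msw) < 1e-6
        assert vc.converged

    def test_constant_response_gives_zero_components(self):
        y = np.full(30, 7.0)
        Z = np.kron(np.eye(10), np.ones((3, 1)))
        vc, beta, _ = fit_lmm_reml(y, np.ones((30, 1)), {"grp": Z})
        assert vc["grp"] == 0.0 and vc["residual"] == 0.0
        assert np.isclose(beta[0], 7.0)

    def test_singular_fixed_design_raises(self):
        y = np.arange(10.0)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lmm_reml(y, X, {})

    def test_row_column_variance_recovery(self):
        """Row/column trial layout, sigma_row^2=2, sigma_col^2=1, sigma_e^2=1:
        median REML estimates over seeds land within +/-25% of truth."""
        nr, nc = 10, 8
        est = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            row = rng.normal(0, np.sqrt(2), nr)
            col = rng.normal(0, 1, nc)
            y = (row[:, None] + col[None, :] + rng.normal(0, 1, (nr, nc))).ravel()
            Zr = np.kron(np.eye(nr), np.ones((nc, 1)))
            Zc = np.kron(np.ones((nr, 1)), np.eye(nc))
            vc, _, _ = fit_lmm_reml(y, np.ones((nr * nc, 1)), {"row": Zr, "col": Zc})
            est.append((vc["row"], vc["col"], vc["residual"]))
        med = np.median(est, axis=0)
        assert np.all(np.abs(med / np.array([2.0, 1.0, 1.0]) - 1.0) < 0.25)

    def test_reml_optimum_beats_random_candidates(self):
        """Spot-check optimality: the reported REML log-likelihood is at least
        the likelihood at 100 random variance-component vectors."""
        g, r = 8, 4
        y, Z = one_way(g, r, 2.0, 1.0, seed=5)
        X = np.ones((g * r, 1))
        vc, _, _ = fit_lmm_reml(y, X, {"grp": Z})
        opt = vc.loglik
        rng = np.random.default_rng(6)
        vary = np.var(y)
        for _ in range(100):
            cand = rng.uniform(0.01, 2.0, 2) * vary
            ll = _reml_loglik(y, X, {"grp": Z}, {"grp": cand[0]}, cand[1])
            assert ll <= opt + 1e-6


class TestBluesWithin:
    def layout_plots(self, n_geno=30, seed=0, var_row=0.0, var_col=0.0,
                     var_plot=0.0, gvals=None):
        cfg = SimulationConfig(n_individuals=n_geno, n_markers=30, seed=seed)
        dm, _ = tg.simulate_dosages(cfg)
        layout = FieldLayoutSpec(n_locations=1, n_years=1, n_blocks=2,
                                 rows=6, cols=5, var_row=var_row,
                                 var_col=var_col, var_plot=var_plot)
        spec = TraitSpec(var_additive=1.0, var_residual=0.0)
        plots, truth = tg.simulate_phenotypes(dm, spec, layout, seed=seed + 1)
        return plots, truth

    def test_no_field_effects_blue_is_genotype_mean(self):
        plots, _ = self.layout_plots()
        res = blues_within_trial(plots)
        means = plots.groupby("genotype")["value"].mean()
        assert np.allclose(res.set_index("genotype")["blue"], means, atol=1e-5)

    def test_block_shift_absorbed_by_fixed_block(self):
        plots, _ = self.layout_plots(var_plot=0.2)
        shifted = plots.copy()
        shifted.loc[shifted["block"] == 2, "value"] += 11.0
        a = blues_within_trial(plots).set_index("genotype")["blue"]
        b = blues_within_trial(shifted).set_index("genotype")["blue"]
        # identical up to REML optimizer tolerance (start values see var(y))
        assert np.allclose(a, b, atol=1e-3)

    def test_adjustment_beats_raw_means(self):
        """With real row/column trends the adjusted means track the true
        genotypic values better than raw means in most seeds."""
        wins = 0
        for seed in range(20):
            plots, truth = self.layout_plots(seed=10 * seed, var_row=1.0,
                                             var_col=1.0, var_plot=0.2)
            res = blues_within_trial(plots).set_index("genotype")
            gv = pd.Series(truth.true_genotypic_values,
                           index=[f"G{i + 1:03d}" for i in range(30)])
            raw = plots.groupby("genotype")["value"].mean()
            r_blue = np.corrcoef(res.loc[gv.index, "blue"], gv)[0, 1]
            r_raw = np.corrcoef(raw.loc[gv.index], gv)[0, 1]
            wins += r_blue > r_raw
        assert wins >= 16

    def test_checks_excluded_from_output(self):
        plots, _ = self.layout_plots()
        res = blues_within_trial(plots, check_genotypes=["G001"])
        assert "G001" not in set(res["genotype"])

    def test_multiple_trials_rejected(self):
        plots, _ = self.layout_plots()
        other = plots.copy()
        other["trial"] = "L9Y9"
        with pytest.raises(ValueError, match="single trial"):
            blues_within_trial(pd.concat([plots, other]))


class TestBluesAcross:
    def make_within(self, shift=0.0):
        g = [f"G{i}" for i in range(12)]
        vals = np.linspace(-1, 1, 12)
        a = pd.DataFrame({"trial": "T1", "genotype": g, "blue": vals, "se": 0.1,
                          "n_outliers": 0})
        b = a.copy()
        b["trial"] = "T2"
        b["blue"] = vals + shift
        return pd.concat([a, b], ignore_index=True)

    def test_identical_trials_reproduce_blues(self):
        within = self.make_within()
        res = blues_across_trials(within).set_index("genotype")["blue"]
        expected = within[within.trial == "T1"].set_index("genotype")["blue"]
        assert np.allclose(res.loc[expected.index], expected, atol=1e-9)

    def test_trial_shift_preserves_contrasts(self):
        res0 = blues_across_trials(self.make_within()).set_index("genotype")["blue"]
        res1 = blues_across_trials(self.make_within(10.0)).set_index("genotype")["blue"]
        d0 = res0 - res0.mean()
        d1 = res1 - res1.mean()
        assert np.allclose(d0, d1, atol=1e-9)

    def test_two_step_equals_joint_model_on_balanced_data(self):
        """On a balanced multi-trial set the two-step pipeline and a single
        joint trial+genotype model give identical genotype contrasts."""
        cfg = SimulationConfig(n_individuals=25, n_markers=30, seed=40)
        dm, _ = tg.simulate_dosages(cfg)
        layout = FieldLayoutSpec(n_locations=2, n_years=1, n_blocks=2,
                                 rows=5, cols=5, var_plot=0.5)
        plots, _ = tg.simulate_phenotypes(dm, TraitSpec(var_residual=0.5),
                                          layout, seed=41)
        within = pd.concat(
            [blues_within_trial(g, fit_rows_cols=False)
             for _, g in plots.groupby("trial")],
            ignore_index=True,
        )
        two_step = blues_across_trials(within).set_index("genotype")["blue"]
        # joint oracle: OLS on plot data with trial + genotype factors
        Xg = pd.get_dummies(plots["genotype"]).to_numpy(float)
        Xt = pd.get_dummies(plots["trial"]).to_numpy(float)[:, 1:]
        X = np.hstack([Xg, Xt])
        beta, *_ = np.linalg.lstsq(X, plots["value"].to_numpy(), rcond=None)
        joint = pd.Series(beta[: Xg.shape[1]], index=sorted(plots["genotype"].unique()))
        d_two = two_step - two_step.mean()
        d_joint = joint - joint.mean()
        assert np.allclose(d_two, d_joint.loc[d_two.index], atol=1e-6)

    def test_single_trial_genotype_warns(self):
        within = self.make_within()
        within = within.drop(within[(within.trial == "T2") & (within.genotype == "G0")].index)
        with pytest.warns(UserWarning, match="single trial"):
            blues_across_trials(within)


class TestHeritability:
    def test_formula_values(self):
        assert heritability({"g": 1.0}, 3, 2) == 1.0
        assert heritability({"g": 0.0, "residual": 1.0}, 3, 2) == 0.0
        # direct arithmetic: 3 / (3 + 0.6/3 + 0.4/2 + 1.2/6) = 5/6
        h = heritability({"g": 3.0, "gL": 0.6, "gT": 0.4, "residual": 1.2}, 3, 2)
        assert np.isclose(h, 5.0 / 6.0)

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            heritability({"g": 0.0}, 3, 2)

    def test_monotonicity(self):
        base = dict(g=2.0, gL=0.5, gT=0.5, residual=1.0)
        h0 = heritability(base, 3, 2)
        for k in ("gL", "gT", "residual"):
            worse = dict(base)
            worse[k] = base[k] * 2
            assert heritability(worse, 3, 2) < h0
        better = dict(base, g=3.0)
        assert heritability(better, 3, 2) > h0
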