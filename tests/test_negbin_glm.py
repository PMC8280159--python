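import numpy as np
import pytest
import statsmodels.api as sm

from dlnmkit.errors import ComparisonError, RankDeficiencyError
from dlnmkit.negbin import (build_design, compare_aic, fit_candidate_set,
                            fit_negbin)
from dlnmkit.simulate import SimConfig, generate_counts, generate_prevalence_panel

from conftest import simulate_panel


class TestBuildDesign:
    def test_column_count_arithmetic(self):
        # 1 intercept + 16 cb + (2-1) country + (8-1) age + 1 gender
        # + (3-1) year + 7 interaction = 35
        cfg = SimConfig(seed=5, n_countries=2, registries_per_country=1)
        panel = generate_prevalence_panel(cfg)
        sim = generate_counts(cfg, panel)
        dm = build_design(sim.records, sim.cross_basis)
        assert dm.n_params == 1 + 16 + 1 + 7 + 1 + 2 + 7

    def test_single_country_no_dummies(self):
        cfg = SimConfig(seed=5, n_countries=1, registries_per_country=2)
        panel = generate_prevalence_panel(cfg)
        sim = generate_counts(cfg, panel)
        dm = build_design(sim.records, sim.cross_basis)
        assert not any(c.startswith("country[") for c in dm.column_names)

    def test_row_permutation_equivariance(self, small_sim):
        _, _, sim = small_sim
        dm = build_design(sim.records, sim.cross_basis)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sim.records))
        from dlnmkit.crossbasis import CrossBasis
        cb_p = CrossBasis(matrix=sim.cross_basis.matrix[perm],
                          exposure_spec=sim.cross_basis.exposure_spec,
                          lag_spec=sim.cross_basis.lag_spec,
                          lag_max=sim.cross_basis.lag_max)
        dm_p = build_design([sim.records[i] for i in perm], cb_p)
        np.testing.assert_array_equal(dm_p.X, dm.X[perm])
        assert dm_p.column_names == dm.column_names

    def test_rank_deficiency_names_columns(self, small_sim):
        _, _, sim = small_sim
        from dlnmkit.crossbasis import CrossBasis
        bad = sim.cross_basis.matrix.copy()
        bad[:, 1] = bad[:, 0]  # duplicate a cross-basis column
        cb = CrossBasis(matrix=bad, exposure_spec=sim.cross_basis.exposure_spec,
                        lag_spec=sim.cross_basis.lag_spec, lag_max=30)
        with pytest.raises(RankDeficiencyError, match="cb_"):
            build_design(sim.records, cb)

    def test_reference_levels_documented(self, small_sim):
        _, _, sim = small_sim
        dm = build_design(sim.records, sim.cross_basis)
        assert dm.reference_levels["gender"] == "F"
        assert dm.reference_levels["age_group"] == "40-44"


class TestFitNegbin:
    def test_poisson_limit_matches_poisson_glm(self):
        # huge theta => effectively Poisson data; compare with the
        # independent statsmodels Poisson GLM route
        cfg, sim = simulate_panel(seed=21, n_countries=4, theta=1e7)
        dm = build_design(sim.records, sim.cross_basis)
        fit = fit_negbin(dm, theta=1e8)
        glm = sm.GLM(dm.y, dm.X, family=sm.families.Poisson(),
                     offset=dm.offset).fit()
        np.testing.assert_allclose(fit.coefficients, glm.params, atol=1e-4)
        # free estimation also drifts to a near-Poisson dispersion
        assert fit_negbin(dm).theta > 1e3

    def test_parameter_recovery(self, medium_fit):
        sim, dm, fit, _ = medium_fit
        idx = dm.cb_indices()
        se = np.sqrt(np.diag(fit.model_vcov))[idx]
        err = fit.coefficients[idx] - sim.true_beta
        assert np.all(np.abs(err) < 5 * se)
        assert abs(fit.theta - sim.config.theta) / sim.config.theta < 0.2

    def test_loglik_dominates_truth(self, medium_fit):
        # ML estimate cannot have lower likelihood than the truth
        from dlnmkit.negbin import _nb_loglik
        sim, dm, fit, _ = medium_fit
        cfg = sim.config
        beta_true = np.zeros(dm.n_params)
        names = dm.column_names
        beta_true[names.index("intercept")] = cfg.alpha
        beta_true[dm.cb_indices()] = sim.true_beta
        for i, c in enumerate(cfg.countries):
            if f"country[{c}]" in names:
                beta_true[names.index(f"country[{c}]")] = \
                    cfg.country_effects[i] - cfg.country_effects[0]
        beta_true[names.index("intercept")] += cfg.country_effects[0]
        for i, b in enumerate(cfg.age_bands):
            if f"age[{b}]" in names:
                beta_true[names.index(f"age[{b}]")] = \
                    cfg.age_effects[i] - cfg.age_effects[0]
        beta_true[names.index("intercept")] += cfg.age_effects[0]
        beta_true[names.index("gender[M]")] = (cfg.gender_effect
                                              + cfg.interaction_effects[0])
        for i, y in enumerate(cfg.outcome_years):
            if f"year[{y}]" in names:
                beta_true[names.index(f"year[{y}]")] = \
                    cfg.year_effects[i] - cfg.year_effects[0]
        beta_true[names.index("intercept")] += cfg.year_effects[0]
        for i, b in enumerate(cfg.age_bands):
            key = f"age[{b}]:gender[M]"
            if key in names:
                beta_true[names.index(key)] = (cfg.interaction_effects[i]
                                               - cfg.interaction_effects[0])
        mu_true = np.exp(dm.X @ beta_true + dm.offset)
        ll_true = _nb_loglik(dm.y, mu_true, cfg.theta)
        assert fit.loglik >= ll_true

    def test_score_zero_at_optimum(self, medium_fit):
        from dlnmkit.negbin import score_vectors
        _, dm, fit, _ = medium_fit
        grad = score_vectors(fit, dm).sum(axis=0)
        assert np.linalg.norm(grad) < 1e-6 * dm.n_obs

    def test_offset_contract(self, small_fit):
        # scaling populations by c shifts the intercept by -log c only
        sim, dm, fit = small_fit
        c = 7.0
        from dataclasses import replace
        dm2 = replace(dm, offset=dm.offset + np.log(c))
        fit2 = fit_negbin(dm2)
        i0 = dm.column_names.index("intercept")
        delta = fit2.coefficients - fit.coefficients
        assert abs(delta[i0] + np.log(c)) < 1e-6
        delta[i0] = 0.0
        assert np.abs(delta).max() < 1e-6
        assert abs(fit2.theta - fit.theta) / fit.theta < 1e-4

    def test_aic_formula(self, small_fit):
        _, dm, fit = small_fit
        assert fit.aic == pytest.approx(
            -2 * fit.loglik + 2 * (dm.n_params + 1))

    def test_vcov_symmetric_psd(self, small_fit):
        _, _, fit = small_fit
        V = fit.model_vcov
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.linalg.eigvalsh(V).min() > 0

    def test_fixed_theta(self, small_fit):
        _, dm, _ = small_fit
        fit = fit_negbin(dm, theta=5.0)
        assert fit.theta == 5.0
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * dm.n_params)

    def test_converged_flag_not_exception(self, small_fit):
        _, dm, _ = small_fit
        fit = fit_negbin(dm, max_iter=1, tol=0.0)
        assert fit.converged is False


class TestCompareAic:
    def test_identical_fits_zero_delta(self, small_fit):
        _, dm, fit = small_fit
        fit2 = fit_negbin(dm)
        table = compare_aic([fit, fit2])
        assert table.delta_aic.iloc[1] == pytest.approx(0.0, abs=1e-6)

    def test_mismatched_data_rejected(self, small_fit):
        _, dm, fit = small_fit
        cfg, sim2 = simulate_panel(seed=99, n_countries=3,
                                   registries_per_country=2)
        dm2 = build_design(sim2.records, sim2.cross_basis)
        with pytest.raises(ComparisonError):
            compare_aic([fit, fit_negbin(dm2)])

    def test_candidate_preset_four_rows(self, small_sim):
        _, _, sim = small_sim
        fits = fit_candidate_set(sim.records, sim.histories,
                                 full_cb=sim.cross_basis)
        table = compare_aic(fits)
        assert len(table) == 4
        assert set(table.label) == {
            "full_df4_interaction", "df4_no_interaction",
            "df3_interaction", "df3_no_interaction"}

    def test_null_interaction_favors_smaller_model(self):
        # simulation under the null: zero interaction -> the reduced model
        # wins on average through the AIC penalty
        deltas = []
        for seed in range(12):
            cfg, sim = simulate_panel(
                seed=200 + seed, n_countries=4,
                interaction_effects=np.zeros(8))
            dm_full = build_design(sim.records, sim.cross_basis)
            dm_red = build_design(sim.records, sim.cross_basis,
                                  interaction=False)
            deltas.append(fit_negbin(dm_full).aic - fit_negbin(dm_red).aic)
        assert np.mean(deltas) > 0
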