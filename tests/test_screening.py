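import numpy as np
import pytest
from scipy import stats

import doeopt as dp
from doeopt.screening import lenth_pse


class TestFirstOrderFit:
    def test_intercept_is_grand_mean_on_balanced_matrix(self, pb16):
        fit = dp.fit_first_order(pb16, pb16.responses, allow_aliased=True)
        assert fit.intercept == pytest.approx(537.3125, abs=1e-9)
        assert fit.intercept == pytest.approx(pb16.responses.mean(), abs=1e-9)

    def test_full_screen_fit_names_aliased_columns(self, pb16):
        with pytest.raises(ValueError, match="ethanol"):
            dp.fit_first_order(pb16, pb16.responses)
        fit = dp.fit_first_order(pb16, pb16.responses, allow_aliased=True)
        assert set(fit.aliased_factors) == {"ethanol", "potassium_chloride"}

    def test_saturated_fit_r_squared_matches_reported_value(self, pb16):
        fit = dp.fit_first_order(pb16, pb16.responses, allow_aliased=True)
        assert fit.r_squared == pytest.approx(0.8353, abs=5e-5)

    def test_reduced_fit_solves_the_hand_built_normal_equations(self, pb16):
        """Three-column refit equals the directly solved 3x3 system."""
        names = ["amino_acids", "temperature", "urea"]
        fit = dp.fit_first_order(pb16, pb16.responses, names)
        idx = [pb16.factor_names.index(n) for n in names]
        X = pb16.matrix[:, idx]
        y = pb16.responses.to_numpy()
        XtX = X.T @ X
        assert np.array_equal(
            XtX, np.array([[16, -4, -4], [-4, 16, 0], [-4, 0, 16]])
        )
        # balanced columns: intercept = grand mean, slopes from X'X b = X'(y - ybar)
        hand = np.linalg.solve(XtX, X.T @ (y - y.mean()))
        assert fit.intercept == pytest.approx(537.3125, abs=1e-9)
        assert fit.coefficients.to_numpy() == pytest.approx(hand, abs=1e-9)

    def test_residual_identities(self, pb16):
        fit = dp.fit_first_order(pb16, pb16.responses, allow_aliased=True)
        y = pb16.responses.to_numpy()
        assert fit.fitted_values + fit.residuals == pytest.approx(y, rel=1e-9)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)
        assert pb16.matrix.T @ fit.residuals == pytest.approx(
            np.zeros(14), abs=1e-7
        )

    def test_exact_linear_response_recovered_on_orthogonal_design(self):
        design = dp.generate_plackett_burman(12, 11)
        beta = np.arange(1.0, 12.0)
        y = 50.0 + design.matrix @ beta
        fit = dp.fit_first_order(design, y)
        assert fit.intercept == pytest.approx(50.0, abs=1e-9)
        assert fit.coefficients.to_numpy() == pytest.approx(beta, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_too_many_parameters_raises(self, pb16):
        tall = dp.Design("custom", pb16.matrix[:4], pb16.factor_names)
        with pytest.raises(ValueError, match="exceed"):
            dp.fit_first_order(tall, pb16.responses.iloc[:4])


class TestMainEffects:
    def test_study_contrasts(self, pb16):
        effects = dp.main_effects(pb16, pb16.responses)
        temp = effects.table.loc["temperature"]
        assert temp["mean_plus"] == pytest.approx(672.75)
        assert temp["mean_minus"] == pytest.approx(401.875)
        assert temp["main_effect"] == pytest.approx(270.875)
        assert effects.table.loc["amino_acids", "main_effect"] == pytest.approx(6.375)

    def test_effect_table_invariants(self, pb16):
        tab = dp.main_effects(pb16, pb16.responses).table
        assert np.allclose(tab["main_effect"], tab["mean_plus"] - tab["mean_minus"])
        assert np.allclose(tab["half_effect"], tab["main_effect"] / 2)
        assert sorted(tab["rank"]) == list(range(1, 15))
        by_rank = tab.sort_values("rank")["main_effect"].abs().to_numpy()
        assert np.all(np.diff(by_rank) <= 1e-12)

    def test_constant_response_gives_zero_effects(self):
        design = dp.generate_plackett_burman(8, 5)
        effects = dp.main_effects(design, np.full(8, 42.0))
        assert np.allclose(effects.table["main_effect"], 0.0)

    def test_three_level_design_is_rejected(self, bbd13):
        with pytest.raises(ValueError, match="two-level"):
            dp.main_effects(bbd13, bbd13.responses)

    def test_half_effects_equal_saturated_ols_on_orthogonal_design(self):
        design = dp.generate_plackett_burman(12, 11)
        rng = np.random.default_rng(11)
        y = rng.normal(100, 20, 12)
        effects = dp.main_effects(design, y)
        fit = dp.fit_first_order(design, y)
        assert effects.table["half_effect"].to_numpy() == pytest.approx(
            fit.coefficients.to_numpy(), abs=1e-9
        )

    def test_run_permutation_invariance(self, pb16):
        perm = np.random.default_rng(3).permutation(16)
        shuffled = dp.Design("custom", pb16.matrix[perm], pb16.factor_names)
        a = dp.main_effects(pb16, pb16.responses).table
        b = dp.main_effects(shuffled, pb16.responses.to_numpy()[perm]).table
        assert np.allclose(a["main_effect"], b["main_effect"])

    def test_response_shift_moves_only_the_intercept(self, pb16):
        y = pb16.responses.to_numpy()
        base_eff = dp.main_effects(pb16, y).table["main_effect"]
        shift_eff = dp.main_effects(pb16, y + 100.0).table["main_effect"]
        assert np.allclose(base_eff, shift_eff)
        f0 = dp.fit_first_order(pb16, y, allow_aliased=True)
        f1 = dp.fit_first_order(pb16, y + 100.0, allow_aliased=True)
        assert f1.intercept - f0.intercept == pytest.approx(100.0, abs=1e-8)
        assert f1.coefficients.to_numpy() == pytest.approx(
            f0.coefficients.to_numpy(), abs=1e-8
        )


class TestSelection:
    def test_top_m_returns_largest_magnitudes(self):
        design = dp.generate_plackett_burman(8, 5)
        y = design.matrix @ np.array([10.0, 0.1, 0.2, 0.05, 0.12])
        effects = dp.main_effects(design, y)
        assert dp.select_significant(effects, "top_m", 1) == ["x1"]
        assert set(dp.select_significant(effects, "top_m", 3)) == {"x1", "x3", "x5"}
        with pytest.raises(ValueError, match="top"):
            dp.select_significant(effects, "top_m", 6)

    def test_top3_on_study_data_ranks_by_contrast_magnitude(self, pb16):
        effects = dp.main_effects(pb16, pb16.responses)
        top3 = dp.select_significant(effects, "top_m", 3)
        ranked = (
            effects.table["main_effect"].abs().sort_values(ascending=False).index[:3]
        )
        assert top3 == list(ranked)
        assert effects.table["significant"].sum() == 3

    def test_lenth_pse_on_a_known_vector(self):
        effects = np.array([10.0, 0.1, 0.2, 0.05, 0.12])
        # s0 = 1.5*median = 0.18; |10| > 2.5*s0 is trimmed; PSE = 1.5*median(rest)
        assert lenth_pse(effects) == pytest.approx(1.5 * 0.11)

    def test_lenth_screen_power_on_simulated_designs(self):
        """Three 5-sigma effects among 11 columns are found in >=90% of reps."""
        design = dp.generate_plackett_burman(12, 11)
        X = design.matrix
        slopes = np.zeros(11)
        slopes[:3] = 2.5  # main effect = 2*slope = 5 sigma at sigma=1
        hits = 0
        n_reps = 500
        for ss in np.random.SeedSequence(20240).spawn(n_reps):
            rng = np.random.default_rng(ss)
            y = X @ slopes + rng.normal(0.0, 1.0, 12)
            effects = dp.main_effects(design, y)
            chosen = dp.select_significant(effects, "lenth_pse", 0.05)
            if {"x1", "x2", "x3"} <= set(chosen):
                hits += 1
        assert hits / n_reps >= 0.90

    def test_lenth_margin_uses_one_third_dof(self):
        design = dp.generate_plackett_burman(12, 11)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 12)
        effects = dp.main_effects(design, y)
        dp.select_significant(effects, "lenth_pse", 0.05)
        pse = lenth_pse(effects.table["main_effect"].to_numpy())
        margin = stats.t.ppf(0.975, 11 / 3) * pse
        expected = effects.table["main_effect"].abs() > margin
        assert (effects.table["significant"] == expected).all()
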