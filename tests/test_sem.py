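import numpy as np
import pytest

import gsemkit as gk
from gsemkit import presets
from gsemkit.sem import (
    FactorModelSpec,
    ModelSpecError,
    compare_models,
    fit_dwls,
    fit_indices,
    parse_model,
    sandwich_se,
)
from gsemkit.synthetic import true_cov_structure

TRAITS9 = presets.FOURFACTOR9_TRAITS


def _triad_matrix(r12=0.56, r13=0.48, r23=0.42):
    return np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])


class TestParseModel:
    def test_fourfactor_spec_parses_with_cross_loadings(self):
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        assert len(spec.factors) == 4
        bd2_jpn = [(f, t) for f, t in spec.free_loadings if t == "BD2_JPN"]
        assert len(bd2_jpn) == 2  # loads on F1 and F2
        bd1_jpn = [(f, t) for f, t in spec.free_loadings if t == "BD1_JPN"]
        assert {f for f, _ in bd1_jpn} == {"F3", "F4"}
        assert spec.q == 12 + 6 + 9

    def test_unknown_trait_name_error(self):
        with pytest.raises(ModelSpecError, match="'X'"):
            parse_model("factor F1: X", ["A", "B"])

    def test_saturated_request(self):
        spec = parse_model("saturated", ["A", "B", "C"])
        assert spec.q == spec.t_star == 6
        assert spec.t_star - spec.q == 0

    def test_fix_statement_removes_free_parameter(self):
        text = "factor F1: A B C\nfix F1->C 0.5"
        spec = parse_model(text, ["A", "B", "C"])
        assert ("F1", "C") not in spec.free_loadings
        assert len(spec.free_loadings) == 2

    def test_overparameterized_rejected(self):
        # two traits: t* = 3 but q = 2 loadings + 2 residuals = 4
        with pytest.raises(ModelSpecError, match="identif"):
            parse_model("factor F1: A B", ["A", "B"])

    def test_empty_text_rejected(self):
        with pytest.raises(ModelSpecError, match="empty"):
            parse_model("  \n", ["A"])


class TestFitDwls:
    def test_saturated_model_fits_exactly(self):
        S = _triad_matrix()
        fit = fit_dwls(parse_model("saturated", ["A", "B", "C"]), S, np.eye(6) * 1e-4)
        assert fit.chi2 == 0.0
        assert fit.srmr == 0.0
        assert fit.cfi == 1.0
        assert np.allclose(fit.implied, S)

    def test_triad_closed_form(self):
        r12, r13, r23 = 0.56, 0.48, 0.42
        S = _triad_matrix(r12, r13, r23)
        spec = parse_model("factor F1: A B C", ["A", "B", "C"])
        fit = fit_dwls(spec, S, np.eye(6) * 1e-4)
        lam, _, _ = spec.matrices(fit.theta)
        expected = [np.sqrt(r12 * r13 / r23), np.sqrt(r12 * r23 / r13),
                    np.sqrt(r13 * r23 / r12)]
        assert np.allclose(lam[:, 0], expected, atol=1e-6)

    def test_noiseless_fourfactor_recovery_including_negative_sign(self):
        truth = true_cov_structure(presets.fourfactor9(seed=0))
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        fit = fit_dwls(spec, truth.s_corr, np.eye(45) * 1e-4, seed=0)
        lam, psi, theta_d = spec.matrices(fit.theta)
        assert np.max(np.abs(lam - truth.loadings)) < 1e-3
        assert np.max(np.abs(psi - truth.psi)) < 1e-3
        assert lam[TRAITS9.index("BD2_JPN"), 0] < 0  # negative cross-loading
        assert fit.converged

    def test_trait_reordering_invariance(self):
        truth = true_cov_structure(presets.fourfactor9(seed=0))
        perm = np.array([2, 0, 5, 8, 1, 7, 3, 6, 4])
        traits_p = [TRAITS9[i] for i in perm]
        spec_a = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        spec_b = parse_model(presets.FOURFACTOR9_MODEL_TEXT, traits_p)
        fit_a = fit_dwls(spec_a, truth.s_corr, np.eye(45) * 1e-4, seed=0)
        fit_b = fit_dwls(spec_b, truth.s_corr[np.ix_(perm, perm)],
                         np.eye(45) * 1e-4, seed=0)
        lam_a, _, _ = spec_a.matrices(fit_a.theta)
        lam_b, _, _ = spec_b.matrices(fit_b.theta)
        assert np.allclose(lam_a[perm], lam_b, atol=1e-6)

    def test_standardized_solution_unit_implied_variances(self, nine_trait_run):
        _, _, _, structure = nine_trait_run
        std = gk.standardize(structure, v_method="jackknife")
        sm = gk.smooth_to_psd(std.S_corr)
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        fit = fit_dwls(spec, sm, std.V_corr, seed=0, n_starts=1)
        assert np.allclose(np.diag(fit.implied), 1.0, atol=1e-4)
        std_lam = fit.standardized_loadings()
        lam, psi, theta_d = spec.matrices(fit.theta)
        d = np.diag(std_lam @ psi @ std_lam.T) + theta_d / np.diag(fit.implied)
        assert np.allclose(d, 1.0, atol=1e-6)

    def test_negative_residuals_flagged(self):
        truth = true_cov_structure(presets.fourfactor9(seed=0))
        S = truth.s_corr.copy()
        # inflate one trait's correlations so its residual goes negative
        i = 0
        S[i, 1:] *= 1.12
        S[1:, i] *= 1.12
        S = gk.smooth_to_psd(S)
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        fit = fit_dwls(spec, S, np.eye(45) * 1e-4, seed=0)
        _, _, theta_d = spec.matrices(fit.theta)
        if theta_d.min() < 0:
            assert fit.negative_residuals
        fit_nn = fit_dwls(spec, S, np.eye(45) * 1e-4, seed=0,
                          nonneg_residuals=True)
        _, _, theta_nn = fit_nn.spec.matrices(fit_nn.theta)
        assert theta_nn.min() >= 0


class TestSandwichSe:
    def test_information_matching_identity(self):
        """When V equals the inverse DWLS weight matrix, the sandwich
        collapses to the bread (Delta' W Delta)^-1."""
        truth = true_cov_structure(presets.fourfactor9(seed=0))
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        V = np.diag(np.full(45, 2.5e-4))
        fit = fit_dwls(spec, truth.s_corr, V, seed=0)
        # independent finite-difference Jacobian
        step = 1e-6
        q = len(fit.theta)
        J = np.empty((45, q))
        for k in range(q):
            e = np.zeros(q)
            e[k] = step
            J[:, k] = (spec.implied_sigma(fit.theta + e)
                       - spec.implied_sigma(fit.theta - e)) / (2 * step)
        W = np.diag(1.0 / np.diag(V))
        bread = np.linalg.inv(J.T @ W @ J)
        assert np.allclose(sandwich_se(fit, V), np.sqrt(np.diag(bread)), atol=1e-8)

    def test_fixed_parameter_has_no_se_row(self):
        text = "factor F1: A B C\nfix F1->C 0.6"
        spec = parse_model(text, ["A", "B", "C"])
        S = _triad_matrix()
        fit = fit_dwls(spec, S, np.eye(6) * 1e-4)
        table = fit.params()
        assert "F1->C" not in set(table["parameter"])
        assert len(table) == spec.q


class TestFitIndices:
    def test_exact_fit_limits(self):
        truth = true_cov_structure(presets.fourfactor9(seed=0))
        spec = parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9)
        fit = fit_dwls(spec, truth.s_corr, np.eye(45) * 1e-4, seed=0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.srmr == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == pytest.approx(1.0, abs=1e-8)

    def test_independence_model_as_target_gives_cfi_zero(self, nine_trait_run):
        _, _, _, structure = nine_trait_run
        std = gk.standardize(structure, v_method="jackknife")
        sm = gk.smooth_to_psd(std.S_corr)
        # a model with no factors: every trait is its own residual
        spec = FactorModelSpec(traits=list(TRAITS9), factors=[], loadings={})
        fit = fit_dwls(spec, sm, std.V_corr, seed=0, efa_start=False,
                       compute_se=False)
        assert fit.cfi == pytest.approx(0.0, abs=1e-10)

    def test_worked_example_matches_hand_calculation(self):
        """Four-trait one-factor fit: chi2, SRMR, AIC recomputed from the
        definitions with explicit loops."""
        lam = np.array([0.7, 0.6, 0.5, 0.4])
        S = np.outer(lam, lam)
        np.fill_diagonal(S, 1.0)
        S[0, 1] += 0.03
        S[1, 0] += 0.03  # deliberate misfit
        rng = np.random.default_rng(0)
        V = np.diag(rng.uniform(1e-4, 3e-4, size=10))
        spec = parse_model("factor F1: A B C D", ["A", "B", "C", "D"])
        fit = fit_dwls(spec, S, V, seed=0)
        s = gk.vech(S)
        sig = gk.vech(fit.implied)
        # spreadsheet-style recomputation
        resid = s - sig
        vp = np.diag(1.0 / np.diag(V))  # V diagonal -> pinv is elementwise
        chi2 = float(resid @ vp @ resid)
        srmr = np.sqrt(np.mean(resid ** 2))
        aic = chi2 + 2 * spec.q
        assert fit.chi2 == pytest.approx(chi2, abs=1e-8)
        assert fit.srmr == pytest.approx(srmr, abs=1e-8)
        assert fit.aic == pytest.approx(aic, abs=1e-8)


class TestCompareModels:
    def test_restricted_model_preferred_when_exact(self):
        lam = np.array([0.7, 0.6, 0.5, 0.4])
        S = np.outer(lam, lam)
        np.fill_diagonal(S, 1.0)
        spec1 = parse_model("factor F1: A B C D", ["A", "B", "C", "D"])
        spec_sat = parse_model("saturated", ["A", "B", "C", "D"])
        V = np.eye(10) * 1e-4
        f1 = fit_dwls(spec1, S, V)
        fsat = fit_dwls(spec_sat, S, V)
        table = compare_models([f1, fsat])
        # both fit exactly (chi2 = 0): the restricted model wins on q
        assert table.iloc[0]["q"] == spec1.q
        assert table.iloc[0]["aic"] < table.iloc[1]["aic"]
        assert table["delta_aic"].iloc[0] == 0.0

    def test_identical_fits_tie_broken_by_q(self):
        S = _triad_matrix()
        V = np.eye(6) * 1e-4
        # triad with free residuals is itself saturated (q = t* = 6)
        f1 = fit_dwls(parse_model("factor F1: A B C", ["A", "B", "C"]), S, V)
        fsat = fit_dwls(parse_model("saturated", ["A", "B", "C"]), S, V)
        table = compare_models([f1, fsat])
        assert np.allclose(table["delta_aic"], 0.0)
        assert list(table["q"]) == sorted(table["q"])

    def test_mismatched_inputs_rejected(self):
        S = _triad_matrix()
        V = np.eye(6) * 1e-4
        f1 = fit_dwls(parse_model("factor F1: A B C", ["A", "B", "C"]), S, V)
        S2 = _triad_matrix(0.3, 0.2, 0.1)
        f2 = fit_dwls(parse_model("factor F1: A B C", ["A", "B", "C"]), S2, V)
        with pytest.raises(ValueError, match="identical"):
            compare_models([f1, f2])

    def test_model_selection_prefers_true_factor_count(self):
        """4-factor truth: AIC prefers the 4-factor over the 3-factor
        spec (small replicate count; the full simulation runs in the
        acceptance suite)."""
        wins = 0
        for s in range(5):
            panel, _ = gk.simulate_panel(presets.fourfactor9(seed=7100 + s))
            std = gk.standardize(gk.build_S_V(panel), v_method="jackknife")
            sm = gk.smooth_to_psd(std.S_corr)
            f4 = fit_dwls(parse_model(presets.FOURFACTOR9_MODEL_TEXT, TRAITS9),
                          sm, std.V_corr, n_starts=1, compute_se=False)
            f3 = fit_dwls(parse_model(presets.THREEFACTOR9_MODEL_TEXT, TRAITS9),
                          sm, std.V_corr, n_starts=1, compute_se=False)
            wins += f4.aic < f3.aic
        assert wins >= 4
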