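"""Restricted design, FGLS, coefficient expansion, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from emovar import (
    SimConfig,
    adf_test,
    asymmetric_distances,
    build_design,
    center_scores,
    estimate_fgls,
    expand_coefficients,
    gen_dimension_scores,
    gen_structured_params,
    granger_tests,
    select_lag_order,
    simulate_panel,
    wald_symmetry,
)
from emovar.errors import DomainError, EstimationError
from emovar.types import EmotionPanel, StructuredParams, replace


def make_panel(values, exog=None, start="2020-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="D")
    freq = pd.DataFrame(values, index=idx,
                        columns=[f"e{i}" for i in range(np.shape(values)[1])])
    ex = None
    if exog is not None:
        ex = pd.DataFrame(exog, index=idx,
                          columns=[f"X_{j+1}" for j in range(np.shape(exog)[1])])
    return EmotionPanel(freq=freq, exog=ex)


class TestBuildDesign:
    def test_shared_column_count_formula(self):
        # N=2, K=1, M=0 -> 4K+6 = 10 shared columns
        cfg = SimConfig(n_emotions=2, n_dims=1, n_days=30, n_exog=0,
                        exog_break_fractions=(), seed=0)
        dims = center_scores(gen_dimension_scores(cfg))
        _, coeffs = gen_structured_params(dims, cfg)
        panel = simulate_panel(coeffs, cfg)
        design = build_design(panel, dims, asymmetric_distances(dims))
        assert design.n_shared == 10
        assert design.X.shape == (2 * 29, 10)
        assert design.colnames[:3] == ["mu0", "mu_1", "mu_S"]

    def test_carryover_regressor_is_lagged_own_frequency(self, small_config,
                                                         small_system, small_panel):
        dims, _, _ = small_system
        cd = center_scores(dims)
        design = build_design(small_panel, cd, asymmetric_distances(cd))
        E = small_panel.freq.to_numpy()
        t_eff = small_panel.n_days - 1
        lam0_col = design.colnames.index("lam0")
        for i in (0, small_config.n_emotions - 1):
            block = design.X[i * t_eff : (i + 1) * t_eff, lam0_col]
            assert np.array_equal(block, E[:-1, i])

    def test_fitted_values_match_expanded_matrices(self, small_system, small_panel):
        dims, truth, coeffs = small_system
        cd = center_scores(dims)
        design = build_design(small_panel, cd, asymmetric_distances(cd))
        th = np.concatenate([truth.theta, truth.beta.ravel()])
        E, X = small_panel.freq.to_numpy(), small_panel.exog.to_numpy()
        pred = coeffs.alpha + E[:-1] @ coeffs.gamma.T + X[1:] @ coeffs.beta.T
        n, t_eff = small_panel.n_emotions, small_panel.n_days - 1
        got = (design.X @ th).reshape(n, t_eff).T
        assert np.max(np.abs(got - pred)) < 1e-10

    def test_rank_deficiency_reported(self, small_system):
        dims, _, coeffs = small_system
        cd = center_scores(dims)
        const = np.tile(coeffs.stationary_mean(), (40, 1))  # no variation at all
        panel = make_panel(const)
        design = build_design(panel, cd, asymmetric_distances(cd))
        with pytest.raises(EstimationError, match="rank"):
            estimate_fgls(design)


class TestEstimateFGLS:
    def test_known_scalar_sigma_gls_equals_ols(self, small_system, small_panel):
        dims, _, _ = small_system
        cd = center_scores(dims)
        design = build_design(small_panel, cd, asymmetric_distances(cd))
        ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        n = small_panel.n_emotions
        gls = estimate_fgls(design, sigma=3.7 * np.eye(n))
        got = np.concatenate([gls.theta, gls.beta.ravel()])
        assert np.max(np.abs(got - ols)) < 1e-8

    def test_noiseless_recovery_is_exact(self, small_config, small_system):
        dims, truth, coeffs = small_system
        quiet = replace(coeffs, sigma=np.zeros_like(coeffs.sigma))
        rng = np.random.default_rng(0)
        e0 = quiet.stationary_mean() * (1 + rng.uniform(-0.4, 0.4, quiet.n_emotions))
        cfg = replace(small_config, burn_in=0)
        panel = simulate_panel(quiet, cfg, initial_state=e0)
        cd = center_scores(dims)
        params = estimate_fgls(build_design(panel, cd, asymmetric_distances(cd)))
        assert np.max(np.abs(params.theta - truth.theta)) < 1e-8
        assert np.max(np.abs(params.beta - truth.beta)) < 1e-8

    def test_singular_sigma_hat_raises_with_diagnostic(self):
        # more emotions than days after lagging -> singular residual covariance
        cfg = SimConfig(n_emotions=12, n_days=10, n_dims=2, n_exog=0,
                        exog_break_fractions=(), burn_in=50, seed=1)
        dims = gen_dimension_scores(cfg)
        _, coeffs = gen_structured_params(dims, cfg)
        panel = simulate_panel(coeffs, cfg)
        cd = center_scores(dims)
        design = build_design(panel, cd, asymmetric_distances(cd))
        with pytest.raises(EstimationError, match="more days or fewer emotions"):
            estimate_fgls(design)

    def test_sigma_hat_self_consistent_with_residuals(self, small_system, small_panel):
        dims, _, _ = small_system
        cd = center_scores(dims)
        design = build_design(small_panel, cd, asymmetric_distances(cd))
        params = estimate_fgls(design)
        th = np.concatenate([params.theta, params.beta.ravel()])
        resid = (design.y - design.X @ th).reshape(
            design.n_emotions, design.n_obs
        ).T
        sig_final = resid.T @ resid / design.n_obs
        # two-step: Sigma-hat comes from OLS residuals; the GLS residual
        # covariance agrees within one iteration's tolerance
        denom = np.abs(params.sigma_hat).max()
        assert np.max(np.abs(sig_final - params.sigma_hat)) / denom < 0.05

    def test_rmse_decreases_with_sample_size(self):
        rmses = []
        for t in (200, 790, 3000):
            errs = []
            for rep in range(4):
                cfg = SimConfig(n_emotions=8, n_days=t, n_dims=2, n_exog=0,
                                exog_break_fractions=(), seed=100 + rep)
                dims = gen_dimension_scores(cfg)
                truth, coeffs = gen_structured_params(dims, cfg)
                panel = simulate_panel(coeffs, cfg)
                cd = center_scores(dims)
                params = estimate_fgls(
                    build_design(panel, cd, asymmetric_distances(cd))
                )
                errs.append(params.theta - truth.theta)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestExpandCoefficients:
    def test_round_trip_with_generated_truth(self, small_system):
        dims, truth, coeffs = small_system
        cd = center_scores(dims)
        again = expand_coefficients(truth, cd, asymmetric_distances(cd))
        assert np.array_equal(again.gamma, coeffs.gamma)

    def test_gamma_asymmetry_identity(self, small_system):
        # gamma_ij - gamma_ji telescopes through the distance asymmetry
        dims, truth, coeffs = small_system
        cd = center_scores(dims)
        dist = asymmetric_distances(cd)
        n = cd.n_emotions
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                want = (
                    (truth.tau_up - truth.tau_down)
                    @ (dist.up[i, j] - dist.down[i, j])
                    + truth.tau_S * (cd.dict_size[i] - cd.dict_size[j])
                )
                got = coeffs.gamma[i, j] - coeffs.gamma[j, i]
                assert got == pytest.approx(want, abs=1e-12)

    def test_zero_tau_gives_diagonal_gamma(self, small_system):
        dims, truth, _ = small_system
        cd = center_scores(dims)
        theta = truth.theta.copy()
        k = truth.k
        theta[2 * k + 4 :] = 0.0  # whole tau block
        diag_truth = StructuredParams(k=k, theta=theta, beta=truth.beta)
        coeffs = expand_coefficients(diag_truth, cd, asymmetric_distances(cd))
        off = ~np.eye(cd.n_emotions, dtype=bool)
        assert np.all(coeffs.gamma[off] == 0.0)


class TestADF:
    def test_white_noise_rejects_unit_root(self):
        rng = np.random.default_rng(0)
        stat, reject = adf_test(rng.standard_normal(790))
        assert reject

    def test_constant_series_undefined(self):
        with pytest.raises(DomainError):
            adf_test(np.ones(100))

    def test_short_series_rejected(self):
        with pytest.raises(DomainError):
            adf_test(np.arange(10.0))


class TestLagOrder:
    def test_criteria_table_shape(self, small_panel):
        p_star, table = select_lag_order(small_panel, p_max=3)
        assert list(table.index) == [1, 2, 3]
        assert set(table.columns) == {"aic", "bic", "hqc"}
        assert 1 <= p_star <= 3

    def test_var2_data_selects_two_lags(self):
        rng = np.random.default_rng(42)
        n, t = 3, 1500
        g1 = np.diag([0.3, 0.25, 0.2])
        g2 = np.diag([0.5, 0.45, 0.55])  # dominant second lag
        E = np.zeros((t, n))
        for s in range(2, t):
            E[s] = 0.02 + g1 @ E[s - 1] + g2 @ E[s - 2] + 0.01 * rng.standard_normal(n)
        p_star, _ = select_lag_order(make_panel(E[200:]), p_max=4)
        assert p_star == 2


class TestGranger:
    def test_diagonal_not_applicable(self, small_panel):
        pmat = granger_tests(small_panel)
        assert np.isnan(np.diag(pmat.to_numpy())).all()

    def test_size_on_independent_white_noise(self):
        rng = np.random.default_rng(7)
        rejections, total = 0, 0
        for _ in range(30):
            E = rng.standard_normal((300, 4)) * 0.01 + 0.05
            pmat = granger_tests(make_panel(E)).to_numpy()
            off = pmat[~np.isnan(pmat)]
            rejections += (off < 0.05).sum()
            total += off.size
        assert 0.02 < rejections / total < 0.09

    def test_power_on_planted_causal_link(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(20):
            t = 500
            e1 = 0.01 * rng.standard_normal(t)
            e2 = np.zeros(t)
            for s in range(1, t):
                e2[s] = 0.5 * e1[s - 1] + 0.005 * rng.standard_normal()
            pmat = granger_tests(make_panel(np.column_stack([e1, e2])))
            if pmat.iloc[1, 0] < 0.001:
                hits += 1
        assert hits >= 19


class TestWaldSymmetry:
    def test_exact_null_point(self, small_system, small_panel):
        dims, _, _ = small_system
        cd = center_scores(dims)
        design = build_design(small_panel, cd, asymmetric_distances(cd))
        params = estimate_fgls(design)
        forced = params.theta.copy()
        names = params.names
        forced[names.index("tau_down_1")] = forced[names.index("tau_up_1")]
        equal = StructuredParams(k=params.k, theta=forced, beta=params.beta,
                                 vcov=params.vcov, sigma_hat=params.sigma_hat)
        chi2, df, p = wald_symmetry(equal, 1)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert df == 1 and p == pytest.approx(1.0)

    def test_requires_vcov(self, small_system):
        _, truth, _ = small_system
        with pytest.raises(EstimationError):
            wald_symmetry(truth, 1)

    def test_power_against_large_asymmetry(self):
        # truth with a big up/down gap on dimension 1 is rejected
        rejections, valid = 0, 0
        for rep in range(20):
            cfg = SimConfig(n_emotions=8, n_days=400, n_dims=2, n_exog=0,
                            exog_break_fractions=(), seed=300 + rep)
            dims = gen_dimension_scores(cfg)
            truth, coeffs = gen_structured_params(dims, cfg)
            theta = truth.theta.copy()
            names = truth.names
            theta[names.index("tau_up_1")] = 0.02
            theta[names.index("tau_down_1")] = -0.02
            truth = StructuredParams(k=2, theta=theta, beta=truth.beta,
                                     sigma_hat=truth.sigma_hat)
            cd = center_scores(dims)
            dist = asymmetric_distances(cd)
            coeffs = expand_coefficients(truth, cd, dist)
            if coeffs.spectral_radius() >= 1:
                continue
            valid += 1
            panel = simulate_panel(coeffs, cfg)
            params = estimate_fgls(build_design(panel, cd, dist))
            _, _, p = wald_symmetry(params, 1)
            rejections += p < 0.05
        assert valid >= 15
        assert rejections >= 0.95 * valid
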