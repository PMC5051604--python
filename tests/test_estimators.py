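"""Estimator correctness: hand-computable fixtures, oracle equivalences, invariants."""

import numpy as np
import pytest
from scipy.special import expit, logit

from drbench import (
    EstimationError,
    ObservedData,
    bcm,
    bootstrap_se,
    clever_covariate,
    fit_outcome_parametric,
    gcomp,
    iptw,
    matched_variance,
    ps_match,
    tmle,
    wls,
)

from conftest import toy_data


def _data(A, Y, W=None):
    A = np.asarray(A, float)
    if W is None:
        W = np.zeros((len(A), 8))
    return ObservedData(W=W, A=A, Y=np.asarray(Y, float))


class TestGcomp:
    def test_constant_difference(self):
        data = toy_data(n=20, seed=1)
        q = lambda a, W: W[:, 5] + np.broadcast_to(np.asarray(a, float), (W.shape[0],))
        assert gcomp(q, data).psi_hat == pytest.approx(1.0)

    def test_equals_stratification_oracle_on_saturated_design(self):
        # one binary covariate, arm-stratified saturated fit == the
        # stratified mean-difference estimator, exactly
        rng = np.random.default_rng(5)
        n = 20
        W = np.zeros((n, 8))
        W[:, 0] = np.r_[np.ones(10), -np.ones(10)]
        A = np.r_[1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1].astype(float)
        Y = rng.normal(size=n)
        data = ObservedData(W=W, A=A, Y=Y)
        q = fit_outcome_parametric(data, terms="W1", stratify_by_arm=True)
        est = gcomp(q, data)

        oracle = 0.0
        for w in (-1.0, 1.0):
            cell = W[:, 0] == w
            oracle += cell.mean() * (Y[cell & (A == 1)].mean() - Y[cell & (A == 0)].mean())
        assert est.psi_hat == pytest.approx(oracle, abs=1e-10)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            gcomp(lambda a, W: np.zeros(W.shape[0]), _data([], []))

    def test_model_se_flows_through(self):
        data = toy_data(n=200, seed=2, noise=1.0)
        q = fit_outcome_parametric(data, terms="main_terms")
        est = gcomp(q, data)
        assert np.isfinite(est.se) and est.ci_lo < est.psi_hat < est.ci_hi


class TestIPTW:
    def test_constant_ps_reduces_to_mean_difference(self):
        data = _data([1, 1, 0, 0], [2, 4, 1, 3])
        est = iptw(np.full(4, 0.5), data)
        assert est.psi_hat == pytest.approx(1.0)

    def test_hand_computed_hajek(self):
        data = _data([1, 1, 0, 0], [2, 3, 2, 0])
        g = np.array([0.8, 0.5, 0.5, 0.2])
        est = iptw(g, data)
        assert est.psi_hat == pytest.approx(8.5 / 3.25 - 4.0 / 3.25, abs=1e-12)

    def test_arm_means_respect_outcome_range(self):
        # the normalised estimator's arm means are convex combinations of Y
        rng = np.random.default_rng(6)
        data = toy_data(n=50, seed=3, noise=1.0)
        g = np.clip(rng.random(50), 0.01, 0.99)
        est = iptw(g, data)
        assert abs(est.psi_hat) <= data.Y.max() - data.Y.min() + 1e-12

    def test_empty_arm_rejected(self):
        with pytest.raises(EstimationError):
            iptw(np.full(3, 0.5), _data([1, 1, 1], [1, 2, 3]))


class TestWLS:
    def test_unit_weights_equal_ols(self):
        import statsmodels.api as sm

        data = toy_data(n=80, seed=4, noise=1.0)
        est = wls(np.full(80, 0.5), data)
        X = np.column_stack([np.ones(80), data.A, data.W])
        ols = sm.OLS(data.Y, X).fit()
        assert est.psi_hat == pytest.approx(ols.params[1], abs=1e-10)

    def test_noiseless_linear_truth_exact(self):
        data = toy_data(n=60, seed=5, effect=2.0, noise=0.0)
        rng = np.random.default_rng(7)
        g = np.clip(rng.random(60), 0.05, 0.95)
        assert wls(g, data).psi_hat == pytest.approx(2.0, abs=1e-8)

    def test_singular_design_rejected(self):
        data = toy_data(n=40, seed=6)
        with pytest.raises(EstimationError):
            wls(np.full(40, 0.5), data, terms="W6+W6")


class TestMatching:
    def test_identical_ps_twins_reduce_to_mean_difference(self):
        Y = [3.0, 5.0, 1.0, 2.0]
        data = _data([1, 1, 0, 0], Y)
        g = np.array([0.3, 0.6, 0.3, 0.6])  # each unit has an exact twin
        _, est = ps_match(g, data)
        assert est.psi_hat == pytest.approx(np.mean(Y[:2]) - np.mean(Y[2:]))

    def test_nearest_on_logit_scale(self):
        # treated PS 0.3; controls 0.2 and 0.4: logit distances 0.442 vs 0.539
        data = _data([1, 0, 0], [1.0, 10.0, 20.0])
        g = np.array([0.3, 0.4, 0.2])
        match, _ = ps_match(g, data)
        assert list(match.neighbors[0]) == [1]
        assert abs(logit(0.3) - logit(0.4)) < abs(logit(0.3) - logit(0.2))

    def test_ties_share_reuse_mass(self):
        data = _data([1, 0, 0], [1.0, 2.0, 4.0])
        g = np.array([0.5, 0.4, 0.6])  # both controls equidistant on the logit scale
        match, _ = ps_match(g, data)
        assert np.allclose(match.weights[0], [0.5, 0.5])
        assert match.K.sum() == pytest.approx(data.n)

    def test_infeasible_match_count(self):
        data = _data([1, 1, 0], [1, 2, 3])
        with pytest.raises(ValueError):
            ps_match(np.full(3, 0.5), data, M=2)


class TestBCM:
    def test_equals_matching_when_matched_covariates_coincide(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((5, 8))
        W = np.vstack([X, X])
        A = np.r_[np.ones(5), np.zeros(5)]
        Y = rng.normal(size=10)
        g = np.tile(np.linspace(0.3, 0.7, 5), 2)
        data = ObservedData(W=W, A=A, Y=Y)
        q = lambda a, Wx: 2.0 * Wx[:, 0] - Wx[:, 6]  # any fixed surface
        _, plain = ps_match(g, data)
        corrected = bcm(g, q, data)
        assert corrected.psi_hat == pytest.approx(plain.psi_hat, abs=1e-12)

    def test_hand_evaluated_six_row_fixture(self):
        # brute-force evaluation of the bias-corrected imputation formulas
        A = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        Y = np.array([5.0, 6.0, 4.0, 1.0, 2.0, 3.0])
        g = np.array([0.6, 0.7, 0.55, 0.35, 0.45, 0.5])
        W = np.zeros((6, 8))
        W[:, 5] = [0.0, 1.0, -1.0, 2.0, 0.5, -0.5]
        data = ObservedData(W=W, A=A, Y=Y)
        q = lambda a, Wx: np.broadcast_to(np.asarray(a, float), (Wx.shape[0],)) + 0.5 * Wx[:, 5]

        lp = logit(g)
        q0, q1 = q(np.zeros(6), W), q(np.ones(6), W)
        deltas = []
        for i in range(6):
            opp = np.flatnonzero(A != A[i])
            j = opp[np.argmin(np.abs(lp[i] - lp[opp]))]
            if A[i] == 1:
                y0 = Y[j] + q0[i] - q0[j]
                deltas.append(Y[i] - y0)
            else:
                y1 = Y[j] + q1[i] - q1[j]
                deltas.append(y1 - Y[i])
        est = bcm(g, q, data)
        assert est.psi_hat == pytest.approx(np.mean(deltas), abs=1e-12)

    def test_exact_under_correct_outcome_model_despite_poor_ps(self):
        data = toy_data(n=60, seed=9, effect=2.0, noise=0.0)
        q = fit_outcome_parametric(data, terms="main_terms", stratify_by_arm=True)
        g = np.clip(np.random.default_rng(10).random(60), 0.05, 0.95)  # junk PS
        assert bcm(g, q, data).psi_hat == pytest.approx(2.0, abs=1e-8)


class TestCleverCovariate:
    @pytest.mark.parametrize(
        "a, g, expected", [(1, 0.25, 4.0), (0, 0.25, -4.0 / 3.0), (1, 0.5, 2.0)]
    )
    def test_values(self, a, g, expected):
        got = clever_covariate(np.array([float(a)]), np.array([g]))[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_degenerate_ps_rejected(self):
        with pytest.raises(EstimationError):
            clever_covariate(np.array([1.0]), np.array([0.0]))


def _tmle_fixture(seed=11, n=8):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, 8))
    A = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    Y = rng.uniform(0.05, 0.95, size=n)
    g = rng.uniform(0.2, 0.8, size=n)
    q0 = rng.uniform(0.1, 0.9, size=n)
    q1 = rng.uniform(0.1, 0.9, size=n)
    q = lambda a, Wx: np.where(np.broadcast_to(np.asarray(a, float), (Wx.shape[0],)) == 1, q1, q0)
    return ObservedData(W=W, A=A, Y=Y), g, q, q0, q1


class TestTMLE:
    def test_zero_fluctuation_is_identity_update(self):
        rng = np.random.default_rng(12)
        n = 10
        W = rng.standard_normal((n, 8))
        A = np.r_[np.ones(5), np.zeros(5)]
        vals = rng.uniform(0.2, 0.8, size=n)
        shift = rng.uniform(-0.05, 0.05, size=n)
        q = lambda a, Wx: np.where(
            np.broadcast_to(np.asarray(a, float), (Wx.shape[0],)) == 1, vals + shift, vals
        )
        Y = np.where(A == 1, vals + shift, vals)  # Y* == Q*0 at observed A
        data = ObservedData(W=W, A=A, Y=Y)
        g = rng.uniform(0.3, 0.7, size=n)
        fluct, est = tmle(g, q, data, bounds=(0.0, 1.0))
        assert fluct.epsilon == pytest.approx(0.0, abs=1e-9)
        assert est.psi_hat == pytest.approx(gcomp(q, data).psi_hat, abs=1e-9)

    def test_epsilon_matches_grid_search_oracle(self):
        data, g, q, q0, q1 = _tmle_fixture()
        fluct, est = tmle(g, q, data, bounds=(0.0, 1.0))

        # independent one-parameter likelihood search
        h = data.A / g - (1 - data.A) / (1 - g)
        qs_obs = np.clip(np.where(data.A == 1, q1, q0), 1e-4, 1 - 1e-4)
        off = logit(qs_obs)

        def nll(eps):
            mu = expit(off + eps * h)
            return -np.sum(data.Y * np.log(mu) + (1 - data.Y) * np.log(1 - mu))

        grid = np.linspace(-3, 3, 60001)
        vals = np.array([nll(e) for e in grid])
        k = int(np.argmin(vals))
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(nll, bracket=(grid[k - 1], grid[k], grid[k + 1]),
                              options={"xtol": 1e-12})
        assert fluct.epsilon == pytest.approx(res.x, abs=1e-6)

        # plug-in with the oracle epsilon reproduces psi
        h1, h0 = 1.0 / g, -1.0 / (1.0 - g)
        qs1 = expit(logit(np.clip(q1, 1e-4, 1 - 1e-4)) + res.x * h1)
        qs0 = expit(logit(np.clip(q0, 1e-4, 1 - 1e-4)) + res.x * h0)
        assert est.psi_hat == pytest.approx(np.mean(qs1 - qs0), abs=1e-8)

    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_score_equation_and_bounds(self, seed):
        data, g, q, _, _ = _tmle_fixture(seed=seed, n=40)
        fluct, est = tmle(g, q, data, bounds=(0.0, 1.0))
        assert abs(est.diagnostics["score_residual"]) <= 1e-6
        for qs in (fluct.q_star0, fluct.q_star1):
            back = qs * (fluct.b_bound - fluct.a_bound) + fluct.a_bound
            assert (back >= fluct.a_bound).all() and (back <= fluct.b_bound).all()

    def test_outcome_outside_bounds_rejected(self):
        data, g, q, _, _ = _tmle_fixture()
        with pytest.raises(ValueError):
            tmle(g, q, data, bounds=(0.4, 0.6))
        with pytest.raises(ValueError):
            tmle(g, q, data, bounds=(1.0, 0.0))

    def test_weighted_regression_can_leave_range_while_tmle_cannot(self):
        # extreme weights + a high-leverage control: the weighted-regression
        # treatment coefficient escapes the endpoint range [0, 1]; the
        # targeted plug-in cannot, by construction
        A = np.array([1.0, 1.0, 0.0, 0.0, 0.0])
        Y = np.array([1.0, 0.95, 0.9, 0.4, 0.0])
        W = np.zeros((5, 8))
        W[:, 5] = [0.0, 0.5, 2.0, 2.5, 3.0]
        g = np.array([0.5, 0.5, 0.05, 0.5, 0.9])
        data = ObservedData(W=W, A=A, Y=Y)
        est_wls = wls(g, data, terms="W6")
        q = fit_outcome_parametric(data, terms="W6", stratify_by_arm=False)
        _, est_tmle = tmle(g, q, data, bounds=(0.0, 1.0))
        assert abs(est_wls.psi_hat) > 1.0
        assert abs(est_tmle.psi_hat) <= 1.0


class TestLocationEquivariance:
    def test_all_estimators_shift_invariant(self):
        data = toy_data(n=80, seed=16, noise=1.0)
        rng = np.random.default_rng(17)
        g = np.clip(rng.random(80), 0.1, 0.9)
        q = fit_outcome_parametric(data, terms="main_terms", stratify_by_arm=True)
        c = 7.3
        shifted = ObservedData(W=data.W, A=data.A, Y=data.Y + c)
        q_s = fit_outcome_parametric(shifted, terms="main_terms", stratify_by_arm=True)

        assert iptw(g, shifted).psi_hat == pytest.approx(iptw(g, data).psi_hat, abs=1e-8)
        assert wls(g, shifted).psi_hat == pytest.approx(wls(g, data).psi_hat, abs=1e-8)
        assert ps_match(g, shifted)[1].psi_hat == pytest.approx(
            ps_match(g, data)[1].psi_hat, abs=1e-8)
        assert bcm(g, q_s, shifted).psi_hat == pytest.approx(
            bcm(g, q, data).psi_hat, abs=1e-8)
        lo, hi = data.Y.min(), data.Y.max()
        t0 = tmle(g, q, data, bounds=(lo, hi))[1].psi_hat
        t1 = tmle(g, q_s, shifted, bounds=(lo + c, hi + c))[1].psi_hat
        assert t1 == pytest.approx(t0, abs=1e-8)


class TestMatchedVariance:
    def test_unique_matches_drop_conditional_reuse_term(self):
        # twin pairs -> every unit used exactly once -> the conditional
        # variance reduces to sum (d - psi)^2 / N^2
        Y = np.array([3.0, 5.0, 1.0, 2.0])
        data = _data([1, 1, 0, 0], Y)
        g = np.array([0.30, 0.60, 0.31, 0.61])
        match, est = ps_match(g, data)
        assert np.allclose(match.K, 1.0)
        cond = matched_variance(match, data, est.psi_hat, 1, conditional=True)
        expected = np.sqrt(np.sum((match.deltas - est.psi_hat) ** 2)) / 4.0
        assert cond == pytest.approx(expected, abs=1e-12)
        # the marginal (CI) form keeps a nonnegative reuse contribution
        assert est.se >= cond - 1e-12

    def test_constant_outcome_gives_zero_se(self):
        data = _data([1, 1, 0, 0], [2.0, 2.0, 2.0, 2.0])
        _, est = ps_match(np.array([0.3, 0.6, 0.31, 0.61]), data)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_small_sample_has_no_variance_estimate(self):
        data = _data([1, 0, 1], [1.0, 2.0, 3.0])
        match, est = ps_match(np.array([0.4, 0.5, 0.6]), data)
        assert np.isnan(est.se)
        with pytest.raises(EstimationError):
            matched_variance(match, data, est.psi_hat, 1)

    def test_agrees_with_bootstrap_on_fixture(self):
        rng = np.random.default_rng(18)
        n = 10
        data = _data(
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
            rng.normal(size=n),
            W=rng.standard_normal((n, 8)),
        )
        g = np.clip(rng.uniform(0.2, 0.8, size=n), 0.05, 0.95)
        _, est = ps_match(g, data)

        boot = []
        for _ in range(500):
            idx = rng.integers(0, n, size=n)
            if len(set(data.A[idx])) < 2:
                continue
            d = ObservedData(W=data.W[idx], A=data.A[idx], Y=data.Y[idx])
            try:
                boot.append(ps_match(g[idx], d)[1].psi_hat)
            except (ValueError, EstimationError):
                continue
        oracle = np.std(boot, ddof=1)
        assert est.se == pytest.approx(oracle, rel=0.25)


class TestBootstrap:
    def test_mean_bootstrap_matches_textbook_se(self):
        rng = np.random.default_rng(19)
        data = _data(
            np.r_[np.ones(100), np.zeros(100)], rng.normal(size=200),
            W=rng.standard_normal((200, 8)),
        )
        se = bootstrap_se(lambda d: d.Y.mean(), data, B=400, seed=0)
        assert se == pytest.approx(data.Y.std(ddof=1) / np.sqrt(200), rel=0.10)

    def test_deterministic_given_seed(self):
        data = toy_data(n=50, seed=20, noise=1.0)
        a = bootstrap_se(lambda d: d.Y.mean(), data, B=60, seed=3)
        b = bootstrap_se(lambda d: d.Y.mean(), data, B=60, seed=3)
        assert a == b

    def test_too_few_replicates_rejected(self):
        data = toy_data(n=50, seed=21)
        with pytest.raises(ValueError):
            bootstrap_se(lambda d: d.Y.mean(), data, B=10, seed=0)
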