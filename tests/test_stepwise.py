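import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from stepglm import (
    StepwiseGLMSelector,
    backward_stage,
    backward_step,
    bic,
    ebic,
    fit_glm,
    forward_stage,
    forward_step,
    get_family,
    loglik,
    make_dataset,
    stepwise_fit,
)
from tests.conftest import make_glm_data

GAUSS = get_family("gaussian")


class TestCriteria:
    def test_ebic_hand_value(self):
        # -2(-1) + 2/100 (log 100 + 2*0.5*log 1000)
        expected = 2.0 + 0.02 * (math.log(100) + math.log(1000))
        assert ebic(-1.0, 2, 100, 1000, 0.5) == pytest.approx(expected, abs=1e-12)
        assert ebic(-1.0, 2, 100, 1000, 0.5) == pytest.approx(2.230259, abs=1e-6)

    def test_bic_hand_value(self):
        # -2(-0.5) + 3*3*log(400)/400
        assert bic(-0.5, 3, 400, 3.0) == pytest.approx(1.0 + 9 * math.log(400) / 400, abs=1e-12)

    def test_eta2_zero_is_minus_two_loglik(self):
        assert bic(-0.7, 5, 250, 0.0) == pytest.approx(1.4, abs=1e-15)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-50, 50),
        st.integers(1, 40),
        st.integers(2, 10_000),
        st.integers(1, 10_000),
    )
    def test_ebic_at_eta1_zero_equals_bic_at_eta2_one(self, ll, size, n, p):
        assert ebic(ll, size, n, p, 0.0) == bic(ll, size, n, 1.0)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            ebic(0.0, 1, 100, 10, -0.1)
        with pytest.raises(ValueError):
            bic(0.0, 1, 100, -1.0)


class TestForwardStep:
    def test_picks_the_noiseless_signal(self, rng):
        X = rng.standard_normal((50, 3))
        y = 2.0 * X[:, 1]  # exact function of the second predictor
        data = make_dataset(X, y)
        j, fit = forward_step([0], data, GAUSS)
        assert j == 2
        assert fit.loglik == pytest.approx(
            loglik([0, 2], fit.beta, data, GAUSS), abs=1e-12
        )

    def test_duplicate_columns_tie_break_smallest_index(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, x, rng.standard_normal(40)])
        y = x + 0.1 * rng.standard_normal(40)
        j, _ = forward_step([0], make_dataset(X, y), GAUSS)
        assert j == 1

    def test_argmax_exists_under_pure_noise(self, rng):
        data, _ = make_glm_data(rng, 30, 4, "gaussian", beta=np.zeros(5))
        j, _ = forward_step([0], data, GAUSS)
        assert 1 <= j <= 4

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_screened_scan_matches_exact_scan(self, rng, family):
        data, _ = make_glm_data(rng, 150, 60, family, n_signals=4, signal=0.8)
        fam = get_family(family)
        j_exact, _ = forward_step([0], data, fam, screen_size=None)
        j_screen, _ = forward_step([0], data, fam, screen_size=10)
        assert j_exact == j_screen


class TestBackwardStep:
    def test_drops_noise_keeps_signal(self, rng):
        X = rng.standard_normal((80, 2))
        y = 3.0 * X[:, 0] + 0.05 * rng.standard_normal(80)
        data = make_dataset(X, y)
        j, fit = backward_step([0, 1, 2], [0], data, GAUSS)
        assert j == 2
        # removal loss verified against explicit leave-one-out fits
        keep1 = fit_glm([0, 1], data, GAUSS)
        keep2 = fit_glm([0, 2], data, GAUSS)
        assert keep1.loglik >= keep2.loglik
        assert fit.loglik == pytest.approx(keep1.loglik)

    def test_singleton_removable(self, rng):
        data, _ = make_glm_data(rng, 40, 2, "gaussian")
        j, _ = backward_step([0, 1, 2], [0, 1], data, GAUSS)
        assert j == 2

    def test_identical_noise_columns_tie_break(self, rng):
        z = rng.standard_normal(60)
        X = np.column_stack([rng.standard_normal(60), z, z])
        y = 2.0 * X[:, 0] + rng.standard_normal(60)
        data = make_dataset(X, y)
        j, _ = backward_step([0, 1, 2, 3], [0, 1], data, GAUSS)
        assert j == 2


class TestStages:
    def test_huge_eta1_stops_at_f0(self, rng):
        data, _ = make_glm_data(rng, 100, 10, "gaussian")
        F, _, trace = forward_stage(data, GAUSS, [0], eta1=1e6)
        assert F == [0]
        assert trace == []

    def test_pure_noise_adds_almost_nothing(self, rng):
        sizes = []
        for _ in range(10):
            data, _ = make_glm_data(rng, 200, 150, "gaussian", beta=np.zeros(151))
            F, _, _ = forward_stage(data, GAUSS, [0], eta1=1.0)
            sizes.append(len(F) - 1)
        assert np.median(sizes) == 0

    def test_strong_signal_is_recruited(self, rng):
        beta = np.zeros(51)
        beta[3] = 5.0
        data, _ = make_glm_data(rng, 400, 50, "gaussian", beta=beta)
        F, _, trace = forward_stage(data, GAUSS, [0], eta1=1.0)
        assert 3 in F
        assert len(trace) >= 1

    def test_eta2_zero_drops_nothing(self, rng):
        data, _ = make_glm_data(rng, 100, 8, "gaussian")
        B0 = [0, 1, 2, 5, 7]
        M, _, trace = backward_stage(B0, [0], data, GAUSS, eta2=0.0)
        assert M == B0
        assert trace == []

    def test_all_protected_returns_unchanged(self, rng):
        data, _ = make_glm_data(rng, 60, 4, "gaussian")
        M, _, trace = backward_stage([0, 1], [0, 1], data, GAUSS, eta2=3.0)
        assert M == [0, 1]
        assert trace == []

    def test_backward_removes_planted_noise_column(self, rng):
        beta = np.zeros(21)
        beta[1], beta[2] = 2.0, -1.5
        data, _ = make_glm_data(rng, 400, 20, "gaussian", beta=beta)
        M, _, _ = backward_stage([0, 1, 2, 9], [0], data, GAUSS, eta2=3.0)
        assert M == [0, 1, 2]


def assert_selection_invariants(result, data, fam, F0=()):
    """Structural contract of a finished run (used across the suite)."""
    n, p = data.n, data.p
    # forward loglik non-decreasing, backward non-increasing
    f_lls = [t.loglik_after for t in result.forward_trace]
    assert all(b >= a - 1e-8 for a, b in zip(f_lls, f_lls[1:]))
    b_lls = [t.loglik_after for t in result.backward_trace]
    assert all(b <= a + 1e-8 for a, b in zip(b_lls, b_lls[1:]))
    # criteria reproducible from trace fields
    for t in result.forward_trace:
        assert t.criterion_after == pytest.approx(
            ebic(t.loglik_after, len(t.active_set_after), n, p, result.eta1), abs=1e-12
        )
    for t in result.backward_trace:
        assert t.criterion_after == pytest.approx(
            bic(t.loglik_after, len(t.active_set_after), n, result.eta2), abs=1e-12
        )
    # accepted steps never worsen their criterion along each stage
    f_crit = [t.criterion_after for t in result.forward_trace]
    assert all(b <= a + 1e-12 for a, b in zip(f_crit, f_crit[1:]))
    # set relations
    F_star = set(result.forward_trace[-1].active_set_after) if result.forward_trace else {0} | set(F0)
    assert set(result.M_hat) <= F_star | {0} | set(F0)
    assert result.k_star2 <= result.k_star
    assert 0 in result.M_hat
    assert set(F0) <= set(result.M_hat)
    # coefficients: zero off the selected set
    off = [j for j in range(1, p + 1) if j not in set(result.M_hat)]
    assert np.all(result.beta_hat[off] == 0.0)


class TestStepwiseFit:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_invariants_hold(self, rng, family):
        data, _ = make_glm_data(rng, 150, 40, family, n_signals=3, signal=0.9)
        res = stepwise_fit(data, family, eta1=0.5, eta2=3.0)
        assert_selection_invariants(res, data, get_family(family))

    def test_f0_is_protected(self, rng):
        data, _ = make_glm_data(rng, 150, 30, "gaussian")
        res = stepwise_fit(data, "gaussian", F0=[25], eta1=0.5, eta2=5.0)
        assert 25 in res.M_hat  # pure-noise column survives because protected
        assert_selection_invariants(res, data, GAUSS, F0=[25])

    def test_f0_by_name(self, rng):
        data, _ = make_glm_data(rng, 100, 5, "gaussian")
        res = stepwise_fit(data, "gaussian", F0=["x4"])
        assert 4 in res.M_hat

    def test_coefficients_on_original_scale(self, rng):
        """De-standardized coefficients equal a plain GLM refit on M_hat."""
        X = rng.standard_normal((200, 10)) * np.array([0.1, 5, 1, 2, 1, 1, 1, 1, 3, 1])
        X += np.array([10, -2, 0, 0, 1, 0, 0, 0, 0, 0])
        beta = np.zeros(11)
        beta[1], beta[2] = 4.0, -0.3
        eta = X @ beta[1:]
        y = eta + rng.standard_normal(200)
        data = make_dataset(X, y)
        res = stepwise_fit(data, "gaussian", eta1=0.5, eta2=3.0)
        S = sorted(res.M_hat)
        oracle = sm.OLS(y, data.X[:, S]).fit().params
        np.testing.assert_allclose(res.beta_hat[S], oracle, atol=1e-8)

    def test_single_predictor_with_signal(self, rng):
        X = rng.standard_normal((200, 1))
        y = 1.2 * X[:, 0] + rng.standard_normal(200)
        res = stepwise_fit(make_dataset(X, y), "gaussian")
        assert res.M_hat == (0, 1)
        se = 1.0 / np.sqrt(200)
        assert abs(res.beta_hat[1] - 1.2) < 3 * se

    def test_eta2_zero_equals_forward_only(self, rng):
        from stepglm.data import standardize

        data, _ = make_glm_data(rng, 120, 25, "gaussian")
        res = stepwise_fit(data, "gaussian", eta1=0.25, eta2=0.0)
        ds, _ = standardize(data)
        F, _, _ = forward_stage(ds, GAUSS, [0], eta1=0.25)
        assert set(res.M_hat) == set(F)
        assert res.k_star2 == 0

    def test_ar_correlated_signals_recovered_no_false_positives(self, rng):
        """AR(0.9) design with signals at 1, 2, 100: no noise selected and
        the two identifiable-at-any-threshold signals always kept."""
        from stepglm.simulate import gen_covariates

        hits = []
        for r in range(3):
            local = np.random.default_rng(r)
            X = gen_covariates(5, 400, 200, local)
            y = -0.5 * X[:, 0] + X[:, 1] + 0.5 * X[:, 99] + local.standard_normal(400)
            res = stepwise_fit(make_dataset(X, y), "gaussian", eta1=0.5, eta2=3.0)
            sel = set(res.M_hat) - {0}
            assert sel <= {1, 2, 100}
            assert {2, 100} <= sel
            hits.append(len(sel))
        assert max(hits) >= 2

    def test_zero_variance_column_excluded_with_warning(self, rng):
        X = rng.standard_normal((80, 5))
        X[:, 3] = 7.0
        y = 2 * X[:, 0] + rng.standard_normal(80)
        with pytest.warns(UserWarning, match="constant predictor"):
            res = stepwise_fit(make_dataset(X, y), "gaussian")
        assert 4 not in res.M_hat


class TestSelectorEstimator:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        data, beta = make_glm_data(rng, 150, 20, "gaussian")
        X, y = data.X[:, 1:], data.y
        sel = StepwiseGLMSelector(family="gaussian", eta1=0.5, eta2=3.0)
        params = sel.get_params()
        assert params["eta1"] == 0.5
        clone(sel)  # get_params/set_params round-trip
        sel.fit(X, y)
        assert sel.support_.shape == (20,)
        assert np.array_equal(np.flatnonzero(sel.support_), sel.selected_)
        assert set(sel.selected_) == {0, 1, 2}
        pred = sel.predict(X)
        assert pred.shape == (150,)
        assert sel.transform(X).shape == (150, len(sel.selected_))

    def test_forced_features_kept(self, rng):
        data, _ = make_glm_data(rng, 120, 15, "gaussian")
        sel = StepwiseGLMSelector(forced=[9], eta2=5.0).fit(data.X[:, 1:], data.y)
        assert 9 in sel.selected_

    def test_binomial_predict_is_probability(self, rng):
        data, _ = make_glm_data(rng, 200, 10, "binomial", signal=1.0)
        sel = StepwiseGLMSelector(family="binomial").fit(data.X[:, 1:], data.y)
        p = sel.predict(data.X[:, 1:])
        assert np.all((p > 0) & (p < 1))

    def test_pipeline_compatibility(self, rng):
        from sklearn.pipeline import Pipeline

        data, _ = make_glm_data(rng, 120, 12, "gaussian")
        pipe = Pipeline([("select", StepwiseGLMSelector())])
        pipe.fit(data.X[:, 1:], data.y)
        assert pipe.predict(data.X[:, 1:]).shape == (120,)
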