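import numpy as np
import pytest
from statsmodels.duration.hazard_regression import PHReg

from frailtymix import (
    EMControl,
    FrailtyParams,
    MembershipPosterior,
    MonotoneLikelihoodWarning,
    SimulationConfig,
    StepBaseline,
    SurvivalDataset,
    ValidationError,
    breslow_baseline,
    build_event_table,
    e_step,
    fit_em,
    m_step_pi,
    m_step_w,
    maximize_beta,
    observable_loglik,
    profile_partial_loglik,
    simulate_dataset,
)


def _toy_params(data, K=2, pi=(0.4, 0.6), w=(1.0, 2.0), beta=(0.3,)):
    et = build_event_table(data)
    jumps = np.full(et.n_times, 0.2)
    return FrailtyParams(pi=pi[:K], w=w[:K], beta=beta,
                         baseline=StepBaseline(et.distinct_event_times, jumps))


class TestEStep:
    def test_single_population_is_degenerate(self, toy_dataset):
        params = _toy_params(toy_dataset, K=1, pi=(1.0,), w=(1.0,))
        alpha = e_step(toy_dataset, params)
        np.testing.assert_array_equal(alpha.alpha, np.ones((2, 1)))

    def test_equal_frailties_return_prior(self, toy_dataset):
        params = _toy_params(toy_dataset, w=(1.7, 1.7))
        alpha = e_step(toy_dataset, params)
        np.testing.assert_allclose(alpha.alpha, np.tile([0.4, 0.6], (2, 1)), atol=1e-12)

    def test_matches_brute_force_bayes(self, toy_dataset):
        params = _toy_params(toy_dataset)
        alpha = e_step(toy_dataset, params).alpha
        # independent scalar evaluation of the Bayes formula
        for j in range(2):
            nums = []
            for k in range(2):
                expo = 0.0
                for i in np.flatnonzero(toy_dataset.group_idx == j):
                    t, d = toy_dataset.time[i], toy_dataset.status[i]
                    eta = float(toy_dataset.covariates[i] @ params.beta)
                    expo += d * np.log(params.w[k])
                    expo -= float(params.baseline.cumhaz(t)) * params.w[k] * np.exp(eta)
                nums.append(params.pi[k] * np.exp(expo))
            np.testing.assert_allclose(alpha[j], np.array(nums) / sum(nums), rtol=1e-12)

    def test_survives_extreme_parameters(self, toy_dataset):
        # log-space computation: no underflow to all-zero rows
        params = _toy_params(toy_dataset, w=(1e-8, 500.0))
        alpha = e_step(toy_dataset, params).alpha
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)


class TestMStepPi:
    def test_hard_assignment(self):
        alpha = MembershipPosterior(np.array([[1, 0], [1, 0], [0, 1]], dtype=float))
        np.testing.assert_allclose(m_step_pi(alpha), [2 / 3, 1 / 3])

    def test_uniform_rows(self):
        alpha = MembershipPosterior(np.full((5, 2), 0.5))
        np.testing.assert_allclose(m_step_pi(alpha), [0.5, 0.5])

    def test_matches_independent_loop(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=(10, 3))
        alpha = MembershipPosterior(raw / raw.sum(axis=1, keepdims=True))
        expected = [sum(alpha.alpha[j, k] for j in range(10)) / 10 for k in range(3)]
        np.testing.assert_allclose(m_step_pi(alpha), expected, rtol=1e-12)


class TestMStepW:
    def test_unit_case(self):
        data = SurvivalDataset(time=[1.0], status=[1], covariates=np.zeros((1, 1)),
                               group_idx=[0], group_labels=["A"])
        baseline = StepBaseline([1.0], [1.0])
        alpha = MembershipPosterior(np.array([[1.0]]))
        np.testing.assert_allclose(m_step_w(data, alpha, baseline, np.zeros(1)), [1.0])

    def test_scale_counter_equivariance(self, toy_dataset):
        alpha = MembershipPosterior(np.array([[0.3, 0.7], [0.8, 0.2]]))
        params = _toy_params(toy_dataset)
        beta = params.beta
        w1 = m_step_w(toy_dataset, alpha, params.baseline, beta)
        w2 = m_step_w(toy_dataset, alpha, params.baseline.scaled(2.0), beta)
        np.testing.assert_allclose(w2, w1 / 2.0, rtol=1e-12)

    def test_matches_term_by_term_sum(self, small_two_pop):
        data, _ = small_two_pop
        params = _toy_params(data)
        rng = np.random.default_rng(2)
        raw = rng.uniform(size=(data.J, 2))
        alpha = MembershipPosterior(raw / raw.sum(axis=1, keepdims=True))
        w = m_step_w(data, alpha, params.baseline, params.beta)
        for k in range(2):
            num = den = 0.0
            for j in range(data.J):
                rows = np.flatnonzero(data.group_idx == j)
                num += alpha.alpha[j, k] * data.status[rows].sum()
                den += alpha.alpha[j, k] * sum(
                    float(params.baseline.cumhaz(data.time[i]))
                    * np.exp(float(data.covariates[i] @ params.beta))
                    for i in rows
                )
            np.testing.assert_allclose(w[k], num / den, rtol=1e-10)


class TestBreslowBaseline:
    def test_first_jump_is_one_over_n(self):
        data = SurvivalDataset(
            time=[1.0, 2.0, 3.0, 4.0], status=[1, 0, 0, 0],
            covariates=np.zeros((4, 1)), group_idx=[0] * 4, group_labels=["A"],
        )
        et = build_event_table(data)
        alpha = MembershipPosterior(np.array([[1.0]]))
        bl = breslow_baseline(et, data, alpha, np.ones(1), np.zeros(1))
        np.testing.assert_allclose(bl.jumps, [0.25])

    def test_reduces_to_nelson_aalen(self, one_pop_dataset):
        """K=1, w=1, beta=0: the weighted Breslow estimator is the plain
        Nelson-Aalen cumulative hazard (independent implementation)."""
        from lifelines import NelsonAalenFitter

        data = one_pop_dataset
        et = build_event_table(data)
        alpha = MembershipPosterior(np.ones((data.J, 1)))
        bl = breslow_baseline(et, data, alpha, np.ones(1), np.zeros(1))
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(data.time, event_observed=data.status)
        ours = bl.cumhaz(et.distinct_event_times)
        theirs = naf.cumulative_hazard_at_times(et.distinct_event_times).to_numpy()
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_frailty_scale_counter_equivariance(self, small_two_pop):
        data, _ = small_two_pop
        et = build_event_table(data)
        rng = np.random.default_rng(4)
        raw = rng.uniform(size=(data.J, 2))
        alpha = MembershipPosterior(raw / raw.sum(axis=1, keepdims=True))
        beta = np.array([0.3])
        w = np.array([1.0, 2.0])
        b1 = breslow_baseline(et, data, alpha, w, beta)
        b2 = breslow_baseline(et, data, alpha, 3.0 * w, beta)
        np.testing.assert_allclose(b2.jumps, b1.jumps / 3.0, rtol=1e-12)


class TestProfilePartialLoglik:
    def test_unit_offsets_match_plain_cox(self, one_pop_dataset):
        data = one_pop_dataset
        et = build_event_table(data)
        beta = np.array([0.25])
        value, grad, hess = profile_partial_loglik(beta, data, et, np.ones(data.n))
        m = PHReg(data.time, data.covariates, status=data.status, ties="breslow")
        assert value == pytest.approx(m.loglike(beta), rel=1e-10)
        np.testing.assert_allclose(grad, m.score(beta), rtol=1e-8)

    def test_single_event_value(self):
        data = SurvivalDataset(
            time=[1.0, 2.0, 3.0], status=[1, 0, 0], covariates=np.zeros((3, 1)),
            group_idx=[0, 0, 0], group_labels=["A"],
        )
        et = build_event_table(data)
        value, _, _ = profile_partial_loglik(np.zeros(1), data, et, np.ones(3))
        assert value == pytest.approx(-np.log(3))

    def test_offsets_match_external_cox(self, small_two_pop):
        data, _ = small_two_pop
        et = build_event_table(data)
        rng = np.random.default_rng(8)
        offset = rng.uniform(0.5, 2.0, size=data.n)
        beta = np.array([0.4])
        value, grad, _ = profile_partial_loglik(beta, data, et, offset)
        m = PHReg(data.time, data.covariates, status=data.status, ties="breslow",
                  offset=np.log(offset))
        # PHReg folds log(offset) into the linear predictor, adding the
        # constant sum of event log-offsets to the value
        const = float(np.log(offset)[data.status == 1].sum())
        assert value == pytest.approx(m.loglike(beta) - const, rel=1e-10)
        np.testing.assert_allclose(grad, m.score(beta), rtol=1e-8, atol=1e-10)


class TestMaximizeBeta:
    def test_matches_external_fit(self, one_pop_dataset):
        data = one_pop_dataset
        et = build_event_table(data)
        beta = maximize_beta(data, et, np.ones(data.n), np.zeros(1))
        res = PHReg(data.time, data.covariates, status=data.status,
                    ties="breslow").fit()
        np.testing.assert_allclose(beta, res.params, atol=1e-6)

    def test_monotone_likelihood_flagged(self):
        # binary covariate with events only at one level
        data = SurvivalDataset(
            time=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], status=[1, 1, 1, 0, 0, 0],
            covariates=np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]]),
            group_idx=[0] * 6, group_labels=["A"],
        )
        et = build_event_table(data)
        with pytest.warns(MonotoneLikelihoodWarning):
            beta = maximize_beta(data, et, np.ones(6), np.zeros(1))
        assert abs(beta[0]) > 10

    def test_no_covariates(self, one_pop_dataset):
        data = one_pop_dataset
        stripped = SurvivalDataset(
            time=data.time, status=data.status, covariates=np.zeros((data.n, 0)),
            group_idx=data.group_idx, group_labels=data.group_labels,
        )
        et = build_event_table(stripped)
        beta = maximize_beta(stripped, et, np.ones(stripped.n), np.zeros(0))
        assert beta.shape == (0,)
        value, _, _ = profile_partial_loglik(beta, stripped, et, np.ones(stripped.n))
        assert np.isfinite(value)


class TestFitEM:
    def test_k1_reduces_to_plain_cox(self, one_pop_dataset, fast_control):
        data = one_pop_dataset
        fit = fit_em(data, 1, fast_control)
        res = PHReg(data.time, data.covariates, status=data.status,
                    ties="breslow").fit()
        np.testing.assert_allclose(fit.params.beta, res.params, atol=1e-6)
        # cumulative baseline at the external beta, against the external
        # Breslow estimator (reported left-continuously, hence the shift)
        times, cumhaz, _ = res.baseline_cumulative_hazard[0]
        ours = fit.params.baseline.cumhaz(times) * fit.params.w[0]
        np.testing.assert_allclose(ours[:-1], cumhaz[1:], atol=1e-6)
        et = build_event_table(data)
        alpha = MembershipPosterior(np.ones((data.J, 1)))
        bl_at_external = breslow_baseline(et, data, alpha, np.ones(1), res.params)
        np.testing.assert_allclose(
            bl_at_external.cumhaz(times)[:-1], cumhaz[1:], atol=1e-8
        )

    def test_loglik_path_non_decreasing(self, small_two_pop, fast_control):
        data, _ = small_two_pop
        fit = fit_em(data, 2, fast_control)
        assert np.all(np.diff(fit.loglik_path) >= -1e-8)

    def test_recovers_labels_strong_contrast(self):
        cfg = SimulationConfig(J=100, n_j=50, pi=(0.3, 0.7), w=(1.0, 3.0), seed=21)
        data, labels = simulate_dataset(cfg)
        fit = fit_em(data, 2, EMControl(seed=2))
        assert np.mean(fit.assignments == labels) >= 0.95

    def test_rescale_invariance(self, small_two_pop, fast_control):
        data, _ = small_two_pop
        fit = fit_em(data, 2, fast_control)
        base = observable_loglik(data, fit.params)
        for c in (0.5, 2.0):
            scaled = FrailtyParams(
                pi=fit.params.pi, w=fit.params.w * c, beta=fit.params.beta,
                baseline=fit.params.baseline.scaled(1.0 / c),
            )
            assert observable_loglik(data, scaled) == pytest.approx(base, abs=1e-8)
        np.testing.assert_allclose(fit.frailty_ratios.min(), 1.0)

    def test_label_permutation_invariance(self, small_two_pop, fast_control):
        data, _ = small_two_pop
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=data.J)
        a0 = np.zeros((data.J, 2))
        a0[np.arange(data.J), labels] = 1.0
        fit1 = fit_em(data, 2, fast_control, init=a0)
        fit2 = fit_em(data, 2, fast_control, init=a0[:, ::-1])
        np.testing.assert_allclose(fit1.params.pi, fit2.params.pi, atol=1e-6)
        np.testing.assert_allclose(fit1.frailty_ratios, fit2.frailty_ratios, atol=1e-5)
        np.testing.assert_array_equal(fit1.assignments, fit2.assignments)

    def test_k_greater_than_J_rejected(self, toy_dataset):
        with pytest.raises(ValidationError):
            fit_em(toy_dataset, 3, EMControl(seed=0))

    def test_parameter_recovery_full_design(self):
        cfg = SimulationConfig(seed=33)  # J=100, n_j=50, ratio 1.55, beta 0.4
        data, _ = simulate_dataset(cfg)
        fit = fit_em(data, 2, EMControl(seed=3))
        assert fit.params.beta[0] == pytest.approx(0.4, abs=0.1)
        assert fit.frailty_ratios[1] == pytest.approx(1.55, abs=0.35)
        assert fit.params.pi[0] == pytest.approx(0.5, abs=0.15)
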