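import warnings

import numpy as np
import pytest

from spaft.aft import INFEASIBLE_LOSS, censored_losses, fit_penalized_aft
from spaft.data_model import SurvivalDataset
from spaft.penalties import PenaltySpec, penalty_value
from spaft.sp_aft import SPConfig, SPState, fit_sp_aft, schedule_age, update_pseudo_labels, update_weights


def make_state(m=3, age=1.0, rnd=1):
    return SPState(
        weights=np.ones(m, dtype=int),
        pseudo_log_time=np.zeros(m),
        age=age,
        round=rnd,
    )


class TestUpdateWeights:
    def test_boundary_inclusive(self):
        np.testing.assert_array_equal(
            update_weights([0.1, 0.5, 2.0], 0.5), [1, 1, 0]
        )

    def test_sentinel_always_excluded(self):
        assert update_weights([INFEASIBLE_LOSS], 1e9)[0] == 0

    def test_all_zero_losses(self):
        np.testing.assert_array_equal(update_weights(np.zeros(4), 0.01), np.ones(4))

    def test_age_must_be_positive(self):
        with pytest.raises(ValueError, match="age"):
            update_weights([1.0], 0.0)


class TestUpdatePseudoLabels:
    def test_selected_get_predictions(self):
        state = SPState(weights=[1, 0], pseudo_log_time=[5.0, 5.0], age=1.0, round=1)
        new = update_pseudo_labels(state, np.array([2.0, 9.0]))
        np.testing.assert_array_equal(new.pseudo_log_time, [2.0, 5.0])

    def test_all_zero_weights_unchanged(self):
        state = SPState(weights=[0, 0], pseudo_log_time=[1.0, 2.0], age=1.0, round=1)
        new = update_pseudo_labels(state, np.array([9.0, 9.0]))
        np.testing.assert_array_equal(new.pseudo_log_time, [1.0, 2.0])

    def test_all_one_weights_replaced(self):
        state = SPState(weights=[1, 1], pseudo_log_time=[1.0, 2.0], age=1.0, round=1)
        new = update_pseudo_labels(state, np.array([7.0, 8.0]))
        np.testing.assert_array_equal(new.pseudo_log_time, [7.0, 8.0])


class TestScheduleAge:
    def test_round1_quantile(self):
        state = make_state(rnd=1)
        cfg = SPConfig(age_init_quantile=0.5)
        assert schedule_age(state, [1.0, 2.0, 3.0, 4.0], cfg) == pytest.approx(2.5)

    def test_growth(self):
        state = make_state(age=2.0, rnd=2)
        assert schedule_age(state, [], SPConfig(age_growth=1.3)) == pytest.approx(2.6)

    def test_strictly_increasing_sequence(self):
        cfg = SPConfig()
        state = make_state(rnd=1)
        age = schedule_age(state, [0.5, 1.0, 2.0], cfg)
        ages = [age]
        for rnd in range(2, 7):
            state = make_state(age=ages[-1], rnd=rnd)
            ages.append(schedule_age(state, [], cfg))
        assert all(b > a for a, b in zip(ages, ages[1:]))

    def test_no_finite_losses_warns(self):
        state = make_state(rnd=1)
        with pytest.warns(RuntimeWarning, match="finite"):
            age = schedule_age(state, [INFEASIBLE_LOSS] * 3, SPConfig())
        assert age > 0

    def test_sentinel_excluded_from_quantile(self):
        state = make_state(rnd=1)
        age = schedule_age(state, [1.0, 3.0, INFEASIBLE_LOSS], SPConfig())
        assert age == pytest.approx(2.0)  # median of the two finite losses


class TestSPStateInvariants:
    def test_nonbinary_weights_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            SPState(weights=[0.5], pseudo_log_time=[1.0])

    def test_nonfinite_labels_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SPState(weights=[1], pseudo_log_time=[np.inf])


def noiseless_fixture(rng, n=60, p=10, censor_frac=0.3, beta_scale=1.0):
    """log t exactly linear in x; censoring scales times down."""
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:3] = np.array([1.0, -0.8, 0.6]) * beta_scale
    log_t = X @ beta
    t = np.exp(log_t)
    status = np.ones(n, dtype=int)
    n_cens = int(censor_frac * n)
    cens = rng.choice(n, n_cens, replace=False)
    status[cens] = 0
    obs = t.copy()
    obs[cens] = t[cens] * rng.uniform(0.4, 0.9, n_cens)
    data = SurvivalDataset(X=X, time=obs, status=status)
    return data, t, beta


def split_by_status(data):
    lab = data.subset(np.flatnonzero(data.status == 1))
    cen = data.subset(np.flatnonzero(data.status == 0))
    return lab, cen


class TestFitSpAft:
    def test_empty_censored_reduces_to_plain_aft(self, rng):
        data, _, _ = noiseless_fixture(rng, censor_frac=0.0)
        lab, cen = split_by_status(data)
        spec = PenaltySpec("mcp", lam=0.02)
        fit, state = fit_sp_aft(lab, cen, spec)
        plain = fit_penalized_aft(lab.X, np.log(lab.time), spec)
        np.testing.assert_array_equal(fit.beta, plain.beta)
        assert fit.intercept == plain.intercept
        assert state.weights.size == 0

    def test_unreachable_censor_times_get_zero_weight(self, rng):
        data, _, _ = noiseless_fixture(rng, n=40, censor_frac=0.25)
        lab, cen = split_by_status(data)
        # 3 censored samples get censor times far above any achievable prediction
        cen.time[:3] = 1e6
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, state = fit_sp_aft(lab, cen, PenaltySpec("mcp", lam=0.02))
        assert np.all(state.weights[:3] == 0)

    def test_retained_samples_satisfy_constraint_exactly(self, rng):
        data, _, _ = noiseless_fixture(rng, n=50, censor_frac=0.4)
        lab, cen = split_by_status(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, state = fit_sp_aft(lab, cen, PenaltySpec("mcp", lam=0.02))
        preds = fit.predict_log_time(cen.X)
        sel = state.weights == 1
        assert np.all(preds[sel] >= np.log(cen.time[sel]))

    def test_noiseless_recovery_of_pseudo_labels(self, rng):
        data, true_t, _ = noiseless_fixture(rng, n=60, p=10, censor_frac=0.3)
        lab, cen = split_by_status(data)
        cen_true = true_t[np.flatnonzero(data.status == 0)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, state = fit_sp_aft(lab, cen, PenaltySpec("mcp", lam=0.005))
        sel = state.weights == 1
        assert sel.sum() > 0
        err = np.abs(state.pseudo_log_time[sel] - np.log(cen_true[sel]))
        assert err.max() < 0.2

    def test_weight_nestedness_in_age(self, rng):
        losses = rng.uniform(0, 5, size=50)
        losses[rng.choice(50, 5, replace=False)] = INFEASIBLE_LOSS
        prev = np.zeros(50, dtype=int)
        for age in np.linspace(0.1, 6.0, 25):
            w = update_weights(losses, age)
            assert np.all(w >= prev)  # selected set only grows with age
            prev = w

    def test_selected_set_objective_nonincreasing_within_beta_step(self, rng):
        """Refitting beta cannot increase the selected-set objective at fixed (v, y)."""
        data, _, _ = noiseless_fixture(rng, n=50, censor_frac=0.4, beta_scale=1.0)
        lab, cen = split_by_status(data)
        spec = PenaltySpec("mcp", lam=0.02)
        trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_sp_aft(lab, cen, spec, SPConfig(max_rounds=8), trace=trace)
        y_lab = np.log(lab.time)

        def objective(intercept, beta, weights, pseudo):
            sel = weights == 1
            r_lab = y_lab - intercept - lab.X @ beta
            r_cen = pseudo[sel] - intercept - cen.X[sel] @ beta
            m = len(y_lab) + sel.sum()
            data_term = (np.sum(r_lab**2) + np.sum(r_cen**2)) / (2 * m)
            return data_term + float(np.sum(penalty_value(beta, spec)))

        for prev, cur in zip(trace, trace[1:]):
            # evaluate both fits on the (v, y) the later fit was trained on
            before = objective(prev["intercept"], prev["beta"], prev["weights"], prev["pseudo_log_time"])
            after = objective(cur["intercept"], cur["beta"], prev["weights"], prev["pseudo_log_time"])
            assert after <= before + 1e-8

    def test_use_spl_false_keeps_all_feasible(self, rng):
        data, _, _ = noiseless_fixture(rng, n=40, censor_frac=0.3)
        lab, cen = split_by_status(data)
        cen.time[0] = 1e6  # unreachable: must be dismissed at termination
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, state = fit_sp_aft(lab, cen, PenaltySpec("mcp", lam=0.02), use_spl=False)
        preds = fit.predict_log_time(cen.X)
        expected = (preds >= np.log(cen.time)).astype(int)
        np.testing.assert_array_equal(state.weights, expected)
        assert state.weights[0] == 0

    def test_too_few_labeled(self, rng):
        data, _, _ = noiseless_fixture(rng, n=10, censor_frac=0.0)
        lab = data.subset([0])
        with pytest.raises(ValueError, match="labeled"):
            fit_sp_aft(lab, data.subset([]), PenaltySpec("mcp", lam=0.1))

    def test_age_nondecreasing_across_rounds(self, rng):
        data, _, _ = noiseless_fixture(rng, n=50, censor_frac=0.4)
        lab, cen = split_by_status(data)
        trace = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_sp_aft(lab, cen, PenaltySpec("mcp", lam=0.02), SPConfig(max_rounds=6), trace=trace)
        ages = [t["age"] for t in trace]
        assert all(b >= a for a, b in zip(ages, ages[1:]))
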