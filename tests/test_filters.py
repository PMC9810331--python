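"""Learning filters: delta rules, changepoint quantities, HMM inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm, uniform

from epinc import filters
from epinc._kernels import FAM_RB2H, batch_loglik
from epinc.filters import (
    DESIGN_SIGMA_N,
    BeliefState,
    LearningFilterEstimator,
    ModelSpec,
    choice_likelihood,
    ci_step,
    compute_cpp,
    compute_learning_rate,
    design_outcome_sd,
    rb_step,
    run_filter,
    rw1q_step,
    rw_step,
)
from oracles import enumerate_context_paths, rw1q_reference


# ---------------------------------------------------------------------------
# delta rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("b0,x,alpha,expected", [
    (0.5, 1.0, 0.0, 0.5),   # no-learning limit
    (0.5, 1.0, 1.0, 1.0),   # full-update limit
    (0.40, 0.80, 0.25, 0.50),
])
def test_rw_step_arithmetic(b0, x, alpha, expected):
    B, delta = rw_step({"A": b0, "B": 0.5}, "A", x, alpha)
    assert B["A"] == pytest.approx(expected)
    assert B["B"] == 0.5  # unchosen deck untouched
    assert delta == pytest.approx(x - b0)


def test_rw_step_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rw_step({"A": 0.5, "B": 0.5}, "A", 1.5, 0.1)
    with pytest.raises(ValueError):
        rw_step({"A": 0.5, "B": 0.5}, "A", 0.5, 1.5)


# ---------------------------------------------------------------------------
# changepoint probability and learning rate
# ---------------------------------------------------------------------------

def test_cpp_limits():
    assert compute_cpp(0.5, 0.2, 0.9, H=0.0, sigma_n=0.3) == 0.0
    assert compute_cpp(0.5, 0.2, 0.9, H=1.0, sigma_n=0.3) == 1.0
    with pytest.raises(ValueError):
        compute_cpp(0.5, 0.2, 0.9, H=0.1, sigma_n=0.0)


def test_cpp_matches_density_ratio_oracle():
    H, tau, sigma, b, x = 0.1, 0.2, 0.3, 0.5, 0.5
    total_sd = math.sqrt(sigma**2 + sigma**2 * tau / (1 - tau))
    u = uniform(0, 1).pdf(x)
    n = norm(b, total_sd).pdf(x)
    expected = H * u / (H * u + (1 - H) * n)
    assert compute_cpp(b, tau, x, H, sigma) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0, 1), st.floats(0, 0.999))
def test_learning_rate_range_and_value(omega, tau):
    a = compute_learning_rate(omega, tau)
    assert 0.0 <= a <= 1.0
    assert a == pytest.approx(omega + (1 - omega) * tau)


@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.99), st.floats(0, 0.99))
def test_learning_rate_monotonicity(o1, o2, t1, t2):
    lo = compute_learning_rate(min(o1, o2), min(t1, t2))
    hi = compute_learning_rate(max(o1, o2), max(t1, t2))
    assert hi >= lo - 1e-12


@pytest.mark.parametrize("omega,tau,expected", [(0.0, 0.3, 0.3), (1.0, 0.7, 1.0), (0.5, 0.5, 0.75)])
def test_learning_rate_values(omega, tau, expected):
    assert compute_learning_rate(omega, tau) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# reduced Bayesian recursion
# ---------------------------------------------------------------------------

def test_rb_full_surprise_jumps_to_outcome():
    # tiny noise, distant outcome: omega ~ 1, so B' ~ outcome
    st_ = BeliefState(B={"A": 0.1, "B": 0.5}, tau=0.1, H=0.1, sigma_n=0.02)
    new = rb_step(st_, "A", 0.9)
    assert new.omega > 0.999
    assert new.B["A"] == pytest.approx(0.9, abs=1e-3)


def test_rb_stable_run_uncertainty_decreases_to_fixed_point():
    st_ = BeliefState(H=0.05, sigma_n=DESIGN_SIGMA_N)
    taus = []
    for _ in range(50):
        taus.append(st_.tau)
        st_ = rb_step(st_, "A", 0.6)  # perfectly consistent outcomes
    diffs = np.diff(taus)
    assert (diffs <= 1e-9).all()
    assert taus[-1] < taus[0]


@given(st.integers(0, 500))
def test_rb_state_ranges(seed):
    rng = np.random.default_rng(seed)
    st_ = BeliefState(H=float(rng.uniform(0.01, 0.5)), sigma_n=float(rng.uniform(0.05, 0.5)))
    for _ in range(30):
        st_ = rb_step(st_, "A" if rng.random() < 0.5 else "B", float(rng.random()))
        assert 0.0 <= st_.omega <= 1.0
        assert 0.0 <= st_.alpha_t <= 1.0
        assert 0.0 <= st_.tau < 1.0
        assert 0.0 <= st_.B["A"] <= 1.0 and 0.0 <= st_.B["B"] <= 1.0
        assert st_.ape == abs(st_.delta)


def test_rb_small_hazard_small_tau_approaches_frozen_rw():
    """With H -> 0 and tau -> 0 the reduced learner's effective learning
    rate vanishes (an RW learner with alpha -> 0)."""
    st_ = BeliefState(tau=1e-6, H=1e-9, sigma_n=DESIGN_SIGMA_N)
    new = rb_step(st_, "A", 1.0)
    assert new.alpha_t < 1e-4
    assert new.B["A"] == pytest.approx(0.5, abs=1e-4)


# ---------------------------------------------------------------------------
# contextual inference
# ---------------------------------------------------------------------------

def test_ci_uniform_likelihood_reduces_to_transition():
    # equal outcome likelihood under both contexts: x equidistant from means
    p = ci_step(np.array([0.8, 0.2]), "A", 0.5, H=0.3)
    expected = np.array([(1 - 0.3) * 0.8 + 0.3 * 0.2, 0.3 * 0.8 + (1 - 0.3) * 0.2])
    np.testing.assert_allclose(p, expected, atol=1e-12)


def test_ci_absorbing_with_zero_hazard():
    p = np.array([1.0, 0.0])
    for x in (0.6, 0.4, 0.8):
        p = ci_step(p, "A", x, H=0.0)
    np.testing.assert_allclose(p, [1.0, 0.0], atol=1e-12)


def test_ci_matches_path_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(20):
        T = int(rng.integers(2, 9))
        choices = ["A" if rng.random() < 0.5 else "B" for _ in range(T)]
        outcomes = rng.uniform(0, 1, T)
        H, sigma = float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.1, 0.4))
        p = np.array([0.5, 0.5])
        for c, x in zip(choices, outcomes):
            p = ci_step(p, c, float(x), H=H, sigma_n=sigma)
        expected = enumerate_context_paths(outcomes, choices, H, sigma)
        np.testing.assert_allclose(p, expected, atol=1e-10)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# single-estimate learner
# ---------------------------------------------------------------------------

def test_rw1q_examples_and_symmetry():
    assert rw1q_step(0.5, "A", 1.0, 1.0) == pytest.approx(1.0)
    # perfectly contradictory alternating evidence with alpha = 0.5
    q = 0.5
    qs = []
    for t in range(20):
        q = rw1q_step(q, "A", 1.0 if t % 2 == 0 else 0.0, 0.5)
        qs.append(q)
    assert np.mean(qs) == pytest.approx(0.5, abs=0.01)
    assert max(qs) > 0.6 and min(qs) < 0.4


def test_rw1q_matches_reference_recursion():
    rng = np.random.default_rng(8)
    choices = ["A" if rng.random() < 0.5 else "B" for _ in range(50)]
    outcomes = rng.uniform(0, 1, 50)
    q = 0.5
    mine = []
    for c, x in zip(choices, outcomes):
        mine.append(q)
        q = rw1q_step(q, c, float(x), 0.3)
    np.testing.assert_allclose(mine, rw1q_reference(choices, outcomes, 0.3), atol=1e-12)


# ---------------------------------------------------------------------------
# choice rule and full filter runs
# ---------------------------------------------------------------------------

def test_choice_likelihood_values():
    assert choice_likelihood(3.0, 0.5, 0.5) == pytest.approx(0.5)
    assert choice_likelihood(3.0, 0.7, 0.5) == pytest.approx(1 / (1 + math.exp(-0.6)))
    assert choice_likelihood(1e6, 0.6, 0.5) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        choice_likelihood(0.0, 0.5, 0.5)


def _toy_trials(n=320, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": "s0",
        "task": "deck_memory",
        "env_code": [-0.5] * (n // 2) + [0.5] * (n // 2),
        "trial_index": np.arange(n),
        "choice_deck": rng.choice(["A", "B"], n),
        "outcome_cents": rng.choice([0, 20, 40, 60, 80, 100], n),
    })


def test_run_filter_deterministic_and_total():
    spec = ModelSpec("RB2H", (0.05, 0.1), beta_temp=5.0)
    trials = _toy_trials()
    a = run_filter(spec, trials)
    b = run_filter(spec, trials)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == len(trials)
    assert a["ru"].notna().all()


def test_run_filter_env_indexed_parameter_switch():
    trials = _toy_trials(seed=3)
    lo = run_filter(ModelSpec("RW2A", (0.1, 0.9)), trials)
    # in the low block the filter must use alpha_low, in the high block alpha_high
    assert (lo["lr"][:160] == 0.1).all()
    assert (lo["lr"][160:] == 0.9).all()


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        ModelSpec("XX", (0.1,))
    with pytest.raises(ValueError):
        ModelSpec("RB2H", (0.1,))  # needs two hazard rates


def test_kernel_agrees_with_python_filter():
    """The numba likelihood kernel and the reference python filter must
    assign identical likelihoods to the same data."""
    spec = ModelSpec("RB2H", (0.07, 0.12), beta_temp=4.0)
    trials = _toy_trials(seed=9)
    ser = run_filter(spec, trials)
    y = (trials["choice_deck"] == "A").to_numpy()
    ll_py = float(np.sum(np.where(y, np.log(ser["p_choose_A"]), np.log1p(-ser["p_choose_A"]))))
    out = np.empty(1)
    batch_loglik(
        FAM_RB2H,
        np.array([[0.07, 0.12, 4.0, 0.0]]),
        spec.sigma_n,
        (trials["choice_deck"] == "B").to_numpy().astype(np.int8),
        trials["outcome_cents"].to_numpy(dtype=float) / 100.0,
        (trials["env_code"] > 0).to_numpy().astype(np.int8),
        np.array([0, len(trials)], dtype=np.int64),
        out,
    )
    assert out[0] == pytest.approx(ll_py, abs=1e-9)


def test_design_outcome_sd_matches_constant():
    assert design_outcome_sd() == pytest.approx(DESIGN_SIGMA_N, abs=5e-4)


def test_estimator_interface():
    est = LearningFilterEstimator(family="RB1H", params=(0.1,), beta_temp=3.0)
    assert est.get_params()["family"] == "RB1H"
    out = est.fit().transform(_toy_trials(n=40, seed=2))
    assert {"deckval_A", "deckval_B", "ru", "cpp", "ape", "lr"} <= set(out.columns)
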