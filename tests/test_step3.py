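import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lmfa
from lmfa.step3 import (
    TransitionModel,
    _batch_expm,
    _build_structure,
    posterior_states_step3,
)

from conftest import no_covariate_config
from oracles import (
    dt_forward_loglik,
    enumerate_loglik,
    enumerate_smoothed_posteriors,
    expm_series,
    random_panel,
)

# the worked 3-state example: rates and the probabilities they imply
EXAMPLE_RATES = np.array([0.31, 0.20, 0.20, 0.66, 0.56, 0.28])
EXAMPLE_Q = np.array(
    [[-0.51, 0.31, 0.20], [0.20, -0.86, 0.66], [0.56, 0.28, -0.84]]
)


# ----------------------------------------------------------------------
def test_intensity_matrix_from_log_rates():
    Q = lmfa.intensity_matrix(np.log(EXAMPLE_RATES)[:, None])
    assert np.allclose(Q, EXAMPLE_Q, atol=1e-12)
    assert Q[0, 0] == pytest.approx(-0.51)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)


def test_intensity_overflow_raises():
    with pytest.raises(OverflowError, match="rescal"):
        lmfa.intensity_matrix(np.full((6, 1), 100.0))


def test_vanishing_rates_freeze_the_chain():
    Q = lmfa.intensity_matrix(np.full((6, 1), -40.0))
    assert np.allclose(Q, 0.0, atol=1e-12)
    assert np.allclose(lmfa.transition_matrix(Q, 5.0), np.eye(3), atol=1e-10)


def test_transition_matrix_identity_and_semigroup():
    assert np.allclose(lmfa.transition_matrix(np.zeros((3, 3)), 1.0), np.eye(3))
    Q = EXAMPLE_Q
    P1 = lmfa.transition_matrix(Q, 0.7)
    P2 = lmfa.transition_matrix(Q, 0.5)
    P12 = lmfa.transition_matrix(Q, 1.2)
    assert np.allclose(P1 @ P2, P12, atol=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 5), st.floats(0.05, 5.0))
def test_transition_matrix_row_stochastic_and_series_accurate(seed, K, delta):
    rng = np.random.default_rng(seed)
    Q = rng.uniform(0.01, 1.0, (K, K))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = lmfa.transition_matrix(Q, delta)
    assert np.all(P >= -1e-12)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(P, expm_series(Q * delta), atol=1e-10)
    # the vectorized stack path agrees with the single-matrix contract
    Pb = _batch_expm((Q * delta)[None])
    assert np.allclose(Pb[0], P, atol=1e-10)


def test_off_diagonal_mass_grows_near_zero():
    Pa = lmfa.transition_matrix(EXAMPLE_Q, 0.01)
    Pb = lmfa.transition_matrix(EXAMPLE_Q, 0.02)
    off = ~np.eye(3, dtype=bool)
    assert np.all(Pb[off] > Pa[off])


def test_initial_probs_uniform_and_printed_example():
    assert np.allclose(lmfa.initial_probs(np.zeros((2, 1))), 1 / 3)
    gamma = np.array([[np.log(0.34 / 0.42)], [np.log(0.24 / 0.42)]])
    assert np.allclose(lmfa.initial_probs(gamma), [0.42, 0.34, 0.24], atol=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(5):
        g = rng.normal(0, 2, (3, 2))
        assert lmfa.initial_probs(g, [rng.normal()]).sum() == pytest.approx(1.0)


# ----------------------------------------------------------------------
def test_single_occasion_subject_contributes_initial_logit():
    frame = pd.DataFrame([{"id": 1, "y1": 0.0}])
    data = lmfa.build_dataset(frame, "id", ["y1"])
    gamma = np.array([[0.3], [-0.2]])
    beta = np.full((6, 1), np.log(0.2))
    for modal in (1, 2, 3):
        ll = lmfa.loglik_ctlmm(data, gamma, beta, np.array([modal]), np.eye(3))
        assert ll == pytest.approx(np.log(lmfa.initial_probs(gamma)[modal - 1]))


def test_forward_matches_enumeration_oracle():
    rng = np.random.default_rng(17)
    for _ in range(20):
        data, modal, E, gamma, beta = random_panel(rng)
        ll = lmfa.loglik_ctlmm(
            data, gamma, beta, modal, E, timeintervals="interval"
        )
        assert ll == pytest.approx(
            enumerate_loglik(data, modal, E, gamma, beta), abs=1e-10
        )


def test_frozen_chain_likelihood_is_initial_only():
    rows = [{"id": 1, "y1": 0.0}] * 3 + [{"id": 2, "y1": 0.0}] * 2
    data = lmfa.build_dataset(pd.DataFrame(rows), "id", ["y1"])
    gamma = np.array([[0.5], [-0.5]])
    beta = np.full((6, 1), -40.0)  # rates ~ 0
    modal = np.array([2, 2, 2, 1, 1])
    ll = lmfa.loglik_ctlmm(data, gamma, beta, modal, np.eye(3))
    pi = lmfa.initial_probs(gamma)
    assert ll == pytest.approx(np.log(pi[1]) + np.log(pi[0]), abs=1e-8)


def test_impossible_sequence_names_subject():
    rows = [{"id": 7, "y1": 0.0}] * 2
    data = lmfa.build_dataset(pd.DataFrame(rows), "id", ["y1"])
    gamma = np.zeros((2, 1))
    beta = np.full((6, 1), np.log(0.2))
    # an emission matrix under which modal state 2 can never be observed
    E = np.array([[1.0, 0.5, 0.0], [0.0, 0.0, 0.0], [0.0, 0.5, 1.0]])
    with pytest.raises(ZeroDivisionError, match="7"):
        lmfa.loglik_ctlmm(data, gamma, beta, np.array([2, 1]), E)


def test_equidistant_case_equals_discrete_time_forward():
    rng = np.random.default_rng(23)
    rows = []
    lengths = [5, 3, 7]
    for i, T in enumerate(lengths):
        rows += [{"id": i + 1, "y1": 0.0}] * T
    data = lmfa.build_dataset(pd.DataFrame(rows), "id", ["y1"])
    modal = rng.integers(1, 4, size=sum(lengths))
    E = rng.dirichlet(np.ones(3), size=3).T
    E /= E.sum(axis=0)
    gamma = rng.normal(0, 1, (2, 1))
    beta = rng.normal(np.log(0.3), 0.4, (6, 1))
    ll = lmfa.loglik_ctlmm(data, gamma, beta, modal, E)  # all intervals 1
    P = lmfa.transition_matrix(lmfa.intensity_matrix(beta), 1.0)
    ll_dt = dt_forward_loglik(modal, lengths, lmfa.initial_probs(gamma), P, E)
    assert ll == pytest.approx(ll_dt, abs=1e-10)


# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def small_ct_fit():
    cfg = no_covariate_config(
        n_subjects=20, occasions_mean=15, occasions_sd=2,
        occasions_min=10, occasions_max=20,
    )
    data, truth = lmfa.simulate_lmfa(cfg, seed=31)
    W = np.zeros((data.n_rows, 3))
    W[np.arange(data.n_rows), truth["state"].to_numpy() - 1] = 1.0
    model = lmfa.fit_step3(
        data, 3, W, timeintervals="interval", n_starts=1, seed=5
    )
    return cfg, data, truth, model


def test_fitted_loglik_beats_generator_parameters(small_ct_fit):
    cfg, data, truth, model = small_ct_fit
    modal = truth["state"].to_numpy()
    ll_gen = lmfa.loglik_ctlmm(
        data, cfg.gamma, cfg.beta, modal, np.eye(3), timeintervals="interval"
    )
    assert model.loglik >= ll_gen - 1e-6
    assert model.converged


def test_probabilities_contract(small_ct_fit):
    *_, model = small_ct_fit
    pi, P = lmfa.probabilities(model)
    assert pi.sum() == pytest.approx(1.0)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
    _, P_small = lmfa.probabilities(model, deltaT=1e-8)
    assert np.allclose(P_small, np.eye(3), atol=1e-6)
    with pytest.raises(ValueError, match="scores"):
        lmfa.probabilities(model, transitionCovariateScores=[1.0])


def test_step3_bic_uses_subject_count(small_ct_fit):
    *_, model = small_ct_fit
    assert model.bic == pytest.approx(
        -2 * model.loglik + model.n_par * np.log(model.n_subjects)
    )
    assert model.n_par == 2 + 6


def test_perfect_separation_modal_preserved(small_ct_fit):
    _, data, truth, model = small_ct_fit
    sa = posterior_states_step3(model)
    # with exact (one-hot) step-2 assignments, step 3 cannot re-resolve them
    assert np.array_equal(sa.modal, truth["state"].to_numpy())


def test_summary_step3_sections(small_ct_fit):
    *_, model = small_ct_fit
    text = lmfa.summary_step3(model)
    for section in ("Parameter estimates", "Initial state probabilities",
                    "Transition probabilities", "State proportions", "BIC"):
        assert section in text


def _manual_model(data, modal, E, gamma, beta):
    st3 = _build_structure(data, modal, E, "interval", [], [])
    return TransitionModel(
        K=3, gamma=gamma, beta=beta, emission=E, vcov=None,
        estimates=pd.DataFrame(), wald=pd.DataFrame(), loglik=np.nan,
        n_par=8, bic=np.nan, converged=True, n_subjects=len(st3.lengths),
        initial_covariates=[], transition_covariates=[],
        initial_means=np.zeros(0), transition_means=np.zeros(0),
        timeintervals="interval", data=data, modal=modal, _structure=st3,
    )


def test_smoothed_posteriors_match_enumeration():
    rng = np.random.default_rng(41)
    for _ in range(5):
        data, modal, E, gamma, beta = random_panel(rng)
        model = _manual_model(data, modal, E, gamma, beta)
        sa = posterior_states_step3(model)
        ref = enumerate_smoothed_posteriors(data, modal, E, gamma, beta)
        assert np.allclose(sa.posterior, ref, atol=1e-10)


def test_invariance_summary_lists_permanent_subjects():
    rng = np.random.default_rng(51)
    rows = (
        [{"id": 1, "interval": 1.0, "y1": 0.0}] * 4
        + [{"id": 2, "interval": 1.0, "y1": 0.0}] * 4
        + [{"id": 3, "interval": 1.0, "y1": 0.0}]
    )
    data = lmfa.build_dataset(pd.DataFrame(rows), "id", ["y1"], "interval")
    modal = np.array([2, 2, 2, 2, 1, 2, 1, 2, 3])
    E = np.full((3, 3), 0.05) + np.eye(3) * 0.85
    E /= E.sum(axis=0)
    gamma = np.zeros((2, 1))
    beta = np.full((6, 1), np.log(0.2))
    model = _manual_model(data, modal, E, gamma, beta)
    inv = lmfa.invariance_summary(model)
    sa = posterior_states_step3(model)
    # listing agrees with the final modal sequences, per state
    for k in range(3):
        expect = []
        for sid, sl in data.subject_slices():
            states = sa.modal[sl]
            if np.all(states == states[0]) and states[0] == k + 1:
                expect.append(sid)
        assert inv[f"S{k + 1}"] == expect
    # subject 1 is constantly in state 2; subject 3 (single occasion)
    # is vacuously permanent
    assert 1 in inv["S2"]
    assert any(3 in v for v in inv.values())


def test_transition_plot_data_equals_modal_column(small_ct_fit):
    _, data, truth, model = small_ct_fit
    sid, sl = data.subject_slices()[0]
    occ, states = lmfa.transition_plot_data(model, sid)
    sa = posterior_states_step3(model)
    assert np.array_equal(states, sa.modal[sl])
    assert np.array_equal(occ, np.arange(1, sl.stop - sl.start + 1))
    with pytest.raises(KeyError):
        lmfa.transition_plot_data(model, "no-such-subject")


# ----------------------------------------------------------------------
def test_wald_invariant_to_covariate_rescaling():
    cfg = no_covariate_config(
        n_subjects=30, occasions_mean=12, occasions_sd=1,
        occasions_min=10, occasions_max=14,
    )
    data, truth = lmfa.simulate_lmfa(cfg, seed=61)
    W = np.zeros((data.n_rows, 3))
    W[np.arange(data.n_rows), truth["state"].to_numpy() - 1] = 1.0
    rng = np.random.default_rng(0)
    frame = data.frame.drop(columns=["_interval"]).copy()
    frame["x"] = rng.standard_normal(len(frame))
    d1 = lmfa.build_dataset(frame, "id", data.indicator_cols, "interval", ["x"])
    frame2 = frame.copy()
    frame2["x"] = frame2["x"] * 10.0
    d2 = lmfa.build_dataset(frame2, "id", data.indicator_cols, "interval", ["x"])
    m1 = lmfa.fit_step3(d1, 3, W, timeintervals="interval",
                        transitionCovariates=["x"], n_starts=0, seed=1)
    m2 = lmfa.fit_step3(d2, 3, W, timeintervals="interval",
                        transitionCovariates=["x"], n_starts=0, seed=1)
    w1 = m1.wald["Wald"].iloc[0]
    w2 = m2.wald["Wald"].iloc[0]
    assert abs(w1 - w2) < 1e-6 * max(1.0, abs(w1))
    # coefficients transform exactly with the rescaling
    assert np.allclose(
        m1.estimates["coef"].to_numpy()[3::2],
        10.0 * m2.estimates["coef"].to_numpy()[3::2],
        rtol=1e-5, atol=1e-6,
    )
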