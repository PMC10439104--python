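import numpy as np
import pandas as pd
import pytest

import lmfa
from lmfa.step1 import ModelSelectionTable

from conftest import check_fit_invariants, make_panel
from oracles import mixture_loglik_direct


def _match_states(fit, cfg):
    """Map each fitted state to the nearest generating state by intercepts."""
    return [
        int(np.argmin(np.sum((cfg.intercepts - nu) ** 2, axis=1)))
        for nu in fit.model.intercepts
    ]


# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "K, J, F, expected",
    [(1, 2, [1], 6), (3, 18, [3, 3, 3], 263), (3, 18, [3, 2, 3], 247)],
)
def test_count_parameters(K, J, F, expected):
    assert lmfa.count_parameters(K, J, F) == expected


def test_enumerate_models_counts_multisets_once():
    small = lmfa.enumerate_models([1, 2], [1, 2])
    assert len(small) == 5
    assert {tuple(sorted(m)) for m in small} == {
        (1,), (2,), (1, 1), (1, 2), (2, 2)
    }
    # a four-state range with two factor choices gives 2+3+4+5 candidates
    assert len(lmfa.enumerate_models([1, 2, 3, 4], [2, 3])) == 14
    # no two candidates are permutations of the same multiset
    ms = [tuple(sorted(m)) for m in lmfa.enumerate_models([1, 2, 3], [1, 2, 3])]
    assert len(ms) == len(set(ms))


def test_loglik_standard_normal_point():
    model = lmfa.MeasurementModel(
        [np.zeros((2, 1))], np.zeros((1, 2)), np.ones((1, 2)), np.ones(1)
    )
    ll = lmfa.loglik_step1(np.zeros((1, 2)), model)
    assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)


def test_loglik_matches_direct_summation():
    rng = np.random.default_rng(3)
    K, J = 2, 3
    model = lmfa.MeasurementModel(
        [rng.normal(0, 1, (J, 1)), rng.normal(0, 1, (J, 2))],
        rng.normal(0, 1, (K, J)),
        rng.uniform(0.5, 2.0, (K, J)),
        np.array([0.4, 0.6]),
    )
    y = rng.normal(0, 2, (7, J))
    assert lmfa.loglik_step1(y, model) == pytest.approx(
        mixture_loglik_direct(y, model), abs=1e-10
    )


def test_loglik_rotation_invariant():
    rng = np.random.default_rng(4)
    J = 4
    Lam = rng.normal(0, 1, (J, 2))
    R, _ = np.linalg.qr(rng.normal(0, 1, (2, 2)))
    base = lmfa.MeasurementModel(
        [Lam], np.zeros((1, J)), np.ones((1, J)), np.ones(1)
    )
    rotated = lmfa.MeasurementModel(
        [Lam @ R], np.zeros((1, J)), np.ones((1, J)), np.ones(1)
    )
    y = rng.normal(0, 1, (11, J))
    assert lmfa.loglik_step1(y, base) == pytest.approx(
        lmfa.loglik_step1(y, rotated), abs=1e-10
    )


# ----------------------------------------------------------------------
def _panel_from_array(y):
    rows = [
        {"id": 1, **{f"y{j + 1}": v for j, v in enumerate(row)}} for row in y
    ]
    return make_panel(rows, [f"y{j + 1}" for j in range(y.shape[1])])


def test_zero_factors_disallowed():
    y = np.random.default_rng(0).normal(0, 1, (50, 3))
    with pytest.raises(ValueError, match="at least one factor"):
        lmfa.fit_step1(_panel_from_array(y), 1, [0], n_starts=1, seed=0)


def test_ledermann_bound_enforced():
    y = np.random.default_rng(0).normal(0, 1, (200, 3))
    # 3 indicators identify at most 1 factor
    with pytest.raises(ValueError, match="Ledermann"):
        lmfa.fit_step1(_panel_from_array(y), 1, [2], n_starts=1, seed=0)


def test_single_state_loading_recovery():
    rng = np.random.default_rng(12)
    lam = np.array([0.8, 0.7, 0.6, 0.5, 0.9, 0.4])
    psi = 1.0 - lam**2 * 0.5
    n = 2000
    eta = rng.standard_normal(n)
    y = np.outer(eta, lam) + rng.standard_normal((n, 6)) * np.sqrt(psi)
    data = _panel_from_array(y)
    fit = lmfa.fit_step1(data, 1, [1], n_starts=2, max_iterations=500,
                         tolerance=1e-8, seed=1)
    check_fit_invariants(fit, data)
    est = fit.model.loadings[0][:, 0]
    if np.dot(est, lam) < 0:
        est = -est
    assert np.sqrt(np.mean((est - lam) ** 2)) < 0.08


def test_two_separated_states_classified():
    rng = np.random.default_rng(7)
    n = 400
    lam = np.full(4, 0.8)
    y1 = np.outer(rng.standard_normal(n), lam) + rng.normal(0, 0.6, (n, 4))
    y2 = 5.0 + np.outer(rng.standard_normal(n), lam) + rng.normal(0, 0.6, (n, 4))
    y = np.vstack([y1, y2])
    true = np.repeat([0, 1], n)
    data = _panel_from_array(y)
    fit = lmfa.fit_step1(data, 2, [1, 1], n_starts=4, max_iterations=300,
                         tolerance=1e-7, seed=3)
    check_fit_invariants(fit, data)
    modal = np.argmax(fit.posterior, axis=1)
    agree = max(np.mean(modal == true), np.mean(modal == 1 - true))
    assert agree > 0.95


def test_states_relabelled_by_descending_size(step1_fit):
    modal = np.argmax(step1_fit.posterior, axis=1)
    counts = np.bincount(modal, minlength=step1_fit.model.n_states)
    assert np.all(np.diff(counts) <= 0)


# ----------------------------------------------------------------------
def _table(rows):
    tab = pd.DataFrame(
        rows, columns=["model", "LL", "BIC", "convergence", "n_par"]
    ).set_index("model")
    return ModelSelectionTable(tab.sort_values("BIC"), {}, 100)


def test_chull_selects_elbow_with_forced_ratio():
    tab = _table(
        [("[1]", -100.0, 0.0, 1, 10), ("[2]", -50.0, 1.0, 1, 20),
         ("[1 1]", -49.0, 2.0, 1, 30)]
    )
    res = lmfa.chull_select(tab)
    assert res.selected == "[2]"
    assert res.hull.loc["[2]", "st"] == pytest.approx(50.0)


def test_chull_flat_hull_flags_no_elbow():
    tab = _table(
        [("[1]", -100.0, 0.0, 1, 10), ("[2]", -90.0, 1.0, 1, 20),
         ("[1 1]", -80.0, 2.0, 1, 30), ("[2 1]", -70.0, 3.0, 1, 40)]
    )
    res = lmfa.chull_select(tab)
    st = res.hull["st"].dropna()
    assert np.allclose(st, 1.0)
    assert res.inflation_flag


def test_chull_needs_three_models():
    tab = _table([("[1]", -100.0, 0.0, 1, 10), ("[2]", -50.0, 1.0, 1, 20)])
    with pytest.raises(ValueError, match="CHull undefined"):
        lmfa.chull_select(tab)


def test_chull_drops_nonconverged_models():
    tab = _table(
        [("[1]", -100.0, 0.0, 1, 10), ("[2]", -50.0, 1.0, 1, 20),
         ("[1 1]", -49.0, 2.0, 1, 30), ("[2 2]", -10.0, 3.0, 0, 40)]
    )
    res = lmfa.chull_select(tab)
    assert "[2 2]" not in res.hull.index


# ----------------------------------------------------------------------
def test_standardized_loading_unit_variance_decomposition():
    model = lmfa.MeasurementModel(
        [np.array([[1.0], [0.0]])], np.zeros((1, 2)), np.ones((1, 2)), np.ones(1)
    )
    std_pat, std_uni = lmfa.standardize_loadings(
        [model.loadings[0]], model
    )
    assert std_pat[0][0, 0] == pytest.approx(1 / np.sqrt(2))
    assert std_pat[0][1, 0] == 0.0
    assert std_uni[0, 1] == 1.0
    # communality + uniqueness = 1 for a one-factor state
    assert np.allclose(std_pat[0][:, 0] ** 2 + std_uni[0], 1.0)


def test_factor_scores_zero_at_intercepts(small_study, step1_fit):
    _, data, _ = small_study
    scored = lmfa.factor_scores(data, step1_fit)
    # scoring the intercept vector of state k gives zero for state k
    model = step1_fit.model
    for k in range(model.n_states):
        A = (
            step1_fit.rotated.phi[k]
            @ step1_fit.rotated.pattern[k].T
            @ np.linalg.inv(model.implied_cov(k))
        )
        assert np.allclose(A @ np.zeros(model.n_indicators), 0.0)
    assert {"S1F1", "S2F1", "S3F1"} <= set(scored.columns)


def test_factor_scores_track_true_scores(small_study, step1_fit):
    cfg, data, truth = small_study
    scored = lmfa.factor_scores(data, step1_fit)
    mapping = _match_states(step1_fit, cfg)
    true_state = truth["state"].to_numpy()
    checked = 0
    for k_fit, k_true in enumerate(mapping):
        rows = true_state == k_true + 1
        F = cfg.n_factors[k_true]
        if step1_fit.model.n_factors[k_fit] != F or rows.sum() < 50:
            continue
        for f_true in range(F):
            eta = truth.loc[rows, f"eta{f_true + 1}"].to_numpy()
            best = max(
                abs(np.corrcoef(
                    eta, scored.loc[rows, f"S{k_fit + 1}F{f + 1}"]
                )[0, 1])
                for f in range(F)
            )
            assert best > 0.8
            checked += 1
    assert checked >= 3


def test_summary_step1_prints_fit_statistics(step1_fit):
    text = lmfa.summary_step1(step1_fit)
    assert "BIC" in text and "Intercepts" in text
    assert f"n_par = {step1_fit.n_par}" in text
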