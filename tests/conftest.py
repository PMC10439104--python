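import dataclasses

import numpy as np
import pandas as pd
import pytest

import lmfa

# baseline intensities of the no-covariate variant: the tutorial-style
# config's rates at sample-mean covariate scores
NOCOV_RATES = np.array([0.155, 0.10, 0.10, 0.33, 0.28, 0.14])


def no_covariate_config(**overrides) -> lmfa.GeneratorConfig:
    """Tutorial-style generator without covariates (intercept-only rates)."""
    base = lmfa.default_tutorial_config()
    cfg = dataclasses.replace(
        base,
        transition_covariates=[],
        beta=np.log(NOCOV_RATES)[:, None],
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def make_panel(rows: list[dict], indicators: list[str], **kw) -> lmfa.ILDataset:
    """Build a validated dataset from literal row dicts."""
    frame = pd.DataFrame(rows)
    return lmfa.build_dataset(frame, kw.pop("id_col", "id"), indicators, **kw)


def check_fit_invariants(fit: "lmfa.Step1Fit", data: lmfa.ILDataset) -> None:
    """EM monotonicity, BIC identity and rotation invariance of one fit."""
    # the loglikelihood never decreased during any EM start
    assert fit.max_ll_decrease <= 1e-6 * (1.0 + abs(fit.loglik))
    assert np.all(np.diff(fit.ll_trace) >= -1e-6 * (1.0 + abs(fit.loglik)))
    # BIC = -2 LL + n_par ln N
    assert fit.bic == pytest.approx(
        -2.0 * fit.loglik + fit.n_par * np.log(data.n_rows), rel=1e-12
    )
    # the rotated solution implies the same common covariance, hence the
    # same loglikelihood
    model = fit.model
    rot_loadings = [
        fit.rotated.pattern[k] @ np.linalg.cholesky(fit.rotated.phi[k])
        for k in range(model.n_states)
    ]
    for k in range(model.n_states):
        assert np.allclose(
            rot_loadings[k] @ rot_loadings[k].T,
            model.loadings[k] @ model.loadings[k].T,
            atol=1e-8,
        )
    rot_model = lmfa.MeasurementModel(
        rot_loadings, model.intercepts, model.uniquenesses, model.mixing
    )
    ll_rot = lmfa.loglik_step1(data, rot_model)
    assert abs(ll_rot - fit.loglik) < 1e-8 + 1e-12 * abs(fit.loglik)


@pytest.fixture(scope="session")
def small_study():
    """30-subject draw from the tutorial-style generator, with ground truth."""
    cfg = lmfa.default_tutorial_config()
    cfg.n_subjects = 30
    data, truth = lmfa.simulate_lmfa(cfg, seed=11)
    return cfg, data, truth


@pytest.fixture(scope="session")
def step1_fit(small_study):
    cfg, data, truth = small_study
    fit = lmfa.fit_step1(
        data, 3, [3, 2, 3], n_starts=3, max_iterations=200,
        tolerance=1e-6, seed=7,
    )
    check_fit_invariants(fit, data)
    return fit


@pytest.fixture(scope="session")
def classification(small_study, step1_fit):
    _, data, _ = small_study
    return lmfa.classify(data, step1_fit)
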