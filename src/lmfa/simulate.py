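"""Synthetic intensive longitudinal data from a fully specified model.

The generator draws, per subject, a number of occasions and irregular
intervals, simulates a continuous-time latent Markov state sequence whose
intensities depend on covariates, and emits indicator vectors from the
state-specific factor model y = nu_k + Lambda_k eta + eps with eta ~
N(0, Phi_k) and eps ~ N(0, Psi_k).  State transitions over an interval use a
single matrix-exponential jump with covariates held at their origin-occasion
values, which matches the likelihood of the fitted model exactly.

:func:`default_tutorial_config` emulates the structure of a typical
experience-sampling affect study: 100 subjects, about 48 occasions each at
irregular intervals (unit: days), 18 indicators on a 0-100 scale, three
well-separated states with [3, 2, 3] factors, and two time-varying
covariates acting on the transition intensities — a binary "intervention"
that switches on for a random half of the subjects after a third of their
participation, and a continuous "negative event" score drawn independently
per occasion.  The parameter values are this package's own choices for a
well-conditioned study design, not a reproduction of any distributed
dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ILDataset, build_dataset
from .step3 import initial_probs, intensity_matrix, transition_matrix

__all__ = ["GeneratorConfig", "default_tutorial_config", "simulate_lmfa"]


@dataclass
class GeneratorConfig:
    """Complete specification of a data-generating latent Markov factor model."""

    n_subjects: int
    occasions_mean: float
    occasions_sd: float
    occasions_min: int
    occasions_max: int
    interval_mean: float
    interval_sd: float
    interval_min: float
    pattern: list[np.ndarray]  # rotated loadings per state, (J, F_k)
    phi: list[np.ndarray]  # factor correlations per state
    intercepts: np.ndarray  # (K, J)
    uniquenesses: np.ndarray  # (K, J)
    gamma: np.ndarray  # (K-1, 1 + P_init) initial-state logit coefficients
    beta: np.ndarray  # (K(K-1), 1 + P_trans) log-intensity coefficients
    initial_covariates: list[str] = field(default_factory=list)
    transition_covariates: list[str] = field(default_factory=list)
    intervention_fraction: float = 0.5  # share of subjects that get the intervention
    intervention_onset: float = 1.0 / 3.0  # fraction of occasions before onset
    negevent_mean: float = 49.65
    negevent_sd: float = 15.11
    indicator_names: list[str] | None = None
    seed: int | None = None

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.pattern)

    @property
    def n_indicators(self) -> int:
        return self.intercepts.shape[1]

    @property
    def n_factors(self) -> list[int]:
        return [p.shape[1] for p in self.pattern]

    def validate(self) -> None:
        K, J = self.n_states, self.n_indicators
        if self.intercepts.shape != (K, J) or self.uniquenesses.shape != (K, J):
            raise ValueError("intercepts/uniquenesses must be K x J")
        if np.any(self.uniquenesses <= 0):
            raise ValueError("unique variances must be positive")
        if self.interval_min <= 0 or self.interval_mean <= 0:
            raise ValueError("intervals must be positive")
        for p, ph in zip(self.pattern, self.phi):
            if ph.shape != (p.shape[1], p.shape[1]):
                raise ValueError("phi dimensions must match the pattern")
            np.linalg.cholesky(ph)
        if self.gamma.shape[0] != K - 1:
            raise ValueError("gamma must have K-1 rows")
        if self.beta.shape[0] != K * (K - 1):
            raise ValueError("beta must have K(K-1) rows")

    # -- plain-text round trip -----------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("pattern", "phi"):
            d[key] = [np.asarray(a).tolist() for a in d[key]]
        for key in ("intercepts", "uniquenesses", "gamma", "beta"):
            d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        d["pattern"] = [np.asarray(a, float) for a in d["pattern"]]
        d["phi"] = [np.asarray(a, float) for a in d["phi"]]
        for key in ("intercepts", "uniquenesses", "gamma", "beta"):
            d[key] = np.asarray(d[key], float)
        return cls(**d)


# ----------------------------------------------------------------------
def default_tutorial_config(seed: int | None = None) -> GeneratorConfig:
    """Three well-separated states with [3, 2, 3] factors and 18 indicators.

    Standardized primary loadings are ~.7 (loading 10, unique variance 100 on
    a 0-100 scale) and state intercepts differ by at least one within-state
    SD, so states are recoverable.  Baseline intensities at sample-mean
    covariates produce moderate switching over a mean interval; the
    intervention lowers the rates into state 1 and raises the rates out of
    it, and higher negative-event scores do the opposite.
    """
    J = 18
    pa = list(range(10))  # "positive affect" block
    na = list(range(10, 18))  # "negative affect" block

    def block_pattern(blocks: list[list[int]]) -> np.ndarray:
        P = np.zeros((J, len(blocks)))
        for f, items in enumerate(blocks):
            P[items, f] = 10.0
        return P

    pattern = [
        block_pattern([pa, list(range(10, 15)), list(range(15, 18))]),
        block_pattern([pa, na]),
        block_pattern([list(range(0, 6)), list(range(6, 12)), list(range(12, 18))]),
    ]
    phi = [
        np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.15], [0.1, 0.15, 1.0]]),
        np.array([[1.0, -0.3], [-0.3, 1.0]]),
        np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.1], [0.2, 0.1, 1.0]]),
    ]
    intercepts = np.zeros((3, J))
    intercepts[0, pa], intercepts[0, na] = 40.0, 60.0  # displeasure
    intercepts[1, pa], intercepts[1, na] = 70.0, 30.0  # pleasure
    intercepts[2, pa], intercepts[2, na] = 55.0, 45.0  # neutral
    uniquenesses = np.full((3, J), 100.0)

    # initial probabilities (.42, .34, .24), no initial covariates
    gamma = np.array([[np.log(0.34 / 0.42)], [np.log(0.24 / 0.42)]])

    # intensities at sample-mean covariate scores; rows (1->2), (1->3),
    # (2->1), (2->3), (3->1), (3->2)
    q_mean = np.array([0.155, 0.10, 0.10, 0.33, 0.28, 0.14])
    eff_intervention = np.array([0.5, 0.5, -0.7, 0.0, -0.7, 0.0])
    eff_negevent = np.array([-0.015, -0.015, 0.02, 0.0, 0.02, 0.0])
    mean_intervention = 0.5 * (1 - 1.0 / 3.0)  # half the subjects, on for 2/3
    mean_negevent = 49.65
    beta = np.column_stack(
        [
            np.log(q_mean)
            - eff_intervention * mean_intervention
            - eff_negevent * mean_negevent,
            eff_intervention,
            eff_negevent,
        ]
    )

    return GeneratorConfig(
        n_subjects=100,
        occasions_mean=47.76,
        occasions_sd=6.56,
        occasions_min=30,
        occasions_max=60,
        interval_mean=1.22,
        interval_sd=1.02,
        interval_min=0.05,
        pattern=pattern,
        phi=phi,
        intercepts=intercepts,
        uniquenesses=uniquenesses,
        gamma=gamma,
        beta=beta,
        transition_covariates=["intervention", "neg_event"],
        indicator_names=[f"y{j + 1}" for j in range(J)],
        seed=seed,
    )


# ----------------------------------------------------------------------
def simulate_lmfa(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[ILDataset, pd.DataFrame]:
    """Draw a dataset and its ground truth from the configured model.

    Returns the validated dataset and a truth frame holding, per row, the
    simulated state and the true factor scores of that state's model
    (columns eta1..eta_Fmax, NaN-padded).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    K, J = config.n_states, config.n_indicators
    Fmax = max(config.n_factors)
    names = config.indicator_names or [f"y{j + 1}" for j in range(J)]
    has_cov = bool(config.transition_covariates)

    # gamma interval parameters from mean/SD
    shape = (config.interval_mean / config.interval_sd) ** 2
    scale = config.interval_sd**2 / config.interval_mean

    chol_phi = [np.linalg.cholesky(p) for p in config.phi]
    sd_eps = np.sqrt(config.uniquenesses)

    intervention_subjects = rng.random(config.n_subjects) < config.intervention_fraction

    rows = []
    truth = []
    for i in range(config.n_subjects):
        T = int(np.clip(
            round(rng.normal(config.occasions_mean, config.occasions_sd)),
            config.occasions_min, config.occasions_max,
        ))
        intervals = np.maximum(
            rng.gamma(shape, scale, size=T), config.interval_min
        )
        onset = int(np.ceil(config.intervention_onset * T))
        interv = np.zeros(T)
        if intervention_subjects[i]:
            interv[onset:] = 1.0
        negev = np.clip(
            rng.normal(config.negevent_mean, config.negevent_sd, size=T), 0.0, 100.0
        )
        X = np.column_stack([interv, negev]) if has_cov else np.zeros((T, 0))

        # latent state path
        states = np.empty(T, dtype=int)
        pi = initial_probs(config.gamma)
        states[0] = rng.choice(K, p=pi)
        for t in range(1, T):
            Q = intensity_matrix(config.beta, X[t - 1])
            P = transition_matrix(Q, intervals[t])
            states[t] = rng.choice(K, p=np.maximum(P[states[t - 1]], 0) /
                                   np.maximum(P[states[t - 1]], 0).sum())

        # responses
        for t in range(T):
            k = states[t]
            F = config.n_factors[k]
            eta = chol_phi[k] @ rng.standard_normal(F)
            y = (
                config.intercepts[k]
                + config.pattern[k] @ eta
                + sd_eps[k] * rng.standard_normal(J)
            )
            row = {"id": i + 1, "interval": intervals[t]}
            row.update(zip(names, y))
            if has_cov:
                row["intervention"] = interv[t]
                row["neg_event"] = negev[t]
            rows.append(row)
            tr = {"id": i + 1, "occasion": t + 1, "state": k + 1}
            for f in range(Fmax):
                tr[f"eta{f + 1}"] = eta[f] if f < F else np.nan
            truth.append(tr)

    frame = pd.DataFrame(rows)
    data = build_dataset(
        frame,
        id_col="id",
        indicator_cols=names,
        interval_col="interval",
        covariate_cols=list(config.transition_covariates),
    )
    return data, pd.DataFrame(truth)
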