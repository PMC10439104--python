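"""Independent reference computations used to validate the implementation.

Everything here is deliberately naive — direct summation, explicit path
enumeration, truncated series — and shares no code with the package's own
algorithms.
"""

import itertools

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import multivariate_normal

import lmfa


def mixture_loglik_direct(y, model: "lmfa.MeasurementModel") -> float:
    """Term-by-term mixture loglikelihood in extended precision."""
    total = 0.0
    for row in np.atleast_2d(y):
        acc = 0.0
        for k in range(model.n_states):
            acc += float(model.mixing[k]) * multivariate_normal.pdf(
                row, mean=model.intercepts[k], cov=model.implied_cov(k)
            )
        total += np.log(acc)
    return float(total)


def random_panel(rng, K=3, max_T=6, n_subjects=3):
    """Tiny random panel + modal sequence + emission + parameters."""
    rows = []
    for i in range(n_subjects):
        T = int(rng.integers(1, max_T + 1))
        for _ in range(T):
            rows.append(
                {"id": i + 1, "interval": float(rng.uniform(0.2, 2.0)), "y1": 0.0}
            )
    data = lmfa.build_dataset(pd.DataFrame(rows), "id", ["y1"], "interval")
    modal = rng.integers(1, K + 1, size=data.n_rows)
    E = rng.dirichlet(np.ones(K), size=K).T
    E = E / E.sum(axis=0)  # columns: P(modal | true)
    gamma = rng.normal(0.0, 1.0, (K - 1, 1))
    beta = rng.normal(np.log(0.3), 0.5, (K * (K - 1), 1))
    return data, modal, E, gamma, beta


def enumerate_loglik(data, modal, E, gamma, beta) -> float:
    """Brute-force loglikelihood: sum over all K^T latent state paths."""
    K = E.shape[0]
    pi = lmfa.initial_probs(gamma)
    Q = lmfa.intensity_matrix(beta)
    ll = 0.0
    for _, sl in data.subject_slices():
        T = sl.stop - sl.start
        iv = data.intervals[sl][1:]
        m = modal[sl]
        Ps = [expm(Q * d) for d in iv]
        tot = 0.0
        for path in itertools.product(range(K), repeat=T):
            p = pi[path[0]] * E[m[0] - 1, path[0]]
            for j in range(1, T):
                p *= Ps[j - 1][path[j - 1], path[j]] * E[m[j] - 1, path[j]]
            tot += p
        ll += np.log(tot)
    return float(ll)


def enumerate_smoothed_posteriors(data, modal, E, gamma, beta):
    """Per-row smoothed state posteriors by explicit path marginalization."""
    K = E.shape[0]
    pi = lmfa.initial_probs(gamma)
    Q = lmfa.intensity_matrix(beta)
    out = np.zeros((data.n_rows, K))
    for _, sl in data.subject_slices():
        T = sl.stop - sl.start
        iv = data.intervals[sl][1:]
        m = modal[sl]
        Ps = [expm(Q * d) for d in iv]
        for path in itertools.product(range(K), repeat=T):
            p = pi[path[0]] * E[m[0] - 1, path[0]]
            for j in range(1, T):
                p *= Ps[j - 1][path[j - 1], path[j]] * E[m[j] - 1, path[j]]
            for j in range(T):
                out[sl.start + j, path[j]] += p
    out /= out.sum(axis=1, keepdims=True)
    return out


def expm_series(A, n_terms=60):
    """Truncated Taylor series for the matrix exponential."""
    out = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, n_terms):
        term = term @ A / k
        out = out + term
    return out


def dt_forward_loglik(modal, lengths, pi, P, E):
    """Discrete-time HMM forward loglikelihood (unit intervals)."""
    ll = 0.0
    start = 0
    for T in lengths:
        m = modal[start : start + T]
        a = pi * E[m[0] - 1]
        c = a.sum()
        ll += np.log(c)
        a /= c
        for j in range(1, T):
            a = (a @ P) * E[m[j] - 1]
            c = a.sum()
            ll += np.log(c)
            a /= c
        start += T
    return float(ll)
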