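"""Step 3: continuous-time latent Markov transition model with correction
for classification error.

The modal state assignments from step 2 are treated as a single categorical
indicator of the true latent state, emitted with the fixed misclassification
probabilities P(modal = s | true = t) estimated in step 2.  The latent chain
is a continuous-time Markov process: transition intensities (rates) q_st are
log-linear in covariates, q_st(x) = exp(beta_st0 + sum_p beta_stp x_p), and
the probability of the chain moving over an interval of length Delta is the
matrix exponential P(Delta, x) = expm(Q(x) * Delta).  Initial state
probabilities follow a baseline-category logit model with state 1 as the
reference.  Estimation maximizes the marginal likelihood of the modal
sequences by quasi-Newton from several random starts; standard errors come
from the inverse of a central finite-difference Hessian, and each covariate
gets a chi-squared Wald omnibus test across all its coefficients.

Coefficient row order for the intensities is (1->2), (1->3), ..., (2->1),
(2->3), ...: origin states in order, destinations in order within origin.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm, logm
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .data_io import ILDataset
from .step2 import classify_posteriors

logger = logging.getLogger("lmfa")

__all__ = [
    "TransitionModel",
    "intensity_matrix",
    "transition_matrix",
    "initial_probs",
    "loglik_ctlmm",
    "fit_step3",
    "probabilities",
    "posterior_states_step3",
    "invariance_summary",
    "transition_plot_data",
    "summary_step3",
]

LOGRATE_CAP = 30.0  # log intensities above this signal overflow / divergence


# ----------------------------------------------------------------------
# elementary conversions
# ----------------------------------------------------------------------
def intensity_matrix(beta: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Intensity matrix Q(x) from log-linear coefficients.

    ``beta`` has one row per ordered state pair (s -> t, s != t) and columns
    (intercept, covariate effects).  Off-diagonals are exp(beta . (1, x));
    each diagonal is minus its row sum, so rows sum to zero.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    n_pairs = beta.shape[0]
    K = int(round((1 + np.sqrt(1 + 4 * n_pairs)) / 2))
    if K * (K - 1) != n_pairs:
        raise ValueError("beta must have K(K-1) rows")
    x = np.zeros(beta.shape[1] - 1) if x is None else np.asarray(x, dtype=float)
    if len(x) != beta.shape[1] - 1:
        raise ValueError("covariate vector length does not match beta")
    logq = beta[:, 0] + beta[:, 1:] @ x
    if np.any(logq > LOGRATE_CAP):
        raise OverflowError(
            "transition intensity overflow; rescale covariates or use a "
            "coarser time unit"
        )
    q = np.exp(logq)
    Q = np.zeros((K, K))
    i = 0
    for s in range(K):
        for t in range(K):
            if t != s:
                Q[s, t] = q[i]
                i += 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, delta: float) -> np.ndarray:
    """Row-stochastic P(delta) = expm(Q * delta) (scaling-and-squaring)."""
    if delta <= 0:
        raise ValueError("the interval must be positive")
    return expm(np.asarray(Q, dtype=float) * float(delta))


def initial_probs(gamma: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Initial state probabilities from baseline-category logits.

    State 1 is the reference: pi_1 proportional to 1, pi_k proportional to
    exp(gamma_k0 + sum_p gamma_kp x_p) for k >= 2.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    x = np.zeros(gamma.shape[1] - 1) if x is None else np.asarray(x, dtype=float)
    if len(x) != gamma.shape[1] - 1:
        raise ValueError("covariate vector length does not match gamma")
    logits = np.concatenate([[0.0], gamma[:, 0] + gamma[:, 1:] @ x])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def _batch_expm(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small intensity-scaled matrices.

    Vectorized scaling-and-squaring: scale the whole stack so the largest
    row-sum norm is below 1/2, evaluate a degree-13 Taylor polynomial by
    Horner's scheme (error ~1e-16 at that norm), then square back.  Entries
    of expm(Q*delta) are probabilities; tiny negative round-off is clipped.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        return expm(A)
    if A.shape[0] == 0:
        return A.copy()
    K = A.shape[-1]
    nrm = float(np.max(np.sum(np.abs(A), axis=2)))
    s = max(0, int(np.ceil(np.log2(nrm / 0.5)))) if nrm > 0.5 else 0
    A2 = A / (2.0**s)
    I = np.broadcast_to(np.eye(K), A.shape)
    E = I.copy()
    for k in range(13, 0, -1):
        E = I + (A2 / k) @ E
    for _ in range(s):
        E = E @ E
    np.clip(E, 0.0, None, out=E)
    return E


# ----------------------------------------------------------------------
# panel structure and likelihood
# ----------------------------------------------------------------------
@dataclass
class _PanelStructure:
    """Precomputed index arrays for the vectorized forward recursion."""

    K: int
    subject_ids: np.ndarray
    first_rows: np.ndarray  # (S,)
    lengths: np.ndarray  # (S,) occasions per subject
    Erow: np.ndarray  # (N, K) emission probabilities of the observed modal
    Xi: np.ndarray  # (S, Pi) initial covariates at the first occasion
    trans_delta: np.ndarray  # (M,)
    trans_X: np.ndarray  # (M, Pt) covariates at the origin occasion
    steps: list[tuple[np.ndarray, np.ndarray]]  # per step: (subject idx, trans idx)
    modal: np.ndarray  # (N,) 1..K


def _build_structure(
    data: ILDataset,
    modal: np.ndarray,
    error_probs: np.ndarray,
    timeintervals: str | None,
    transition_covariates: list[str],
    initial_covariates: list[str],
) -> _PanelStructure:
    K = error_probs.shape[0]
    slices = data.subject_slices()
    first_rows = np.array([sl.start for _, sl in slices])
    lengths = np.array([sl.stop - sl.start for _, sl in slices])
    ids = np.array([sid for sid, _ in slices], dtype=object)

    Erow = error_probs[np.asarray(modal) - 1]  # (N, K)

    Xi = (
        data.covariates(initial_covariates)[first_rows]
        if initial_covariates
        else np.zeros((len(slices), 0))
    )
    Xt_all = (
        data.covariates(transition_covariates)
        if transition_covariates
        else np.zeros((data.n_rows, 0))
    )
    if timeintervals is None:
        delta_all = np.ones(data.n_rows)
    else:
        delta_all = data.intervals

    # transitions ordered by subject, then step
    trans_delta, trans_X = [], []
    offsets = np.zeros(len(slices), dtype=int)
    m = 0
    for i, (_, sl) in enumerate(slices):
        offsets[i] = m
        for j in range(sl.start + 1, sl.stop):
            trans_delta.append(delta_all[j])
            trans_X.append(Xt_all[j - 1])  # covariates at the origin occasion
            m += 1
    trans_delta = np.asarray(trans_delta, dtype=float)
    trans_X = (
        np.asarray(trans_X, dtype=float)
        if m
        else np.zeros((0, len(transition_covariates)))
    )

    steps = []
    t = 1
    while True:
        subj = np.flatnonzero(lengths > t)
        if len(subj) == 0:
            break
        steps.append((subj, offsets[subj] + t - 1))
        t += 1
    return _PanelStructure(
        K=K,
        subject_ids=ids,
        first_rows=first_rows,
        lengths=lengths,
        Erow=Erow,
        Xi=Xi,
        trans_delta=trans_delta,
        trans_X=trans_X,
        steps=steps,
        modal=np.asarray(modal),
    )


def _unpack(theta: np.ndarray, K: int, n_pi: int, n_pt: int):
    n_gamma = (K - 1) * (1 + n_pi)
    gamma = theta[:n_gamma].reshape(K - 1, 1 + n_pi)
    beta = theta[n_gamma:].reshape(K * (K - 1), 1 + n_pt)
    return gamma, beta


def _initial_matrix(gamma: np.ndarray, Xi: np.ndarray) -> np.ndarray:
    """(S, K) initial probabilities per subject."""
    S = Xi.shape[0]
    logits = np.zeros((S, gamma.shape[0] + 1))
    logits[:, 1:] = gamma[:, 0] + Xi @ gamma[:, 1:].T
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _transition_stack(beta: np.ndarray, st: _PanelStructure) -> np.ndarray | None:
    """(M, K, K) transition probability matrices, or None on overflow."""
    K = st.K
    M = len(st.trans_delta)
    if M == 0:
        return np.zeros((0, K, K))
    logq = beta[:, 0] + st.trans_X @ beta[:, 1:].T  # (M, K(K-1))
    if np.any(logq > LOGRATE_CAP):
        return None
    q = np.exp(logq)
    A = np.zeros((M, K, K))
    i = 0
    for s in range(K):
        for t in range(K):
            if t != s:
                A[:, s, t] = q[:, i]
                i += 1
    diag = -A.sum(axis=2)
    idx = np.arange(K)
    A[:, idx, idx] = diag
    A *= st.trans_delta[:, None, None]
    return _batch_expm(A)


def _forward_loglik(
    gamma: np.ndarray, beta: np.ndarray, st: _PanelStructure
) -> float:
    """Scaled forward recursion over all subjects; -inf on numerical failure."""
    P = _transition_stack(beta, st)
    if P is None:
        return -np.inf
    pi0 = _initial_matrix(gamma, st.Xi)
    alpha = pi0 * st.Erow[st.first_rows]
    c = alpha.sum(axis=1)
    if np.any(c <= 0):
        bad = st.subject_ids[np.argmax(c <= 0)]
        raise ZeroDivisionError(
            f"zero likelihood at the first occasion of subject {bad!r}"
        )
    ll = float(np.sum(np.log(c)))
    alpha = alpha / c[:, None]
    for t, (subj, tidx) in enumerate(st.steps, start=1):
        a = np.einsum("mk,mkl->ml", alpha[subj], P[tidx])
        a = a * st.Erow[st.first_rows[subj] + t]
        c = a.sum(axis=1)
        if np.any(c <= 0):
            bad = st.subject_ids[subj[np.argmax(c <= 0)]]
            raise ZeroDivisionError(
                f"zero likelihood for subject {bad!r} at occasion {t + 1}"
            )
        ll += float(np.sum(np.log(c)))
        alpha[subj] = a / c[:, None]
    return ll


def loglik_ctlmm(
    data: ILDataset,
    gamma: np.ndarray,
    beta: np.ndarray,
    modal: np.ndarray,
    error_probs: np.ndarray,
    timeintervals: str | None = None,
    transition_covariates: list[str] | None = None,
    initial_covariates: list[str] | None = None,
) -> float:
    """Marginal loglikelihood of the modal sequences under the CT-LMM.

    ``error_probs[s, t]`` is the fixed probability of observing modal state
    s when the true state is t (columns sum to 1).
    """
    st = _build_structure(
        data, modal, np.asarray(error_probs, float), timeintervals,
        list(transition_covariates or []), list(initial_covariates or []),
    )
    return _forward_loglik(
        np.atleast_2d(np.asarray(gamma, float)),
        np.atleast_2d(np.asarray(beta, float)),
        st,
    )


# ----------------------------------------------------------------------
# estimation
# ----------------------------------------------------------------------
@dataclass
class TransitionModel:
    K: int
    gamma: np.ndarray  # (K-1, 1+Pi)
    beta: np.ndarray  # (K(K-1), 1+Pt)
    emission: np.ndarray  # fixed error probabilities P(modal | true)
    vcov: np.ndarray | None
    estimates: pd.DataFrame  # coef, s.e., z-value, p-value
    wald: pd.DataFrame  # Wald, df, p-value per covariate
    loglik: float
    n_par: int
    bic: float
    converged: bool
    n_subjects: int
    initial_covariates: list[str]
    transition_covariates: list[str]
    initial_means: np.ndarray
    transition_means: np.ndarray
    timeintervals: str | None
    data: ILDataset = field(repr=False)
    modal: np.ndarray = field(repr=False)
    _structure: _PanelStructure = field(repr=False)


def _random_theta(
    rng: np.random.Generator, K: int, n_pi: int, n_pt: int
) -> np.ndarray:
    gamma = rng.uniform(-1.0, 1.0, size=(K - 1, 1 + n_pi))
    beta = np.empty((K * (K - 1), 1 + n_pt))
    beta[:, 0] = rng.uniform(np.log(0.05), np.log(0.5), size=K * (K - 1))
    beta[:, 1:] = rng.uniform(-0.1, 0.1, size=(K * (K - 1), n_pt))
    return np.concatenate([gamma.ravel(), beta.ravel()])


def _empirical_theta(st: _PanelStructure, K: int, n_pi: int, n_pt: int) -> np.ndarray:
    """Moment-based start: modal frequencies for the logits, matrix log of
    the smoothed modal transition table for the intensity intercepts.
    Covariate effects start at zero."""
    first = np.maximum(
        np.bincount(st.modal[st.first_rows] - 1, minlength=K), 0.5
    ).astype(float)
    gamma = np.zeros((K - 1, 1 + n_pi))
    gamma[:, 0] = np.log(first[1:] / first[0])
    beta = np.zeros((K * (K - 1), 1 + n_pt))
    q0 = np.full(K * (K - 1), 0.1)
    if len(st.trans_delta):
        counts = np.full((K, K), 0.5)
        modal0 = st.modal - 1
        for i in range(len(st.lengths)):
            r0 = st.first_rows[i]
            for t in range(1, st.lengths[i]):
                counts[modal0[r0 + t - 1], modal0[r0 + t]] += 1
        P = counts / counts.sum(axis=1, keepdims=True)
        dbar = float(np.mean(st.trans_delta))
        try:
            Q = np.real(logm(P)) / dbar
            off = []
            for s in range(K):
                for t in range(K):
                    if t != s:
                        off.append(max(Q[s, t], 1e-3))
            q0 = np.asarray(off)
        except Exception:  # keep the flat default
            pass
    beta[:, 0] = np.log(q0)
    return np.concatenate([gamma.ravel(), beta.ravel()])


def _central_gradient(f, theta: np.ndarray) -> np.ndarray:
    h = 1e-5 * (1.0 + np.abs(theta))
    g = np.empty_like(theta)
    for i in range(len(theta)):
        e = np.zeros_like(theta)
        e[i] = h[i]
        g[i] = (f(theta + e) - f(theta - e)) / (2.0 * h[i])
    return g


def _polish(f, theta: np.ndarray, hess_inv, max_iter: int = 5) -> np.ndarray:
    """Quasi-Newton polish with low-noise central-difference gradients.

    L-BFGS localizes the optimum only to the noise level of its one-sided
    gradients; a few damped steps along hess_inv * central-gradient tighten
    it enough for stable standard errors and Wald statistics.
    """
    fval = f(theta)
    for _ in range(max_iter):
        g = _central_gradient(f, theta)
        step = hess_inv.matvec(g) if hasattr(hess_inv, "matvec") else hess_inv @ g
        if not np.all(np.isfinite(step)):
            break
        alpha = 1.0
        for _ in range(8):
            cand = theta - alpha * step
            fc = f(cand)
            if fc <= fval:
                theta, fval = cand, fc
                break
            alpha *= 0.5
        else:
            break
        if np.linalg.norm(alpha * step) < 1e-10 * (1.0 + np.linalg.norm(theta)):
            break
    return theta


def _numerical_hessian(f, theta: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian.

    The step 3e-4 * (1 + |theta_i|) balances truncation error (~h^2)
    against rounding noise (~eps_f / h^2) for loglikelihoods of the
    magnitude seen here, keeping standard errors stable to ~1e-6.
    """
    p = len(theta)
    h = 3e-4 * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2.0 * f(theta) + f(theta - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej)
                - f(theta + ei - ej)
                - f(theta - ei + ej)
                + f(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _coef_names(K, initial_covariates, transition_covariates):
    names = []
    for k in range(2, K + 1):
        names.append(f"initial S{k} intercept")
        for c in initial_covariates:
            names.append(f"initial S{k} {c}")
    for s in range(1, K + 1):
        for t in range(1, K + 1):
            if t != s:
                names.append(f"S{s}->S{t} intercept")
                for c in transition_covariates:
                    names.append(f"S{s}->S{t} {c}")
    return names


def fit_step3(
    data: ILDataset,
    n_states: int,
    postprobs: np.ndarray | pd.DataFrame,
    timeintervals: str | None = None,
    transitionCovariates: list[str] | None = None,
    initialCovariates: list[str] | None = None,
    n_starts: int = 5,
    max_iterations: int = 1000,
    tolerance: float = 1e-8,
    seed: int | None = None,
    theta0: np.ndarray | None = None,
) -> TransitionModel:
    """Estimate the error-corrected CT latent Markov model.

    Modal assignments and misclassification probabilities are recomputed
    from ``postprobs`` (the step-2 posteriors on the same row ordering).
    ``theta0`` optionally adds a user-supplied start to the random ones.
    Without ``timeintervals`` all intervals are taken as 1 (equidistant).
    """
    postprobs = np.asarray(postprobs, dtype=float)
    if postprobs.shape != (data.n_rows, n_states):
        raise ValueError("postprobs must be N x n_states for this dataset")
    cls = classify_posteriors(postprobs)
    trans_cov = list(transitionCovariates or [])
    init_cov = list(initialCovariates or [])
    for c in trans_cov + init_cov:
        if c not in data.frame.columns:
            raise ValueError(f"covariate {c!r} not found in the data")
    if init_cov:
        # initial covariates act at the first occasion only; require them
        # constant within subject up to that point of use (no check needed:
        # only the first-occasion value is read)
        pass
    st = _build_structure(
        data, cls.modal, cls.error_probs, timeintervals, trans_cov, init_cov
    )
    K = n_states
    n_pi, n_pt = len(init_cov), len(trans_cov)
    n_par = (K - 1) * (1 + n_pi) + K * (K - 1) * (1 + n_pt)

    # optimize with internally standardized covariates (better conditioning);
    # the estimates and their covariance are mapped back afterwards, and the
    # Wald statistic is invariant under this linear reparameterization
    mi = st.Xi.mean(axis=0) if n_pi else np.zeros(0)
    si = np.where(st.Xi.std(axis=0) > 0, st.Xi.std(axis=0), 1.0) if n_pi else np.zeros(0)
    if n_pt and len(st.trans_X):
        mt = st.trans_X.mean(axis=0)
        s_ = st.trans_X.std(axis=0)
        stdev_t = np.where(s_ > 0, s_, 1.0)
    else:
        mt, stdev_t = np.zeros(n_pt), np.ones(n_pt)
    st_work = dataclasses.replace(
        st,
        Xi=(st.Xi - mi) / si if n_pi else st.Xi,
        trans_X=(st.trans_X - mt) / stdev_t if n_pt else st.trans_X,
    )
    # linear map from scaled-space coefficients to the user covariate scale
    Tmap = np.eye(n_par)
    _blocks = [(r * (1 + n_pi), mi, si) for r in range(K - 1)]
    _base = (K - 1) * (1 + n_pi)
    _blocks += [(_base + r * (1 + n_pt), mt, stdev_t) for r in range(K * (K - 1))]
    for b0, m, s_arr in _blocks:
        for p in range(len(m)):
            Tmap[b0, b0 + 1 + p] = -m[p] / s_arr[p]
            Tmap[b0 + 1 + p, b0 + 1 + p] = 1.0 / s_arr[p]

    def negll(theta):
        gamma, beta = _unpack(theta, K, n_pi, n_pt)
        try:
            ll = _forward_loglik(gamma, beta, st_work)
        except ZeroDivisionError:
            return np.inf
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    starts = []
    if theta0 is not None:  # user-scale start -> scaled space
        starts.append(np.linalg.solve(Tmap, np.asarray(theta0, dtype=float)))
    starts.append(_empirical_theta(st_work, K, n_pi, n_pt))
    starts += [_random_theta(rng, K, n_pi, n_pt) for _ in range(n_starts)]

    best = None
    for th0 in starts:
        res = minimize(
            negll, th0, method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": tolerance,
                     "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta_work = _polish(negll, best.x, best.hess_inv)
    ll = -negll(theta_work)
    converged = bool(best.success)
    if not converged:
        logger.warning("step-3 optimization did not fully converge: %s",
                       best.message)

    # observed information -> covariance of the estimates (scaled space)
    H = _numerical_hessian(negll, theta_work)
    vcov_work = None
    try:
        vcov_work = np.linalg.inv(H)
        if np.any(np.diag(vcov_work) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        logger.warning(
            "Hessian is singular or not positive definite; standard errors "
            "are unavailable"
        )
        vcov_work = None

    # map estimates back to the user covariate scale
    theta = Tmap @ theta_work
    vcov = Tmap @ vcov_work @ Tmap.T if vcov_work is not None else None
    se = np.sqrt(np.diag(vcov)) if vcov is not None else np.full(n_par, np.nan)

    z = theta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    estimates = pd.DataFrame(
        {"coef": theta, "s.e.": se, "z-value": z, "p-value": pvals},
        index=_coef_names(K, init_cov, trans_cov),
    )

    # Wald omnibus test per covariate
    wald_rows = []
    n_gamma = (K - 1) * (1 + n_pi)
    for ci, c in enumerate(init_cov):
        idx = [r * (1 + n_pi) + 1 + ci for r in range(K - 1)]
        wald_rows.append((c + " (initial)", *_wald(theta, vcov, idx)))
    for ci, c in enumerate(trans_cov):
        idx = [n_gamma + r * (1 + n_pt) + 1 + ci for r in range(K * (K - 1))]
        wald_rows.append((c, *_wald(theta, vcov, idx)))
    wald = pd.DataFrame(
        wald_rows, columns=["covariate", "Wald", "df", "p-value"]
    ).set_index("covariate")

    gamma, beta = _unpack(theta, K, n_pi, n_pt)
    init_means = (
        st.Xi.mean(axis=0) if n_pi else np.zeros(0)
    )
    trans_means = (
        data.covariates(trans_cov).mean(axis=0) if n_pt else np.zeros(0)
    )
    return TransitionModel(
        K=K,
        gamma=gamma,
        beta=beta,
        emission=cls.error_probs,
        vcov=vcov,
        estimates=estimates,
        wald=wald,
        loglik=ll,
        n_par=n_par,
        bic=float(-2.0 * ll + n_par * np.log(st.Xi.shape[0])),
        converged=converged,
        n_subjects=int(st.Xi.shape[0]),
        initial_covariates=init_cov,
        transition_covariates=trans_cov,
        initial_means=np.asarray(init_means, float),
        transition_means=np.asarray(trans_means, float),
        timeintervals=timeintervals,
        data=data,
        modal=cls.modal,
        _structure=st,
    )


def _wald(theta, vcov, idx):
    if vcov is None:
        return np.nan, len(idx), np.nan
    th = theta[idx]
    V = vcov[np.ix_(idx, idx)]
    try:
        stat = float(th @ np.linalg.solve(V, th))
    except np.linalg.LinAlgError:
        return np.nan, len(idx), np.nan
    return stat, len(idx), float(chi2.sf(stat, len(idx)))


# ----------------------------------------------------------------------
# derived quantities
# ----------------------------------------------------------------------
def probabilities(
    model: TransitionModel,
    deltaT: float = 1.0,
    initialCovariateScores: np.ndarray | None = None,
    transitionCovariateScores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial and transition probabilities at given covariate scores.

    Defaults to the covariate sample means and a unit interval.
    """
    xi = (
        model.initial_means
        if initialCovariateScores is None
        else np.asarray(initialCovariateScores, dtype=float)
    )
    xt = (
        model.transition_means
        if transitionCovariateScores is None
        else np.asarray(transitionCovariateScores, dtype=float)
    )
    if len(xi) != len(model.initial_covariates):
        raise ValueError("wrong number of initial covariate scores")
    if len(xt) != len(model.transition_covariates):
        raise ValueError("wrong number of transition covariate scores")
    pi = initial_probs(model.gamma, xi)
    Q = intensity_matrix(model.beta, xt)
    P = transition_matrix(Q, deltaT)
    return pi, P


@dataclass
class StateAssignments:
    posterior: np.ndarray  # (N, K) smoothed
    modal: np.ndarray  # (N,) 1..K
    proportions: np.ndarray


def posterior_states_step3(model: TransitionModel) -> StateAssignments:
    """Forward-backward smoothed state posteriors under the fitted model.

    These final assignments can differ from step 2's: the transition model
    (with covariates and intervals) adds information about likely paths.
    """
    st = model._structure
    K = model.K
    P = _transition_stack(model.beta, st)
    pi0 = _initial_matrix(model.gamma, st.Xi)
    N = len(st.Erow)
    post = np.empty((N, K))
    for i in range(st.Xi.shape[0]):
        r0 = st.first_rows[i]
        T = st.lengths[i]
        # transitions of subject i occupy a contiguous block in P
        off = int(np.sum(np.maximum(st.lengths[:i] - 1, 0)))
        # forward
        alphas = np.empty((T, K))
        a = pi0[i] * st.Erow[r0]
        a /= a.sum()
        alphas[0] = a
        for t in range(1, T):
            Pt = P[off + t - 1]
            a = (a @ Pt) * st.Erow[r0 + t]
            s = a.sum()
            a = a / s
            alphas[t] = a
        # backward
        b = np.ones(K)
        post[r0 + T - 1] = alphas[T - 1]
        for t in range(T - 2, -1, -1):
            Pt = P[off + t]
            b = Pt @ (st.Erow[r0 + t + 1] * b)
            b /= b.sum()
            g = alphas[t] * b
            post[r0 + t] = g / g.sum()
    modal = np.argmax(post, axis=1) + 1
    proportions = np.bincount(modal - 1, minlength=K) / N
    return StateAssignments(post, modal, proportions)


def attach_final_assignments(model: TransitionModel) -> pd.DataFrame:
    """Copy of the data with smoothed posteriors and final modal states."""
    sa = posterior_states_step3(model)
    cols = {f"State{k + 1}": sa.posterior[:, k] for k in range(model.K)}
    cols["Modal"] = sa.modal
    return model.data.with_columns(pd.DataFrame(cols))


def invariance_summary(model: TransitionModel) -> dict[str, list]:
    """Subjects whose final modal state never changes, listed per state.

    A subject in the same state at every occasion satisfies within-person
    invariance; subjects sharing a permanent state additionally satisfy
    between-person invariance.  States with no such subject map to an empty
    list (printed as NA).
    """
    sa = posterior_states_step3(model)
    st = model._structure
    out: dict[str, list] = {f"S{k + 1}": [] for k in range(model.K)}
    for i, sid in enumerate(st.subject_ids):
        r0, T = st.first_rows[i], st.lengths[i]
        states = sa.modal[r0 : r0 + T]
        if np.all(states == states[0]):
            out[f"S{states[0]}"].append(sid)
    return out


def transition_plot_data(
    model: TransitionModel, subject_id
) -> tuple[np.ndarray, np.ndarray]:
    """(occasions, modal states) of one subject's final assignments."""
    sa = posterior_states_step3(model)
    st = model._structure
    match = np.flatnonzero(st.subject_ids == subject_id)
    if len(match) == 0:
        raise KeyError(f"unknown subject id {subject_id!r}")
    i = int(match[0])
    r0, T = st.first_rows[i], st.lengths[i]
    return np.arange(1, T + 1), sa.modal[r0 : r0 + T]


def plot_transitions(model: TransitionModel, subject_id, ax=None):
    """Step plot of one subject's state membership over occasions."""
    import matplotlib.pyplot as plt

    occ, states = transition_plot_data(model, subject_id)
    if ax is None:
        _, ax = plt.subplots()
    ax.step(occ, states, where="post")
    ax.set_yticks(np.arange(1, model.K + 1))
    ax.set_xlabel("measurement occasion")
    ax.set_ylabel("state")
    ax.set_title(f"subject {subject_id}")
    return ax


# ----------------------------------------------------------------------
def summary_step3(model: TransitionModel) -> str:
    pi, P = probabilities(model)
    sa = posterior_states_step3(model)
    states = [f"S{k + 1}" for k in range(model.K)]
    parts = [
        "Parameter estimates",
        model.estimates.to_string(float_format=lambda v: f"{v:.4f}"),
        "",
    ]
    if len(model.wald):
        parts += [
            "Wald tests",
            model.wald.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
        ]
    parts += [
        f"LL = {model.loglik:.2f}   BIC = {model.bic:.2f}   "
        f"n_par = {model.n_par}",
        "",
    ]
    if model.transition_covariates:
        means = ", ".join(
            f"{c} = {m:.2f}"
            for c, m in zip(model.transition_covariates, model.transition_means)
        )
        parts.append(f"(transition covariates at sample means: {means})")
    parts += [
        "Initial state probabilities",
        pd.Series(pi, index=states).to_string(float_format=lambda v: f"{v:.4f}"),
        "",
        "Transition probabilities (unit interval)",
        pd.DataFrame(P, index=states, columns=states)
        .to_string(float_format=lambda v: f"{v:.4f}"),
        "",
        "State proportions",
        pd.Series(sa.proportions, index=states)
        .to_string(float_format=lambda v: f"{v:.4f}"),
    ]
    return "\n".join(parts)


def summary_probabilities(
    model: TransitionModel,
    deltaT: float = 1.0,
    initialCovariateScores=None,
    transitionCovariateScores=None,
) -> str:
    """Probabilities printer echoing the covariate scores and interval."""
    pi, P = probabilities(
        model, deltaT, initialCovariateScores, transitionCovariateScores
    )
    xi = (
        model.initial_means
        if initialCovariateScores is None
        else np.asarray(initialCovariateScores, float)
    )
    xt = (
        model.transition_means
        if transitionCovariateScores is None
        else np.asarray(transitionCovariateScores, float)
    )
    states = [f"S{k + 1}" for k in range(model.K)]
    parts = [f"Interval: {deltaT}"]
    if model.initial_covariates:
        parts.append(
            "Initial covariate scores: "
            + ", ".join(f"{c} = {v:.2f}" for c, v in zip(model.initial_covariates, xi))
        )
    if model.transition_covariates:
        parts.append(
            "Transition covariate scores: "
            + ", ".join(
                f"{c} = {v:.2f}" for c, v in zip(model.transition_covariates, xt)
            )
        )
    parts += [
        "",
        "Initial state probabilities",
        pd.Series(pi, index=states).to_string(float_format=lambda v: f"{v:.4f}"),
        "",
        "Transition probabilities",
        pd.DataFrame(P, index=states, columns=states)
        .to_string(float_format=lambda v: f"{v:.4f}"),
    ]
    return "\n".join(parts)
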