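"""State-specific measurement models: mixture exploratory factor analysis.

Step 1 of the three-step estimator fits a mixture of factor-analysis models
to all observations while disregarding the temporal ordering: observation
y_it in state k follows N(nu_k, Lambda_k Lambda_k' + Psi_k) with mixing
proportions pi.  Factors are identified by fixing their covariance to the
identity and their means to zero per state, so state-specific intercepts are
state-specific item means.  Estimation is multistart EM; the M-step runs a
fixed number of inner EM iterations for factor analyzers on
posterior-weighted sufficient statistics, which makes every outer iteration
a generalized EM step and keeps the loglikelihood monotone.

Model selection compares candidate numbers of states/factors with BIC and
the convex-hull (CHull) scree procedure.  Interpretation uses obliquely
rotated, standardized loadings (see :mod:`lmfa.rotation`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

from .data_io import ILDataset
from .rotation import rotate_pattern

logger = logging.getLogger("lmfa")

__all__ = [
    "MeasurementModel",
    "RotatedView",
    "Step1Fit",
    "ModelSelectionTable",
    "CHullResult",
    "count_parameters",
    "ledermann_bound",
    "loglik_step1",
    "fit_step1",
    "enumerate_models",
    "model_selection",
    "chull_select",
    "rotate_oblique",
    "standardize_loadings",
    "factor_scores",
    "summary_step1",
]

# EM defaults; user-settable through fit_step1 / model_selection
DEFAULT_TOLERANCE = 1e-8
DEFAULT_MAX_ITERATIONS = 1000
INNER_FA_ITERATIONS = 25
PSI_FLOOR_FRACTION = 1e-4  # floor on unique variances, as fraction of item variance


# ----------------------------------------------------------------------
@dataclass
class MeasurementModel:
    """Per-state factor model: loadings, intercepts, unique variances, mixing."""

    loadings: list[np.ndarray]  # K matrices, each (J, F_k), identified (Phi = I)
    intercepts: np.ndarray  # (K, J)
    uniquenesses: np.ndarray  # (K, J), positive
    mixing: np.ndarray  # (K,), simplex

    @property
    def n_states(self) -> int:
        return len(self.loadings)

    @property
    def n_indicators(self) -> int:
        return self.intercepts.shape[1]

    @property
    def n_factors(self) -> list[int]:
        return [L.shape[1] for L in self.loadings]

    def implied_cov(self, k: int) -> np.ndarray:
        L = self.loadings[k]
        return L @ L.T + np.diag(self.uniquenesses[k])


@dataclass
class RotatedView:
    """Obliquely rotated, interpretable view of a measurement model."""

    pattern: list[np.ndarray]  # rotated loadings, (J, F_k) per state
    phi: list[np.ndarray]  # factor correlations, (F_k, F_k)
    std_pattern: list[np.ndarray]  # pattern / model-implied item SD
    std_uniquenesses: np.ndarray  # (K, J), in (0, 1]


@dataclass
class Step1Fit:
    model: MeasurementModel
    rotated: RotatedView
    posterior: np.ndarray  # (N, K)
    loglik: float
    n_par: int
    bic: float
    converged: bool
    n_starts: int
    best_start: int
    n_iterations: int
    ll_trace: np.ndarray  # best start's LL per outer iteration
    max_ll_decrease: float  # largest observed LL drop across all starts (>=0)
    psi_floor_hit: bool = False
    indicator_cols: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
def ledermann_bound(J: int) -> int:
    """Largest number of factors identifiable from a J x J covariance."""
    return int(np.floor((2 * J + 1 - np.sqrt(8 * J + 1)) / 2))


def count_parameters(K: int, J: int, n_fact: list[int]) -> int:
    """Free parameters: mixing + identified loadings + intercepts + uniquenesses."""
    if len(n_fact) != K:
        raise ValueError("n_fact must have one entry per state")
    total = K - 1
    for F in n_fact:
        total += J * F - F * (F - 1) // 2 + J + J
    return total


def _state_logpdf(y: np.ndarray, nu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Gaussian log density of every row of y under one state."""
    J = y.shape[1]
    try:
        L = cholesky(Sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "model-implied covariance is not positive definite"
        ) from exc
    x = solve_triangular(L, (y - nu).T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (J * np.log(2 * np.pi) + logdet + np.sum(x**2, axis=0))


def loglik_step1(data: ILDataset | np.ndarray, model: MeasurementModel) -> float:
    """Mixture loglikelihood  sum_it log sum_k pi_k N(y_it; nu_k, Sigma_k).

    Invariant under rotation of any state's loadings, since only
    Lambda_k Lambda_k' enters the density.
    """
    y = data.indicators if isinstance(data, ILDataset) else np.asarray(data, float)
    logp = _mixture_logmatrix(y, model)
    return float(np.sum(logsumexp(logp, axis=1)))


def _mixture_logmatrix(y: np.ndarray, model: MeasurementModel) -> np.ndarray:
    """(N, K) matrix of log pi_k + log N(y; nu_k, Sigma_k)."""
    K = model.n_states
    out = np.empty((y.shape[0], K))
    for k in range(K):
        out[:, k] = np.log(model.mixing[k]) + _state_logpdf(
            y, model.intercepts[k], model.implied_cov(k)
        )
    return out


# ----------------------------------------------------------------------
def _fa_inner_em(
    S: np.ndarray,
    Lam: np.ndarray,
    psi: np.ndarray,
    psi_floor: np.ndarray,
    n_iter: int = INNER_FA_ITERATIONS,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EM for a single factor-analysis model on a weighted covariance S.

    Maximizes (improves) the Gaussian likelihood with covariance
    Lambda Lambda' + diag(psi) given sufficient statistic S.
    """
    F = Lam.shape[1]
    floored = False
    I = np.eye(F)
    for _ in range(n_iter):
        Sigma = Lam @ Lam.T + np.diag(psi)
        c = cho_factor(Sigma, lower=True)
        B = cho_solve(c, Lam).T  # F x J: Lambda' Sigma^{-1}
        BS = B @ S
        M = I - B @ Lam + BS @ B.T  # E[eta eta']
        Lam = np.linalg.solve(M.T, BS).T  # S B' M^{-1}
        psi = np.diag(S - Lam @ BS)
        if np.any(psi < psi_floor):
            psi = np.maximum(psi, psi_floor)
            floored = True
    return Lam, np.asarray(psi, float).copy(), floored


def _init_fa(S: np.ndarray, F: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component start for the inner factor-analysis EM."""
    d, V = np.linalg.eigh(S)
    d = d[::-1]
    V = V[:, ::-1]
    psi0 = np.maximum(0.5 * np.diag(S), 1e-6)
    load = V[:, :F] * np.sqrt(np.maximum(d[:F] - np.mean(psi0), 1e-6))
    return load, psi0


class _StartFailed(Exception):
    pass


def _em_one_start(
    y: np.ndarray,
    K: int,
    n_fact: list[int],
    rng: np.random.Generator,
    max_iterations: int,
    tolerance: float,
):
    """Run EM from one random start.  Returns (model, posterior, trace, conv, floored)."""
    N, J = y.shape
    psi_floor = PSI_FLOOR_FRACTION * np.maximum(np.var(y, axis=0), 1e-12)

    # random initial posteriors: flat Dirichlet per observation
    W = rng.dirichlet(np.ones(K), size=N)

    loadings: list[np.ndarray | None] = [None] * K
    psis: list[np.ndarray | None] = [None] * K
    nus = np.empty((K, J))
    mixing = np.empty(K)
    floored_any = False

    trace = []
    prev_ll = -np.inf
    converged = False
    for it in range(max_iterations):
        # ---- M-step on current posteriors
        tot = W.sum(axis=0)
        if np.any(tot < 1.0):  # pi_k < 1/N: state collapsed
            raise _StartFailed("empty state")
        mixing = tot / N
        for k in range(K):
            w = W[:, k]
            nu = (w @ y) / tot[k]
            yc = y - nu
            S = (yc.T * w) @ yc / tot[k]
            if loadings[k] is None:
                loadings[k], psis[k] = _init_fa(S, n_fact[k])
            loadings[k], psis[k], fl = _fa_inner_em(
                S, loadings[k], psis[k], psi_floor
            )
            floored_any = floored_any or fl
            nus[k] = nu
        model = MeasurementModel(
            [l.copy() for l in loadings], nus.copy(),
            np.vstack([p for p in psis]), mixing.copy(),
        )
        # ---- E-step
        logp = _mixture_logmatrix(y, model)
        lse = logsumexp(logp, axis=1)
        W = np.exp(logp - lse[:, None])
        ll = float(np.sum(lse))
        trace.append(ll)
        if abs(ll - prev_ll) < tolerance:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return model, W, np.array(trace), converged, floored_any


def _canonicalize(Lam: np.ndarray) -> np.ndarray:
    """Fix rotational freedom of an identified loading matrix via SVD.

    Returns Lambda with Lambda'Lambda diagonal (descending) and column signs
    fixed, preserving Lambda Lambda'.
    """
    U, s, _ = np.linalg.svd(Lam, full_matrices=False)
    out = U * s
    for q in range(out.shape[1]):
        j = int(np.argmax(np.abs(out[:, q])))
        if out[j, q] < 0:
            out[:, q] = -out[:, q]
    return out


def _relabel_by_size(model, W):
    """Reorder states by descending modal-assignment count (ties: posterior mass)."""
    modal = np.argmax(W, axis=1)
    counts = np.bincount(modal, minlength=model.n_states)
    mass = W.sum(axis=0)
    order = np.lexsort((-mass, -counts))
    model = MeasurementModel(
        [model.loadings[k] for k in order],
        model.intercepts[order],
        model.uniquenesses[order],
        model.mixing[order],
    )
    return model, W[:, order]


def fit_step1(
    data: ILDataset,
    n_states: int,
    n_fact: list[int] | int,
    n_starts: int = 25,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    tolerance: float = DEFAULT_TOLERANCE,
    seed: int | None = None,
    n_rotation_starts: int = 10,
) -> Step1Fit:
    """Fit the K-state mixture factor model by multistart EM.

    The start with the highest converged loglikelihood wins; if no start
    converges the best loglikelihood is returned with ``converged=False``.
    States are relabelled by descending size.
    """
    y = data.indicators
    N, J = y.shape
    if isinstance(n_fact, int):
        n_fact = [n_fact] * n_states
    n_fact = list(n_fact)
    if len(n_fact) != n_states:
        raise ValueError("n_fact must have length n_states")
    bound = ledermann_bound(J)
    for F in n_fact:
        if F < 1:
            raise ValueError("each state needs at least one factor")
        if F > bound:
            raise ValueError(
                f"{F} factors with {J} indicators exceeds the identifiability "
                f"(Ledermann) bound of {bound}"
            )
    n_par = count_parameters(n_states, J, n_fact)
    if N < n_par:
        raise ValueError(
            f"{N} observations cannot identify {n_par} parameters"
        )

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_starts + 1)
    best = None
    max_decrease = 0.0
    for s in range(n_starts):
        rng = np.random.default_rng(child_seeds[s])
        try:
            model, W, trace, conv, floored = _em_one_start(
                y, n_states, n_fact, rng, max_iterations, tolerance
            )
        except (_StartFailed, np.linalg.LinAlgError):
            continue
        if len(trace) > 1:
            max_decrease = max(max_decrease, float(np.max(-np.diff(trace))))
        ll = trace[-1]
        key = (conv, ll)
        if best is None or key > (best[3], best[2]):
            best = (model, W, ll, conv, trace, s, floored)
    if best is None:
        raise RuntimeError(
            "every EM start failed (collapsed state or singular covariance); "
            "try more starts or fewer states/factors"
        )
    model, W, ll, conv, trace, best_start, floored = best
    if not conv:
        logger.warning(
            "model [%s] did not converge within %d iterations; consider "
            "re-estimating with more iterations",
            " ".join(map(str, n_fact)), max_iterations,
        )
    model, W = _relabel_by_size(model, W)
    model.loadings = [_canonicalize(L) for L in model.loadings]

    rot_rng = np.random.default_rng(child_seeds[-1])
    rotated = rotate_oblique(model, n_starts=n_rotation_starts, rng=rot_rng)
    bic = -2.0 * ll + n_par * np.log(N)
    return Step1Fit(
        model=model,
        rotated=rotated,
        posterior=W,
        loglik=float(ll),
        n_par=n_par,
        bic=float(bic),
        converged=bool(conv),
        n_starts=n_starts,
        best_start=best_start,
        n_iterations=len(trace),
        ll_trace=np.asarray(trace),
        max_ll_decrease=max_decrease,
        psi_floor_hit=floored,
        indicator_cols=list(data.indicator_cols),
    )


# ----------------------------------------------------------------------
def enumerate_models(
    state_range: list[int], factor_range: list[int]
) -> list[tuple[int, ...]]:
    """All distinct factor-count multisets, one per permutation class.

    E.g. states 1-2 x factors 1-2 gives [1], [2], [1 1], [2 1], [2 2].
    """
    state_range = list(state_range)
    factor_range = sorted(set(factor_range))
    if not state_range or not factor_range:
        raise ValueError("state and factor ranges must be nonempty")
    out = []
    for K in state_range:
        for combo in itertools.combinations_with_replacement(
            sorted(factor_range, reverse=True), K
        ):
            out.append(combo)
    return out


def _label(n_fact) -> str:
    return "[" + " ".join(str(f) for f in n_fact) + "]"


@dataclass
class ModelSelectionTable:
    table: pd.DataFrame  # index: label; columns LL, BIC, convergence, n_par
    fits: dict[str, Step1Fit]
    n_observations: int

    def best_bic(self) -> str:
        return str(self.table.index[0])

    def get(self, label: str) -> Step1Fit:
        return self.fits[label]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.table.to_string(float_format=lambda v: f"{v:.2f}")
        if (self.table["convergence"] == 0).any():
            s += (
                "\n\nNote: some models did not converge; consider re-estimating"
                " them with more iterations before selecting a model."
            )
        return s


def model_selection(
    data: ILDataset,
    n_states: list[int],
    n_fact: list[int],
    n_starts: int = 25,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    tolerance: float = DEFAULT_TOLERANCE,
    seed: int | None = None,
) -> ModelSelectionTable:
    """Fit every candidate factor-count multiset and tabulate fit vs parsimony.

    Rows are sorted ascending by BIC.  Each fit relabels its states by
    descending size, so the bracket label reads largest state first.
    """
    candidates = enumerate_models(n_states, n_fact)
    N = data.n_rows
    if N < 1000 * max(n_states):
        logger.warning(
            "only %d observations for up to %d states; at least 1000 "
            "observations per state are recommended", N, max(n_states),
        )
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(candidates))
    rows = []
    fits: dict[str, Step1Fit] = {}
    for cand, s in zip(candidates, seeds):
        fit = fit_step1(
            data, len(cand), list(cand), n_starts=n_starts,
            max_iterations=max_iterations, tolerance=tolerance,
            seed=int(s.generate_state(1)[0] % (2**31)),
        )
        lab = _label(fit.model.n_factors)
        fits[lab] = fit
        rows.append((lab, fit.loglik, fit.bic, int(fit.converged), fit.n_par))
    tab = pd.DataFrame(
        rows, columns=["model", "LL", "BIC", "convergence", "n_par"]
    ).set_index("model")
    tab = tab.sort_values("BIC")
    if (tab["convergence"] == 0).any():
        logger.warning(
            "models %s did not converge; consider re-estimating with more "
            "iterations", list(tab.index[tab["convergence"] == 0]),
        )
    return ModelSelectionTable(tab, fits, N)


# ----------------------------------------------------------------------
@dataclass
class CHullResult:
    hull: pd.DataFrame  # hull models with n_par, LL, st (NaN at boundaries)
    selected: str
    inflation_flag: bool
    note: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.hull.to_string(float_format=lambda v: f"{v:.3f}")
        s += f"\n\nSelected model: {self.selected}\n{self.note}"
        if self.inflation_flag:
            s += (
                "\nWarning: the winning scree ratio shows signs of artificial"
                " inflation (near-flat hull); inspect the CHull plot and"
                " consider the next-best model(s)."
            )
        return s


CHULL_INFLATION_FRACTION = 1e-3


def chull_select(table: ModelSelectionTable) -> CHullResult:
    """Convex-hull scree selection on the (n_par, LL) plot.

    Keeps converged models, finds the upper convex hull, computes the scree
    ratio st_i = slope(i-1, i) / slope(i, i+1) for interior hull models, and
    selects the model with the largest ratio.  Boundary hull models get no
    ratio.  A near-flat incoming slope at the winner flags possible
    artificial inflation of the ratio.
    """
    tab = table.table[table.table["convergence"] == 1]
    if len(tab) < 3:
        raise ValueError("CHull undefined: fewer than 3 converged models")
    pts = tab[["n_par", "LL"]].reset_index()
    # per parameter count keep only the best-fitting model
    pts = pts.loc[pts.groupby("n_par")["LL"].idxmax()]
    pts = pts.sort_values("n_par").reset_index(drop=True)
    p_all = pts["n_par"].to_numpy(float)
    ll_all = pts["LL"].to_numpy(float)
    # upper convex hull by monotone chain
    hull_idx: list[int] = []
    for i in range(len(pts)):
        while len(hull_idx) >= 2:
            a, b = hull_idx[-2], hull_idx[-1]
            # drop the middle point only if strictly below the chord, so
            # collinear models stay on the hull (flat hull, no elbow)
            if (ll_all[b] - ll_all[a]) * (p_all[i] - p_all[b]) < (
                ll_all[i] - ll_all[b]
            ) * (p_all[b] - p_all[a]):
                hull_idx.pop()
            else:
                break
        hull_idx.append(i)
    hull = pts.loc[hull_idx].reset_index(drop=True)
    if len(hull) < 3:
        raise ValueError("CHull undefined: fewer than 3 models on the hull")
    p = hull["n_par"].to_numpy(float)
    ll = hull["LL"].to_numpy(float)
    st = np.full(len(hull), np.nan)
    for i in range(1, len(hull) - 1):
        num = (ll[i] - ll[i - 1]) / (p[i] - p[i - 1])
        den = (ll[i + 1] - ll[i]) / (p[i + 1] - p[i])
        st[i] = num / den if den > 0 else np.inf
    hull["st"] = st
    winner = int(np.nanargmax(st))
    mean_slope = (ll[-1] - ll[0]) / (p[-1] - p[0])
    incoming = (ll[winner] - ll[winner - 1]) / (p[winner] - p[winner - 1])
    inflation = (
        bool(incoming < CHULL_INFLATION_FRACTION * abs(mean_slope))
        if mean_slope != 0
        else True
    )
    # a winning ratio of ~1 means the hull has no elbow at all
    if st[winner] <= 1.0 + 1e-9:
        inflation = True
    note = (
        "Note: the least and most complex hull models cannot be selected by "
        "scree ratio; always inspect the CHull plot as well."
    )
    return CHullResult(
        hull=hull.set_index("model"),
        selected=str(hull["model"].iloc[winner]),
        inflation_flag=inflation,
        note=note,
    )


# ----------------------------------------------------------------------
def rotate_oblique(
    model: MeasurementModel,
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
) -> RotatedView:
    """Quartimin-rotate each state's loadings and standardize the result."""
    rng = np.random.default_rng(rng)
    pattern, phi = [], []
    for k in range(model.n_states):
        L, P = rotate_pattern(model.loadings[k], n_starts=n_starts, rng=rng)
        pattern.append(L)
        phi.append(P)
    std_pat, std_uni = standardize_loadings(pattern, model)
    return RotatedView(pattern, phi, std_pat, std_uni)


def standardize_loadings(
    pattern: list[np.ndarray], model: MeasurementModel
) -> tuple[list[np.ndarray], np.ndarray]:
    """Scale loadings by model-implied item SDs; uniquenesses to proportions."""
    std_pat = []
    std_uni = np.empty_like(model.uniquenesses)
    for k in range(model.n_states):
        sd = np.sqrt(np.diag(model.implied_cov(k)))
        std_pat.append(pattern[k] / sd[:, None])
        std_uni[k] = model.uniquenesses[k] / sd**2
    return std_pat, std_uni


def factor_scores(data: ILDataset, fit: Step1Fit) -> pd.DataFrame:
    """Regression-method factor scores on the rotated solution, per state.

    E[eta | y, state k] = Phi_k pattern_k' Sigma_k^{-1} (y - nu_k), computed
    for every observation under every state and appended as columns
    "S{k}F{f}" to a copy of the data.
    """
    y = data.indicators
    model = fit.model
    cols = {}
    for k in range(model.n_states):
        Sigma = model.implied_cov(k)
        A = fit.rotated.phi[k] @ fit.rotated.pattern[k].T @ np.linalg.inv(Sigma)
        scores = (y - model.intercepts[k]) @ A.T
        for f in range(scores.shape[1]):
            cols[f"S{k + 1}F{f + 1}"] = scores[:, f]
    return data.with_columns(pd.DataFrame(cols))


# ----------------------------------------------------------------------
def summary_step1(fit: Step1Fit, threshold: float = 0.3) -> str:
    """Printable report: fit statistics, intercepts, standardized rotated
    loadings (|loading| >= threshold marked), factor correlations,
    standardized unique variances."""
    model = fit.model
    items = fit.indicator_cols or [f"y{j + 1}" for j in range(model.n_indicators)]
    lines = [
        f"LL = {fit.loglik:.2f}   BIC = {fit.bic:.2f}   "
        f"convergence = {int(fit.converged)}   n_par = {fit.n_par}",
        "",
        "Intercepts",
    ]
    ic = pd.DataFrame(
        fit.model.intercepts.T, index=items,
        columns=[f"S{k + 1}" for k in range(model.n_states)],
    )
    lines.append(ic.to_string(float_format=lambda v: f"{v:.2f}"))
    lines += ["", f"Standardized oblique loadings (* marks |loading| >= {threshold})"]
    for k in range(model.n_states):
        pat = fit.rotated.std_pattern[k]
        body = pd.DataFrame(
            pat, index=items,
            columns=[f"S{k + 1}F{f + 1}" for f in range(pat.shape[1])],
        )
        txt = body.to_string(
            float_format=lambda v: f"{v:+.2f}*" if abs(v) >= threshold else f"{v:+.2f} "
        )
        lines.append(txt)
        if pat.shape[1] > 1:
            lines.append(f"Factor correlations S{k + 1}")
            lines.append(
                pd.DataFrame(fit.rotated.phi[k]).to_string(
                    float_format=lambda v: f"{v:.2f}"
                )
            )
        lines.append("")
    lines.append("Standardized unique variances")
    uv = pd.DataFrame(
        fit.rotated.std_uniquenesses.T, index=items,
        columns=[f"S{k + 1}" for k in range(model.n_states)],
    )
    lines.append(uv.to_string(float_format=lambda v: f"{v:.2f}"))
    return "\n".join(lines)


def plot_bic(table: ModelSelectionTable, ax=None):
    """BIC against number of parameters, lowest-BIC model highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = table.table[table.table["convergence"] == 1]
    ax.scatter(tab["n_par"], tab["BIC"], color="k")
    best = tab["BIC"].idxmin()
    ax.scatter([tab.loc[best, "n_par"]], [tab.loc[best, "BIC"]], color="red", zorder=3)
    for lab, row in tab.iterrows():
        ax.annotate(lab, (row["n_par"], row["BIC"]), fontsize=7)
    ax.set_xlabel("number of parameters")
    ax.set_ylabel("BIC")
    return ax


def plot_chull(result: CHullResult, ax=None):
    """Loglikelihood against number of parameters along the upper hull."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.hull["n_par"], result.hull["LL"], "o-", color="k")
    for lab, row in result.hull.iterrows():
        ax.annotate(str(lab), (row["n_par"], row["LL"]), fontsize=7)
    ax.set_xlabel("number of parameters")
    ax.set_ylabel("loglikelihood")
    return ax
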