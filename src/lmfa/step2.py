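"""Step 2: modal state assignment and classification-error quantification.

Each observation is assigned to its highest-posterior state.  Because the
assignment is imperfect whenever posteriors are not degenerate, step 3
treats the modal assignment as a misclassified single indicator of the true
state; the misclassification probabilities estimated here — P(modal = s |
true = t), with the "true" state operationalized as posterior mass, the
standard ML three-step convention — are fixed as the emission model there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ILDataset
from .step1 import Step1Fit

logger = logging.getLogger("lmfa")

__all__ = ["Classification", "classify", "attach_assignments", "summary_step2"]

R2_ENTROPY_WARN = 0.5


@dataclass
class Classification:
    posterior: np.ndarray  # (N, K), rows on the simplex
    modal: np.ndarray  # (N,), values in 1..K
    error_counts: np.ndarray  # (K, K): D[s, t] = sum_i 1[modal=s] W[i, t]
    error_probs: np.ndarray  # (K, K): P(modal = s | true = t), columns sum to 1
    r2_entropy: float | None  # None when K == 1
    total_error: float
    proportions: np.ndarray  # modal state shares

    @property
    def n_states(self) -> int:
        return self.posterior.shape[1]


def classify(data: ILDataset, fit: Step1Fit) -> Classification:
    """Cross-classify modal assignments against posterior ("true") mass.

    total_error = 1 - mean(max posterior); R2_entropy = 1 minus the average
    posterior entropy normalized by ln K (natural log; the base cancels).
    """
    W = fit.posterior
    if len(W) != data.n_rows:
        raise ValueError("fit posteriors do not match the dataset")
    return classify_posteriors(W)


def classify_posteriors(W: np.ndarray) -> Classification:
    """Classification statistics from a posterior matrix alone."""
    W = np.asarray(W, dtype=float)
    N, K = W.shape
    modal0 = np.argmax(W, axis=1)  # argmax takes the lowest index on ties
    D = np.zeros((K, K))
    for s in range(K):
        D[s] = W[modal0 == s].sum(axis=0)
    col = D.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        error_probs = np.where(col > 0, D / col, np.where(np.eye(K) == 1, 1.0, 0.0))
    total_error = float(1.0 - np.mean(np.max(W, axis=1)))
    if K == 1:
        r2 = None
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(W > 0, W * np.log(W), 0.0).sum()
        r2 = float(1.0 - ent / (N * np.log(K)))
        if r2 < R2_ENTROPY_WARN:
            logger.warning(
                "R2_entropy = %.3f < %.1f: poor state separation can make the "
                "classification-error correction unreliable; consider "
                "full-information estimation instead", r2, R2_ENTROPY_WARN,
            )
    proportions = np.bincount(modal0, minlength=K) / N
    return Classification(
        posterior=W,
        modal=modal0 + 1,
        error_counts=D,
        error_probs=error_probs,
        r2_entropy=r2,
        total_error=total_error,
        proportions=proportions,
    )


def attach_assignments(data: ILDataset, classification: Classification) -> pd.DataFrame:
    """Copy of the data with posterior columns "State1".."StateK" and "Modal"."""
    K = classification.n_states
    cols = {f"State{k + 1}": classification.posterior[:, k] for k in range(K)}
    cols["Modal"] = classification.modal
    return data.with_columns(pd.DataFrame(cols))


def summary_step2(classification: Classification) -> str:
    K = classification.n_states
    states = [f"S{k + 1}" for k in range(K)]
    r2 = (
        "not applicable (single state)"
        if classification.r2_entropy is None
        else f"{classification.r2_entropy:.4f}"
    )
    parts = [
        f"R2_entropy: {r2}",
        f"Total classification error: {classification.total_error:.4f}",
        "",
        "Classification errors (rows: modal, columns: true)",
        pd.DataFrame(classification.error_counts, index=states, columns=states)
        .to_string(float_format=lambda v: f"{v:.2f}"),
        "",
        "Classification-error probabilities P(modal | true)",
        pd.DataFrame(classification.error_probs, index=states, columns=states)
        .to_string(float_format=lambda v: f"{v:.4f}"),
        "",
        "State proportions",
        pd.Series(classification.proportions, index=states)
        .to_string(float_format=lambda v: f"{v:.4f}"),
    ]
    return "\n".join(parts)
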