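"""Matched classified mixed model prediction (CMMP) for test observations.

Each test observation is treated as its own group of size one.  For every
outcome m, the observation is classified to the training cluster whose
BLUP is nearest (in squared distance) to its fixed-effect residual

    I_hat = argmin_j (y_nm - x_n' beta_hat_m - alpha_hat_jm)^2,

and the mixed effect is predicted as theta_hat = x_n' beta_hat_m +
alpha_hat_{I_hat, m}.  The per-sample consensus cluster (the modal
assignment across outcomes) is reported for diagnostics only; it is never
fed back into prediction.  Comparator modes: the naive estimate (the
observed y itself), regression prediction (OLS on the same design), and
oracle CMMP (mixed-model fits trained on the true cluster labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mixed_model import OutcomeFit, ols_fit

__all__ = [
    "PredictionSet",
    "classify_observation",
    "predict_theta",
    "predict_all",
    "consensus_cluster",
    "cmmp_predict_matrix",
]

METHODS = ("naive", "regression", "cmmp", "oracle")


@dataclass
class PredictionSet:
    """Predictions for the test set under one method."""

    method: str
    theta_hat: np.ndarray            # n_test x M
    assigned: np.ndarray | None      # n_test x M cluster labels (cmmp/oracle)
    consensus: np.ndarray | None     # n_test modal labels

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def classify_observation(y_nm: float, x_n: np.ndarray, fit: OutcomeFit) -> int:
    """Cluster label (1-based) minimizing the squared residual distance
    to the cluster BLUPs; ties take the lowest label."""
    if np.isnan(y_nm):
        raise ValueError("matched CMMP requires the observed outcome y_nm")
    resid = y_nm - float(np.asarray(x_n) @ fit.beta_hat)
    return int(np.argmin((resid - fit.alpha_hat) ** 2)) + 1


def predict_theta(x_n: np.ndarray, fit: OutcomeFit, assigned: int) -> float:
    """theta_hat = x_n' beta_hat + alpha_hat of the assigned cluster."""
    if not 1 <= assigned <= fit.alpha_hat.size:
        raise ValueError(f"assigned cluster {assigned} outside 1..{fit.alpha_hat.size}")
    return float(np.asarray(x_n) @ fit.beta_hat + fit.alpha_hat[assigned - 1])


def cmmp_predict_matrix(Y_test, X_test, fits) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized matched CMMP over all test samples and outcomes.

    Returns (theta_hat n_test x M, assigned n_test x M).
    """
    Y_test = np.asarray(Y_test, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if np.isnan(Y_test).any():
        raise ValueError("matched CMMP requires observed test outcomes")
    n_t, m = Y_test.shape
    theta = np.empty((n_t, m))
    assigned = np.empty((n_t, m), dtype=int)
    for j, fit in enumerate(fits):
        xb = X_test @ fit.beta_hat
        resid = Y_test[:, j] - xb
        idx = np.argmin((resid[:, None] - fit.alpha_hat[None, :]) ** 2, axis=1)
        assigned[:, j] = idx + 1
        theta[:, j] = xb + fit.alpha_hat[idx]
    return theta, assigned


def consensus_cluster(per_outcome_labels: np.ndarray) -> int:
    """Modal label across outcomes; ties take the lowest label."""
    labels = np.asarray(per_outcome_labels, dtype=int).ravel()
    if labels.size == 0:
        raise ValueError("need at least one per-outcome label")
    counts = np.bincount(labels)
    return int(np.argmax(counts))


def predict_all(
    test_outcomes,
    test_design,
    fits=None,
    mode: str = "cmmp",
    train_outcomes=None,
    train_design=None,
    ols_betas=None,
) -> PredictionSet:
    """Full test x outcome prediction table under one method.

    ``cmmp`` and ``oracle`` expect per-outcome mixed-model fits (trained
    on k-means labels and true labels respectively); ``regression`` uses
    OLS coefficients on the same design (supplied directly or fitted from
    the training data); ``naive`` returns the observed test outcomes.
    """
    Y = np.asarray(test_outcomes, dtype=float)
    if mode == "naive":
        return PredictionSet(method=mode, theta_hat=Y.copy(), assigned=None, consensus=None)
    X = np.asarray(test_design, dtype=float)
    if mode == "regression":
        if ols_betas is None:
            if train_outcomes is None or train_design is None:
                raise ValueError("regression mode needs OLS coefficients or training data")
            ols_betas, _ = ols_fit(train_outcomes, train_design)
        return PredictionSet(
            method=mode, theta_hat=X @ ols_betas, assigned=None, consensus=None
        )
    if mode in ("cmmp", "oracle"):
        if fits is None:
            raise ValueError(f"{mode} mode requires per-outcome mixed-model fits")
        theta, assigned = cmmp_predict_matrix(Y, X, fits)
        consensus = np.array([consensus_cluster(row) for row in assigned])
        return PredictionSet(method=mode, theta_hat=theta, assigned=assigned, consensus=consensus)
    raise ValueError(f"unknown mode {mode!r}")
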