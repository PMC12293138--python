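"""Common spatial patterns (CSP) feature extraction.

CSP finds spatial filters that maximize the variance of one class while
minimizing the other's. For each trial D (channels x samples) the normalized
spatial covariance is M = D D^T / trace(D D^T); class-average covariances
M1, M2 are combined into Mc = M1 + M2, whitened by W = lambda_c^(-1/2) Ec^T
(so W Mc W^T = I), and the whitened class covariances K1 = W M1 W^T and
K2 = W M2 W^T share eigenvectors U with eigenvalue pairs summing to one
(lambda1 + lambda2 = I). The projection P = U^T W maps a trial to component
series Z = P D whose first rows carry maximal class-1 variance and last rows
maximal class-2 variance; the sample variances of those rows are the
classification features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import CLASSES, EpochSet, Trial

logger = logging.getLogger(__name__)


class DegenerateTrialError(ValueError):
    """A trial carries no signal power, so its covariance is undefined."""


def normalized_covariance(trial: Trial | np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance M = D D^T / trace(D D^T)."""
    D = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if D.ndim != 2 or D.shape[1] < 2:
        raise ValueError("trial must be channels x samples with >= 2 samples")
    C = D @ D.T
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateTrialError("all-zero trial has no spatial covariance")
    return C / tr


@dataclass
class CSPModel:
    """Fitted whitening and projection matrices with eigenvalue spectra."""

    Ec: np.ndarray  # eigenvectors of the composite covariance
    lambda_c: np.ndarray  # its eigenvalues
    W: np.ndarray  # whitening transform
    K1: np.ndarray  # whitened class-1 covariance
    K2: np.ndarray
    U: np.ndarray  # shared eigenvectors of K1 and K2
    lambda1: np.ndarray  # paired eigenvalues (descending), lambda1 + lambda2 = 1
    lambda2: np.ndarray
    P: np.ndarray  # projection matrix, rows ordered by descending lambda1
    n_pairs: int
    classes: tuple[str, str] = CLASSES
    M1_bar: np.ndarray | None = None
    M2_bar: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.P.shape[1]


def _class_mean_covariances(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    covs: dict[str, list[np.ndarray]] = {c: [] for c in CLASSES}
    for t in epochs.trials:
        if t.label in covs:
            covs[t.label].append(normalized_covariance(t))
    if not covs[CLASSES[0]] or not covs[CLASSES[1]]:
        raise ValueError("both classes must be present in the training set")
    return (np.mean(covs[CLASSES[0]], axis=0), np.mean(covs[CLASSES[1]], axis=0))


def _csp_decomposition(M1: np.ndarray, M2: np.ndarray):
    """Whitening + shared eigendecomposition from two class covariances."""
    n_ch = M1.shape[0]
    Mc = M1 + M2
    lam_c, Ec = np.linalg.eigh(Mc)
    if lam_c[-1] <= 0:
        raise np.linalg.LinAlgError("composite covariance is not positive")
    if lam_c[0] < 1e-10 * lam_c[-1]:
        ridge = 1e-10 * np.trace(Mc)
        logger.warning("rank-deficient composite covariance; adding ridge %.3e", ridge)
        lam_c, Ec = np.linalg.eigh(Mc + ridge * np.eye(n_ch))
    if lam_c[0] <= 0:
        raise np.linalg.LinAlgError(
            "composite covariance is rank-deficient; regularize or add trials")
    W = (lam_c ** -0.5)[:, None] * Ec.T
    K1 = W @ M1 @ W.T
    K2 = W @ M2 @ W.T
    mu, U = np.linalg.eigh(K1)
    order = np.argsort(mu)[::-1]  # descending class-1 eigenvalue
    mu = mu[order]
    U = U[:, order]
    P = U.T @ W
    # deterministic sign: largest-magnitude entry of each row positive
    flip = np.sign(P[np.arange(n_ch), np.argmax(np.abs(P), axis=1)])
    flip[flip == 0] = 1.0
    P = flip[:, None] * P
    U = U * flip[None, :]
    return Ec, lam_c, W, K1, K2, U, mu, P


def csp_projection_from_covariances(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    """The full projection matrix P from two class-average covariances."""
    return _csp_decomposition(M1, M2)[-1]


def fit_csp(train: EpochSet, n_pairs: int = 3) -> CSPModel:
    """Fit CSP on the training split of a two-class epoch set.

    Class 1 is right-hand, class 2 right-foot. Eigenvalues of the whitened
    class-1 covariance are sorted descending, so the first rows of P maximize
    class-1 variance and the last rows class-2 variance. Each row's sign is
    fixed by making its largest-magnitude entry positive (features are
    sign-invariant; the convention just makes fits reproducible).
    """
    M1, M2 = _class_mean_covariances(train)
    if M1.shape[0] < 2 * n_pairs:
        raise ValueError(f"{M1.shape[0]} channels cannot provide {n_pairs} filter pairs")
    Ec, lam_c, W, K1, K2, U, mu, P = _csp_decomposition(M1, M2)
    return CSPModel(Ec=Ec, lambda_c=lam_c, W=W, K1=K1, K2=K2, U=U,
                    lambda1=mu, lambda2=1.0 - mu, P=P, n_pairs=n_pairs,
                    M1_bar=M1, M2_bar=M2)


def apply_csp(model: CSPModel, trial: Trial | np.ndarray) -> np.ndarray:
    """Component series Z = P D for one trial."""
    D = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if D.shape[0] != model.n_channels:
        raise ValueError(f"trial has {D.shape[0]} channels, projection expects {model.n_channels}")
    return model.P @ D


def variance_features(Z: np.ndarray, n_pairs: int) -> np.ndarray:
    """Sample variances (denominator L-1) of the first and last n_pairs rows.

    Returned in row order: rows 0..n_pairs-1 then rows -n_pairs..-1. With six
    input signals and three pairs every component is used exactly once.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("Z must be components x samples with >= 2 samples")
    if Z.shape[0] < 2 * n_pairs:
        raise ValueError(f"{Z.shape[0]} rows cannot supply {n_pairs} variance pairs")
    rows = np.concatenate([Z[:n_pairs], Z[-n_pairs:]])
    return rows.var(axis=1, ddof=1)


def features_for_epochs(model: CSPModel, epochs: EpochSet) -> tuple[np.ndarray, list[str]]:
    """Feature matrix (n_trials x 2*n_pairs) and labels for an epoch set."""
    X = np.stack([variance_features(apply_csp(model, t), model.n_pairs)
                  for t in epochs.trials])
    return X, epochs.labels
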