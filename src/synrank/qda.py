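"""Quadratic discriminant analysis and the two evaluation metrics.

QDA keeps class-specific covariance matrices, so pairwise feature
interactions influence the decision boundary. Class covariances are shrunk
toward a scaled identity so that fits on small cross-validation folds never
fail on singular covariance estimates. The implementation is deliberately
lean: it sits in the innermost loop of forward selection, where it is called
hundreds of thousands of times per evaluation run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, InsufficientClassError, UndefinedMetricError

__all__ = [
    "QdaModel",
    "fit_qda",
    "posterior",
    "predict",
    "qda_fold_posterior",
    "accuracy",
    "auc_score",
]

DEFAULT_SHRINKAGE = 1e-4
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class QdaModel:
    priors: np.ndarray        # (2,) class priors, sum to 1
    means: np.ndarray         # (2, d)
    inv_covs: np.ndarray      # (2, d, d) inverses of regularized class covariances
    log_dets: np.ndarray      # (2,) log-determinants (via Cholesky)
    n_features: int
    feature_subset: tuple[int, ...] | None = None


def _qda_stats(X: np.ndarray, y: np.ndarray, shrinkage: float):
    """Class priors, means, inverse covariances and log-determinants.

    Each class covariance S is replaced by
    ``(1 - shrinkage) * S + shrinkage * (trace(S)/d) * I`` (plus a tiny
    absolute diagonal floor), after which its Cholesky factorization is
    required to succeed. Shared by :func:`fit_qda` and the fast fold scorer.
    """
    n, d = X.shape
    means = np.empty((2, d))
    priors = np.empty(2)
    covs = np.empty((2, d, d))
    diag = np.arange(d)
    for c in (0, 1):
        Xc = X[y == c]
        nc = Xc.shape[0]
        if nc < 2:
            raise InsufficientClassError(f"class {c} has {nc} samples; need at least 2")
        priors[c] = nc / n
        mu = Xc.mean(axis=0)
        means[c] = mu
        Z = Xc - mu
        cov = (Z.T @ Z) / (nc - 1)
        tr = np.trace(cov)
        cov *= 1.0 - shrinkage
        cov[diag, diag] += shrinkage * tr / d + 1e-10
        covs[c] = cov
    L = np.linalg.cholesky(covs)
    log_dets = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    inv_covs = np.linalg.inv(covs)
    return priors, means, inv_covs, log_dets


def fit_qda(
    train_features: np.ndarray,
    train_outcome: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    feature_subset: tuple[int, ...] | None = None,
) -> QdaModel:
    """Fit class priors, means and (regularized) class covariances."""
    X = np.asarray(train_features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InputError("train_features must be 2-D")
    y = np.asarray(train_outcome)
    n, d = X.shape
    if y.shape != (n,):
        raise InputError("outcome length mismatch")
    priors, means, inv_covs, log_dets = _qda_stats(X, y, shrinkage)
    return QdaModel(
        priors=priors,
        means=means,
        inv_covs=inv_covs,
        log_dets=log_dets,
        n_features=d,
        feature_subset=feature_subset,
    )


def _posterior_from_stats(priors, means, inv_covs, log_dets, X: np.ndarray) -> np.ndarray:
    diff = X[None, :, :] - means[:, None, :]           # (2, n, d)
    maha = np.einsum("cnd,cde,cne->cn", diff, inv_covs, diff)
    ll = -0.5 * (maha + log_dets[:, None]) + np.log(priors)[:, None]
    m = ll.max(axis=0)
    w = np.exp(ll - m)
    return w[1] / (w[0] + w[1])


def _class_log_likelihood(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """(n, 2) Gaussian log-densities plus log-priors."""
    n, d = X.shape
    out = np.empty((n, 2))
    for c in (0, 1):
        diff = X - model.means[c]
        maha = np.einsum("ni,ij,nj->n", diff, model.inv_covs[c], diff)
        out[:, c] = -0.5 * (maha + model.log_dets[c] + d * _LOG_2PI) + np.log(
            model.priors[c]
        )
    return out


def qda_fold_posterior(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> np.ndarray:
    """P(y=1 | v) on X_test for a QDA fit on (X_train, y_train).

    Equivalent to ``posterior(fit_qda(X_train, y_train), X_test)`` without
    the model-object overhead; used in the forward-selection inner loop.
    """
    return _posterior_from_stats(*_qda_stats(X_train, y_train, shrinkage), X_test)


def posterior(model: QdaModel, features: np.ndarray) -> np.ndarray:
    """P(y = 1 | v) per sample, via a stable log-sum-exp normalization."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.n_features:
        raise InputError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    ll = _class_log_likelihood(model, X)
    m = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - m)
    return w[:, 1] / w.sum(axis=1)


def predict(model: QdaModel, features: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (posterior(model, features) >= threshold).astype(np.int64)


def accuracy(outcome: np.ndarray, predicted: np.ndarray) -> float:
    outcome = np.asarray(outcome)
    predicted = np.asarray(predicted)
    if outcome.size == 0:
        raise InputError("accuracy of empty input is undefined")
    if outcome.shape != predicted.shape:
        raise InputError("length mismatch between outcome and predictions")
    return float(np.mean(outcome == predicted))


def _average_ranks(s: np.ndarray) -> np.ndarray:
    # midrank of each element (ties get the average of their rank range)
    ss = np.sort(s)
    lo = np.searchsorted(ss, s, side="left")
    hi = np.searchsorted(ss, s, side="right")
    return 0.5 * (lo + hi + 1)


def auc_score(outcome: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the normalized Mann-Whitney statistic.

    Ties between a case score and a control score count one half.
    """
    y = np.asarray(outcome)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InputError("length mismatch between outcome and scores")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined: outcome has a single class")
    r = _average_ranks(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
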