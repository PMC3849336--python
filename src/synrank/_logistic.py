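"""Batched maximum-likelihood logistic regression with coefficient tests.

This is the numerical engine behind the synergy-network weights.  Designs are
tiny (2 or 4 columns) but very numerous — one fit per feature and one per
unordered feature pair, rebuilt inside every cross-validation fold — so the
solver runs Newton iterations simultaneously over a whole batch of design
matrices instead of looping over per-fit library calls.

Fit status codes (per batch element):
  OK          plain ML fit converged
  RIDGE       non-convergent ML fit; refit with a small L2 penalty on slopes
  SEPARATION  data perfectly separated; the tested effect is capped at the
              p-value floor
  FAILED      no usable fit; the caller assigns zero weight
  COLLINEAR   design is rank-deficient (e.g. product term collinear); the
              caller assigns zero weight
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, log_expit

P_FLOOR = 1e-300
RIDGE_FALLBACK = 1e-4
_MAX_STEP = 20.0

OK, RIDGE, SEPARATION, FAILED, COLLINEAR = 0, 1, 2, 3, 4


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log L = sum_i [ y*eta - log(1+exp(eta)) ], numerically stable
    return (y * eta + log_expit(-eta)).sum(axis=-1)


def newton_logit_batch(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit logistic models for a batch of designs sharing one outcome.

    Parameters
    ----------
    X : (B, n, d) array — designs, first column is the intercept.
    y : (n,) or (B, n) binary array.
    ridge : L2 penalty applied to slope coefficients (never the intercept).

    Returns
    -------
    beta : (B, d) coefficient estimates
    cov : (B, d, d) inverse observed information at the estimate
    converged : (B,) bool
    mu : (B, n) fitted probabilities
    """
    X = np.asarray(X, dtype=float)
    B, n, d = X.shape
    y = np.broadcast_to(np.asarray(y, dtype=float), (B, n))
    beta = np.zeros((B, d))
    converged = np.zeros(B, dtype=bool)
    eye_slopes = np.zeros((d, d))
    eye_slopes[np.arange(1, d), np.arange(1, d)] = 1.0

    # iterate only the not-yet-converged slice of the batch
    active = np.arange(B)
    for _ in range(max_iter):
        Xa, ya, ba = X[active], y[active], beta[active]
        eta = np.einsum("bnd,bd->bn", Xa, ba)
        mu_a = expit(eta)
        w = mu_a * (1.0 - mu_a)
        grad = np.einsum("bnd,bn->bd", Xa, ya - mu_a)
        if ridge:
            grad -= ridge * ba @ eye_slopes
        H = np.einsum("bnd,bn,bne->bde", Xa, w, Xa)
        if ridge:
            H += ridge * eye_slopes
        # tiny jitter keeps the batched solve from raising on separated fits
        H[:, np.arange(d), np.arange(d)] += (
            1e-12 * (1.0 + np.trace(H, axis1=1, axis2=2))[:, None]
        )
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        big = np.abs(step).max(axis=1)
        scale = np.where(big > _MAX_STEP, _MAX_STEP / np.maximum(big, 1e-30), 1.0)
        step *= scale[:, None]
        beta[active] = ba + step
        done = np.abs(step).max(axis=1) < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    eta = np.einsum("bnd,bd->bn", X, beta)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = np.einsum("bnd,bn,bne->bde", X, w, X)
    if ridge:
        H += ridge * eye_slopes
    H[:, np.arange(d), np.arange(d)] += 1e-300
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover - jitter prevents this
        cov = np.linalg.pinv(H)
    return beta, cov, converged, mu


def _collinear_mask(X: np.ndarray) -> np.ndarray:
    """True where the design is numerically rank-deficient."""
    gram = np.einsum("bnd,bne->bde", X, X)
    ev = np.linalg.eigvalsh(gram)
    return ev[:, 0] < 1e-10 * np.maximum(ev[:, -1], 1e-30)


def coef_pvalues_batch(
    X: np.ndarray,
    y: np.ndarray,
    coef_index: int,
    test: str = "wald",
    p_floor: float = P_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """p-value of one coefficient for every design in a batch.

    Returns ``(p, status)`` with ``p`` in [p_floor, 1] and ``status`` the
    per-element fit status code. Failed / collinear fits report p = 1
    (zero weight downstream).
    """
    if test not in {"wald", "lr"}:
        raise ValueError(f"unknown test {test!r}")
    X = np.asarray(X, dtype=float)
    B, n, d = X.shape
    yb = np.broadcast_to(np.asarray(y, dtype=float), (B, n))
    p = np.ones(B)
    status = np.full(B, OK, dtype=np.int8)

    bad = _collinear_mask(X)
    status[bad] = COLLINEAR
    good = ~bad
    if not good.any():
        return p, status

    Xg, yg = X[good], yb[good]
    beta, cov, conv, mu = newton_logit_batch(Xg, yg)

    # perfect (quasi-)separation: the diverging fit reproduces y exactly
    sep = ~conv & (np.abs(mu - yg).max(axis=1) < 1e-3)
    need_ridge = ~conv & ~sep
    if need_ridge.any():
        b2, c2, conv2, mu2 = newton_logit_batch(
            Xg[need_ridge], yg[need_ridge], ridge=RIDGE_FALLBACK
        )
        beta[need_ridge], cov[need_ridge], mu[need_ridge] = b2, c2, mu2
        ok_ridge = np.zeros(len(Xg), dtype=bool)
        ok_ridge[need_ridge] = conv2
        failed = need_ridge & ~ok_ridge
    else:
        ok_ridge = np.zeros(len(Xg), dtype=bool)
        failed = np.zeros(len(Xg), dtype=bool)

    if test == "wald":
        se = np.sqrt(np.maximum(cov[:, coef_index, coef_index], 1e-300))
        z = beta[:, coef_index] / se
        pg = 2.0 * stats.norm.sf(np.abs(z))
    else:
        eta = np.einsum("bnd,bd->bn", Xg, beta)
        ll_full = _log_likelihood(eta, yg)
        keep = [k for k in range(d) if k != coef_index]
        b0, _, _, _ = newton_logit_batch(Xg[:, :, keep], yg)
        eta0 = np.einsum("bnd,bd->bn", Xg[:, :, keep], b0)
        ll_red = _log_likelihood(eta0, yg)
        lr = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        pg = stats.chi2.sf(lr, df=1)

    pg = np.clip(pg, p_floor, 1.0)
    pg[sep] = p_floor
    pg[failed] = 1.0

    sg = np.full(len(Xg), OK, dtype=np.int8)
    sg[ok_ridge] = RIDGE
    sg[sep] = SEPARATION
    sg[failed] = FAILED
    p[good] = pg
    status[good] = sg
    return p, status
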