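"""L1-penalized logistic regression via IRLS + cyclic coordinate descent.

Solves

    min_{b0, b}  (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
                 + lam * sum_j penalty_factor_j * |b_j|,
    eta_i = b0 + x_i . b

with an unpenalized intercept, soft-thresholding updates on a weighted
quadratic approximation of the Bernoulli log-likelihood, and warm starts
along a decreasing penalty path.  For ``lam >= lam_max`` (all penalty
factors one) the exact null solution ``b = 0``, ``b0 = logit(mean(y))``
is returned in closed form, since it satisfies the KKT conditions there.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConvergenceError",
    "lambda_max",
    "fit_penalized",
    "fit_path",
    "binomial_deviance",
]

# IRLS weight floor, as in coordinate-descent GLM solvers
_WEIGHT_FLOOR = 1e-5
_ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    """Raised when the solver does not converge within ``max_iter`` passes."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def lambda_max(X: np.ndarray, y: np.ndarray, penalty_factor: np.ndarray | None = None) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    Computed from the score of the null (intercept-only) model:
    ``max_j |x_j . (y - mean(y))| / (n * factor_j)`` over penalized j.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    score = np.abs(X.T @ (y - y.mean())) / n
    if penalty_factor is None:
        return float(score.max())
    factor = np.asarray(penalty_factor, dtype=float)
    penalized = factor > 0
    if not penalized.any():
        return 0.0
    return float((score[penalized] / factor[penalized]).max())


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-7,
    max_iter: int = 1000,
    penalty_factor: np.ndarray | None = None,
    coef_init: np.ndarray | None = None,
    intercept_init: float | None = None,
) -> tuple[float, np.ndarray, int]:
    """Fit one penalized logistic regression.

    Returns ``(intercept, coef, n_iter)``.  ``penalty_factor`` rescales the
    penalty per coefficient (0 exempts a coefficient, e.g. an autoregressive
    path).  Raises :class:`ConvergenceError` if ``max_iter`` IRLS passes do
    not reach ``tol`` (maximum absolute parameter change).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    ybar = float(y.mean())
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("outcome is constant; logistic fit undefined")

    factor = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, dtype=float)

    # Exact null-model branch: for lam >= lam_max (all coefficients penalized
    # at unit factor) the zero vector satisfies the KKT conditions and the
    # intercept is the closed-form marginal logit.
    if lam > 0 and np.all(factor == 1.0) and lam >= lambda_max(X, y):
        return float(np.log(ybar / (1.0 - ybar))), np.zeros(p), 0

    b = np.zeros(p) if coef_init is None else np.array(coef_init, dtype=float)
    b0 = float(np.log(ybar / (1.0 - ybar))) if intercept_init is None else float(intercept_init)

    thresholds = lam * factor
    eta = b0 + X @ b

    for it in range(1, max_iter + 1):
        p_hat = _sigmoid(eta)
        w = np.clip(p_hat * (1.0 - p_hat), _WEIGHT_FLOOR, None)
        z = eta + (y - p_hat) / w
        wn = w / n
        # covariance updates: the weighted least-squares surrogate only
        # needs these p-dimensional summaries, so each sweep is O(p^2)
        A = (X * wn[:, None]).T @ X  # (p, p) weighted Gram / n
        v = X.T @ (wn * z)  # (p,)
        u = X.T @ wn  # (p,)
        wz_sum = float(wn @ z)
        sum_wn = float(wn.sum())
        diagA = np.diag(A).copy()
        Ab = A @ b

        max_delta = 0.0
        for _ in range(1000):
            delta = 0.0
            for j in range(p):
                if diagA[j] <= 0.0:  # constant-zero column in this (re)sample
                    continue
                bj = b[j]
                grad = v[j] - u[j] * b0 - Ab[j] + diagA[j] * bj
                new = _soft(grad, thresholds[j]) / diagA[j]
                if new != bj:
                    Ab += A[:, j] * (new - bj)
                    b[j] = new
                    delta = max(delta, abs(new - bj))
            new0 = (wz_sum - float(u @ b)) / sum_wn
            if new0 != b0:
                delta = max(delta, abs(new0 - b0))
                b0 = new0
            max_delta = max(max_delta, delta)
            if delta < tol * 0.1:
                break
        eta = b0 + X @ b
        if max_delta < tol:
            return b0, b, it
        if not np.all(np.isfinite(b)) or abs(b0) > 1e6 or np.abs(b).max() > 1e6:
            raise ConvergenceError("parameters diverging (separation?)", it)

    raise ConvergenceError("coordinate descent did not converge", max_iter)


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    *,
    tol: float = 1e-7,
    max_iter: int = 1000,
    penalty_factor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a decreasing penalty path with warm starts.

    Returns ``(intercepts, coefs)`` with shapes ``(L,)`` and ``(L, p)``.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("penalty path must be non-increasing")
    p = X.shape[1]
    intercepts = np.empty(lambdas.shape[0])
    coefs = np.empty((lambdas.shape[0], p))
    b = np.zeros(p)
    b0 = None
    for k, lam in enumerate(lambdas):
        b0, b, _ = fit_penalized(
            X,
            y,
            float(lam),
            tol=tol,
            max_iter=max_iter,
            penalty_factor=penalty_factor,
            coef_init=b,
            intercept_init=b0,
        )
        intercepts[k] = b0
        coefs[k] = b
    return intercepts, coefs


def binomial_deviance(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Mean binomial deviance ``-(2/n) sum [y log p + (1-y) log(1-p)]``."""
    p_hat = np.clip(p_hat, 1e-10, 1.0 - 1e-10)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p_hat) + (1.0 - y) * np.log(1.0 - p_hat)))
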