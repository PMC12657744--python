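"""Cross-lagged panel network estimation.

For one ordered wave pair (t, t+1), each item at wave t+1 is regressed on
every item at wave t (including itself — the autoregressive path) with
L1-penalized logistic regression, one model per outcome item.  The
coefficients on the log-odds scale are assembled into a directed weighted
network ``B`` with ``B[i, j]`` = effect of item i at wave t on item j at
wave t+1; ``exp(B)`` gives the odds-ratio view where 1 means "no edge".

The penalty for each outcome is chosen by K-fold cross-validated binomial
deviance over a log-spaced path from the smallest all-zero penalty
(lambda_max) down to lambda_max/1000, glmnet-style, or fixed by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _solver
from ._solver import ConvergenceError
from .io import PanelDataset, recode_reverse

__all__ = [
    "FitConfig",
    "CLPNetwork",
    "penalized_logistic",
    "select_lambda",
    "fit_clpn",
    "to_odds_ratios",
    "ConvergenceError",
]

logger = logging.getLogger(__name__)

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings for one network fit.

    lambda_mode
        ``"cv_1se"`` (default): largest per-outcome penalty whose 10-fold
        cross-validated deviance is within one standard error of the
        minimum — the usual conservative rule, chosen for its specificity
        (a null network should come back essentially empty).
        ``"cv_min"``: penalty at the deviance minimum (ties broken toward
        the larger, sparser penalty).  ``"fixed"``: use ``lambda_value``
        for every outcome.
    penalize_autoregressive
        Whether the self-path coefficient is shrunk like any other (default
        True); set False to exempt it from the penalty.
    standardize_predictors
        On by default, as in glmnet: predictors are standardized internally
        for the penalty only and coefficients are returned on the original
        0/1 scale, so the odds-ratio interpretation is unchanged.  Without
        it, low-variance items (very rare or near-universal symptoms)
        receive a harsher effective penalty than the rest.
    direction_convention
        ``"recode_reverse_first"`` (default) flips reverse-keyed items
        before fitting so all items point toward depression; ``"raw"``
        fits the items as coded, so positively worded items yield negative
        associations with the depressive items.
    """

    lambda_mode: str = "cv_1se"
    lambda_value: float | None = None
    n_folds: int = 10
    penalize_autoregressive: bool = True
    standardize_predictors: bool = True
    direction_convention: str = "recode_reverse_first"
    seed: int = 0
    tol: float = 1e-7
    max_iter: int = 1000

    def __post_init__(self):
        if self.lambda_mode not in ("cv_1se", "cv_min", "fixed"):
            raise ValueError("lambda_mode must be 'cv_1se', 'cv_min' or 'fixed'")
        if self.lambda_mode == "fixed":
            if self.lambda_value is None or self.lambda_value < 0:
                raise ValueError("fixed lambda_mode needs lambda_value >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.direction_convention not in ("recode_reverse_first", "raw"):
            raise ValueError("direction_convention must be 'recode_reverse_first' or 'raw'")


@dataclass
class CLPNetwork:
    """A fitted cross-lagged panel network for one wave pair."""

    items: tuple[str, ...]
    B: np.ndarray  # (p, p) log-odds weights, rows = predictors, cols = outcomes
    intercepts: np.ndarray  # (p,) per-outcome intercepts
    n_fit: int
    lambda_used: dict[str, float] | None
    wave_pair: tuple[str, str]

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        p = len(self.items)
        if self.B.shape != (p, p):
            raise ValueError("B must be (p, p)")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("B must be finite")

    @property
    def odds_ratios(self) -> np.ndarray:
        """Elementwise exp(B); exactly 1 wherever B is exactly 0."""
        return np.exp(self.B)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def edge(self, source: str, target: str) -> float:
        return float(self.B[self.items.index(source), self.items.index(target)])

    def cross_lagged_mask(self) -> np.ndarray:
        return ~np.eye(self.n_items, dtype=bool)


def _prepare_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("predictors and outcome must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; cannot fit a logistic model")
    return X, y


def _penalty_factor(p: int, config: FitConfig, self_index: int | None) -> np.ndarray | None:
    if config.penalize_autoregressive or self_index is None:
        return None
    factor = np.ones(p)
    factor[self_index] = 0.0
    return factor


def penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: FitConfig | None = None,
    *,
    penalty_factor: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """One L1-penalized logistic regression (intercept unpenalized).

    Minimizes mean negative Bernoulli log-likelihood plus
    ``lam * sum|coef|``.  At ``lam = 0`` exactly collinear predictors raise
    (no silent pseudo-inverse); with a positive penalty the L1 term resolves
    the degeneracy.
    """
    config = config or FitConfig()
    X, y = _prepare_xy(X, y)
    if lam == 0.0:
        design = np.column_stack([np.ones(X.shape[0]), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("exactly collinear predictors at lambda=0; drop a column")

    if config.standardize_predictors:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant predictor column cannot be standardized")
        b0, b, _ = _solver.fit_penalized(
            (X - mu) / sd, y, lam, tol=config.tol, max_iter=config.max_iter,
            penalty_factor=penalty_factor,
        )
        b = b / sd
        b0 = b0 - float(mu @ b)
        return b0, b
    b0, b, _ = _solver.fit_penalized(
        X, y, lam, tol=config.tol, max_iter=config.max_iter, penalty_factor=penalty_factor,
    )
    return b0, b


def lambda_path(X: np.ndarray, y: np.ndarray, penalty_factor=None) -> np.ndarray:
    lmax = _solver.lambda_max(X, y, penalty_factor)
    return np.geomspace(lmax, lmax * LAMBDA_MIN_RATIO, N_LAMBDA)


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    """Seeded stratified folds whose every training part has both classes;
    reshuffles up to 10 times before giving up."""
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < 2:
        raise ValueError("minority class has < 2 observations; cannot cross-validate")
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with both outcome classes in every training set")


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    config: FitConfig | None = None,
    *,
    penalty_factor: np.ndarray | None = None,
    return_details: bool = False,
):
    """Cross-validated penalty for one outcome.

    K-fold CV over a 100-point log-spaced path from lambda_max down to
    lambda_max/1000.  ``cv_min`` returns the penalty minimizing mean
    out-of-fold binomial deviance (ties go to the larger penalty, i.e.
    the sparser model, because the path is scanned from large to small);
    ``cv_1se`` (default) returns the largest penalty within one standard
    error of that minimum.
    """
    config = config or FitConfig()
    X, y = _prepare_xy(X, y)
    if X.shape[0] < config.n_folds:
        raise ValueError("need at least n_folds observations")
    if config.standardize_predictors:
        # select the penalty on the same (standardized) scale it is applied on
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant predictor column cannot be standardized")
        X = (X - X.mean(axis=0)) / sd
    path = lambda_path(X, y, penalty_factor)
    folds = _stratified_folds(y, config.n_folds, config.seed)

    # CV ranks penalties by out-of-fold deviance; the path fits can run at a
    # looser tolerance than the final fit without changing the ranking
    cv_tol = max(config.tol, 1e-5)
    deviance = np.zeros((len(folds), path.size))
    for k, (train, test) in enumerate(folds):
        intercepts, coefs = _solver.fit_path(
            X[train], y[train], path,
            tol=cv_tol, max_iter=config.max_iter, penalty_factor=penalty_factor,
        )
        eta = intercepts[None, :] + X[test] @ coefs.T  # (n_test, L)
        probs = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        for l in range(path.size):
            deviance[k, l] = _solver.binomial_deviance(y[test], probs[:, l])
    mean_dev = deviance.mean(axis=0)
    best = int(np.argmin(mean_dev))  # first minimum = largest penalty on a descending path
    if config.lambda_mode == "cv_1se":
        se = deviance[:, best].std(ddof=1) / np.sqrt(len(folds))
        within = np.flatnonzero(mean_dev <= mean_dev[best] + se)
        best = int(within.min())  # largest penalty within one SE
    if return_details:
        return float(path[best]), path, mean_dev
    return float(path[best])


def fit_clpn(
    panel: PanelDataset,
    wave_t: str,
    wave_t1: str,
    config: FitConfig | None = None,
) -> CLPNetwork:
    """Estimate the cross-lagged panel network for one wave pair.

    Requires complete data on both waves (run imputation or complete-case
    filtering first).  Each outcome item at ``wave_t1`` is regressed on all
    items at ``wave_t``; per-outcome penalties come from ``config``.
    """
    config = config or FitConfig()
    if config.direction_convention == "recode_reverse_first" and panel.codebook.reverse_keyed:
        panel = recode_reverse(panel)

    if not panel.is_complete([wave_t, wave_t1]):
        raise ValueError(
            f"waves ({wave_t}, {wave_t1}) contain missing values; impute or take complete cases"
        )
    X = panel.wave_matrix(wave_t)
    p = panel.codebook.n_items
    B = np.zeros((p, p))
    intercepts = np.zeros(p)
    lambdas: dict[str, float] = {}
    for j, item in enumerate(panel.items):
        y = panel.wave_matrix(wave_t1)[:, j]
        factor = _penalty_factor(p, config, j)
        try:
            if config.lambda_mode == "fixed":
                lam = float(config.lambda_value)
            else:
                lam = select_lambda(X, y, config, penalty_factor=factor)
            b0, b = penalized_logistic(X, y, lam, config, penalty_factor=factor)
        except ConvergenceError as err:
            raise ConvergenceError(f"outcome item {item!r}: {err}", err.n_iter) from err
        except ValueError as err:
            raise ValueError(f"outcome item {item!r}: {err}") from err
        B[:, j] = b
        intercepts[j] = b0
        lambdas[item] = lam
    logger.info(
        "fit_clpn %s->%s: n=%d, nonzero cross-lagged edges=%d",
        wave_t, wave_t1, panel.n_persons, int(np.count_nonzero(B[~np.eye(p, dtype=bool)])),
    )
    return CLPNetwork(
        items=panel.items,
        B=B,
        intercepts=intercepts,
        n_fit=panel.n_persons,
        lambda_used=lambdas,
        wave_pair=(wave_t, wave_t1),
    )


def to_odds_ratios(net: CLPNetwork) -> np.ndarray:
    """Edge weights as odds ratios: elementwise exp; a zero log-odds entry
    maps to exactly 1 ("no connection")."""
    return net.odds_ratios
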