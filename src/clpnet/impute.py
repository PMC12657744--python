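"""Minimal chained-equation single imputation for binary panel items.

Missing item-wave cells are initialized by draws from each column's
observed marginal, then cycled: each incomplete column is regressed
(unpenalized logistic) on every other item-wave column plus the auxiliary
covariates using the currently completed data, and its missing cells are
re-drawn as Bernoulli(fitted probability).  Observed cells are never
altered; one completed dataset is returned (single imputation — run the
loop over seeds yourself if you want several).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .io import PanelDataset

__all__ = ["ImputeConfig", "chained_impute", "complete_cases"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputeConfig:
    n_cycles: int = 10
    aux_vars: tuple[str, ...] = ()
    seed: int = 0
    max_iter: int = 200  # inner logistic solver iterations

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def _encode_aux(aux: pd.DataFrame | None, aux_vars: Sequence[str]) -> np.ndarray | None:
    if not aux_vars:
        return None
    if aux is None:
        raise ValueError(f"aux covariates {list(aux_vars)} requested but panel has none")
    missing = [v for v in aux_vars if v not in aux.columns]
    if missing:
        raise ValueError(f"aux covariates not present: {missing}")
    sub = aux[list(aux_vars)]
    if sub.isna().any().any():
        raise ValueError("aux covariates must be complete for every person")
    encoded = pd.get_dummies(sub, drop_first=True, dtype=float)
    return encoded.to_numpy(dtype=float)


def chained_impute(panel: PanelDataset, config: ImputeConfig | None = None) -> PanelDataset:
    """Return one completed copy of ``panel`` (seeded, deterministic).

    A column whose logistic fit fails (single observed class, solver
    failure, non-finite coefficients) falls back to a marginal draw for
    that cycle, with a logged warning.  An all-missing column is an error.
    """
    config = config or ImputeConfig()
    rng = np.random.default_rng(config.seed)
    n, p, w = panel.responses.shape
    cols = panel.responses.transpose(0, 2, 1).reshape(n, w * p).copy()  # wave-major blocks
    names = [f"{item}@{wave}" for wave in panel.waves for item in panel.items]
    miss = np.isnan(cols)

    if not miss.any():
        return panel.copy()
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [names[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"columns with no observed values: {bad}")

    aux_X = _encode_aux(panel.aux, config.aux_vars)

    # initialize from observed marginals
    for j in np.flatnonzero(miss.any(axis=0)):
        p_obs = np.nanmean(cols[:, j])
        cols[miss[:, j], j] = (rng.random(int(miss[:, j].sum())) < p_obs).astype(float)

    incomplete = list(np.flatnonzero(miss.any(axis=0)))
    for _cycle in range(config.n_cycles):
        for j in incomplete:
            obs_rows = ~miss[:, j]
            y = cols[obs_rows, j]
            predictors = np.delete(cols, j, axis=1)
            if aux_X is not None:
                predictors = np.column_stack([predictors, aux_X])
            prob = _fit_draw_probability(
                predictors[obs_rows], y, predictors[miss[:, j]], names[j], config.max_iter
            )
            cols[miss[:, j], j] = (rng.random(prob.shape[0]) < prob).astype(float)

    out = panel.copy()
    out.responses = cols.reshape(n, w, p).transpose(0, 2, 1).copy()
    # observed cells are bitwise untouched by construction (only miss cells written)
    return out


def _fit_draw_probability(X_obs, y, X_miss, col_name, max_iter) -> np.ndarray:
    """Fitted P(y=1) on the missing rows, or the marginal on failure."""
    marginal = float(y.mean())
    if marginal in (0.0, 1.0):
        logger.warning("impute: column %s has a single observed class; marginal draw", col_name)
        return np.full(X_miss.shape[0], marginal)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
            model.fit(X_obs, y)
        if not (np.all(np.isfinite(model.coef_)) and np.all(np.isfinite(model.intercept_))):
            raise ValueError("non-finite coefficients")
        return model.predict_proba(X_miss)[:, 1]
    except Exception as err:  # noqa: BLE001 - any fit failure degrades to marginal
        logger.warning("impute: logistic fit failed for %s (%s); marginal draw", col_name, err)
        return np.full(X_miss.shape[0], marginal)


def complete_cases(panel: PanelDataset, waves: Sequence[str]) -> PanelDataset:
    """Persons with no missing item in the named waves (sensitivity mode)."""
    idx = [panel.wave_index(w) for w in waves]
    keep = ~np.isnan(panel.responses[:, :, idx]).any(axis=(1, 2))
    if not keep.any():
        raise ValueError(f"no complete cases for waves {list(waves)}")
    return PanelDataset(
        panel.persons[keep],
        panel.waves,
        panel.responses[keep],
        panel.codebook,
        None if panel.aux is None else panel.aux.iloc[np.flatnonzero(keep)],
    )
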