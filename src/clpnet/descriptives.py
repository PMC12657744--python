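"""Sample descriptives for dichotomous item panels.

Endorsement counts/proportions per item and wave, closed-form Bernoulli
item moments, KR-20 internal consistency (Cronbach's alpha for binary
items), and paired t-tests on sum scores across waves.

For a Bernoulli(p) item the population moments are available in closed
form:  skewness (1-2p)/sqrt(p(1-p)) and excess kurtosis
(1-6p(1-p))/(p(1-p)); at p=0.5 these are 0 and -2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import PanelDataset, recode_reverse

__all__ = [
    "bernoulli_moments",
    "endorsement",
    "kr20_alpha",
    "paired_ttest",
    "describe_panel",
    "DEPRESSED_AFFECT_ITEMS",
    "SOMATIC_ITEMS",
]

# CES-D-8 subscales: five depressive-affect items, three somatic complaints
DEPRESSED_AFFECT_ITEMS = ("depressed", "happy", "lonely", "enjoy", "sad")
SOMATIC_ITEMS = ("effort", "sleep", "getgoing")


def bernoulli_moments(p: float) -> tuple[float, float]:
    """Population skewness and excess kurtosis of a Bernoulli(p) item."""
    if not 0.0 < p < 1.0:
        raise ValueError("moments are undefined at p in {0, 1}")
    q = 1.0 - p
    return (1.0 - 2.0 * p) / np.sqrt(p * q), (1.0 - 6.0 * p * q) / (p * q)


def endorsement(panel: PanelDataset) -> pd.DataFrame:
    """Endorsement count/proportion and item moments per item and wave.

    Proportions use the non-missing denominator per item-wave cell.
    Moments are reported as NaN for degenerate (all-0 or all-1) cells.
    """
    rows = []
    for wave in panel.waves:
        for item in panel.items:
            col = panel.values(item, wave)
            obs = col[~np.isnan(col)]
            n_obs = obs.size
            n_end = int(obs.sum()) if n_obs else 0
            p = n_end / n_obs if n_obs else 0.0
            if 0.0 < p < 1.0:
                skew, kurt = bernoulli_moments(p)
            else:
                skew, kurt = np.nan, np.nan
            rows.append((item, wave, n_end, n_obs, p, skew, kurt))
    return pd.DataFrame(
        rows,
        columns=[
            "item", "wave", "n_endorsed", "n_observed",
            "prop_endorsed", "skewness", "excess_kurtosis",
        ],
    )


def kr20_alpha(items_matrix: np.ndarray) -> float:
    """KR-20 internal consistency for a persons x items binary matrix.

    ``(k/(k-1)) * (1 - sum p_i q_i / Var(sum))`` — Cronbach's alpha
    specialized to dichotomous items, with population (1/n) variances
    throughout, so k identical columns give exactly 1.  Rows with any
    missing value are dropped with a warning (the total-score variance
    needs complete rows).
    """
    X = np.asarray(items_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    complete = ~np.isnan(X).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"kr20_alpha: dropping {int((~complete).sum())} incomplete rows", stacklevel=2
        )
        X = X[complete]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 complete rows")
    k = X.shape[1]
    p = X.mean(axis=0)
    total_var = X.sum(axis=1).var(ddof=0)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - (p * (1.0 - p)).sum() / total_var))


def paired_ttest(sum_t: np.ndarray, sum_t1: np.ndarray) -> tuple[float, float, int]:
    """Classical paired-samples t-test on per-person scores at two waves.

    Returns (t, two-sided p, df).  Pairs with a missing score are dropped.
    """
    a = np.asarray(sum_t, dtype=float)
    b = np.asarray(sum_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must pair the same persons")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    d = a - b
    if d.size < 2 or np.allclose(d, d[0]):
        raise ValueError("need >= 2 pairs with non-identical differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), int(d.size - 1)


def describe_panel(panel: PanelDataset, recode_for_alpha: bool = True) -> dict:
    """Descriptive summary: per item-wave endorsement/moments and
    per-wave KR-20 for the full scale and the affect/somatic subscales.

    Moments and endorsement are computed on the data as coded; internal
    consistency is computed after recoding reverse-keyed items (a scale
    with mixed keying has artificially negative covariances).
    """
    table = endorsement(panel)
    scale_panel = recode_reverse(panel) if (
        recode_for_alpha and panel.codebook.reverse_keyed
    ) else panel
    known = set(panel.items)
    subscales = {"full": panel.items}
    if set(DEPRESSED_AFFECT_ITEMS) <= known:
        subscales["depressed_affect"] = DEPRESSED_AFFECT_ITEMS
    if set(SOMATIC_ITEMS) <= known:
        subscales["somatic"] = SOMATIC_ITEMS
    alphas: dict[str, dict[str, float]] = {}
    for wave in panel.waves:
        alphas[wave] = {}
        for name, items in subscales.items():
            idx = [panel.item_index(it) for it in items]
            mat = scale_panel.wave_matrix(wave)[:, idx]
            try:
                alphas[wave][name] = kr20_alpha(mat)
            except ValueError:
                alphas[wave][name] = float("nan")
    return {"endorsement": table, "alpha": alphas}
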