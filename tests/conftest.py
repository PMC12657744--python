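"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from clpnet.io import ItemCodebook
from clpnet.synthetic import SyntheticSpec, simulate_panel, default_fixture_spec


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent unpenalized Newton-IRLS logistic fit (test oracle).

    Deliberately written from the normal equations, not via the package
    solver: beta_{k+1} = beta_k + (X'WX)^-1 X'(y - p).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        H = (Xd * W[:, None]).T @ Xd
        step = np.linalg.solve(H, Xd.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[0], beta[1:]


def bernoulli_design(n, p, prevalence, seed):
    """Random binary design matrix with a logistic outcome attached later."""
    rng = np.random.default_rng(seed)
    return (rng.random((n, p)) < prevalence).astype(float), rng


def logistic_outcome(X, intercept, coefs, rng):
    eta = intercept + X @ np.asarray(coefs, dtype=float)
    return (rng.random(X.shape[0]) < 1.0 / (1.0 + np.exp(-eta))).astype(float)


def null_spec(seed: int, prevalences=None) -> SyntheticSpec:
    """Two-wave spec with no transition structure (B = 0)."""
    prev = prevalences or (0.12, 0.20, 0.36, 0.92, 0.12, 0.91, 0.20, 0.20)
    p = len(prev)
    codebook = ItemCodebook(tuple(f"i{k}" for k in range(p)))
    logits = np.log(np.asarray(prev) / (1.0 - np.asarray(prev)))
    return SyntheticSpec(
        codebook=codebook,
        n_waves=2,
        wave1_prevalence=tuple(prev),
        B=(np.zeros((p, p)),),
        intercepts=(logits,),
        seed=seed,
    )


def small_edge_spec(seed: int, edges: dict, p: int = 4, prevalence: float = 0.3,
                    autoregressive: float = 0.8) -> SyntheticSpec:
    """Small p-item spec with named cross-lagged edges {(i, j): weight}."""
    codebook = ItemCodebook(tuple(f"i{k}" for k in range(p)))
    B = np.eye(p) * autoregressive
    for (i, j), w in edges.items():
        B[i, j] = w
    return SyntheticSpec(
        codebook=codebook,
        n_waves=2,
        wave1_prevalence=(prevalence,) * p,
        B=(B,),
        seed=seed,
    )


@pytest.fixture(scope="session")
def fixture_panel_small():
    """Complete 8-item fixture panel, modest n, for structural tests."""
    return simulate_panel(default_fixture_spec(seed=11), 600)


@pytest.fixture(scope="session")
def fixture_panel_missing():
    """Fixture panel with MAR missingness applied."""
    from clpnet.synthetic import apply_missingness

    spec = default_fixture_spec(seed=12)
    return apply_missingness(simulate_panel(spec, 800), spec), spec
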