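"""Network estimation: penalty selection, fitting contracts, invariances."""

import numpy as np
import pytest

from clpnet.clpn import (
    FitConfig,
    fit_clpn,
    lambda_path,
    penalized_logistic,
    select_lambda,
    to_odds_ratios,
)
from clpnet.io import ItemCodebook, PanelDataset
from clpnet.synthetic import SyntheticSpec, simulate_panel

from conftest import bernoulli_design, logistic_outcome, small_edge_spec


def test_large_lambda_full_shrinkage_intercept_logit():
    X, rng = bernoulli_design(400, 8, 0.3, 1)
    y = logistic_outcome(X, -1.0, np.full(8, 0.4), rng)
    b0, b = penalized_logistic(X, y, 10.0, FitConfig(standardize_predictors=False))
    assert np.all(b == 0.0)
    assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-10)


def test_exact_collinearity_rejected_at_zero_lambda():
    X, rng = bernoulli_design(200, 3, 0.4, 2)
    X = np.column_stack([X, X[:, 0]])  # duplicate predictor
    y = logistic_outcome(X[:, :3], -0.5, [1.0, 0.2, -0.2], rng)
    with pytest.raises(ValueError, match="collinear"):
        penalized_logistic(X, y, 0.0)
    # a positive penalty resolves the degeneracy
    b0, b = penalized_logistic(X, y, 0.05, FitConfig(standardize_predictors=False))
    assert np.all(np.isfinite(b))


def test_constant_outcome_named_in_fit_clpn_error():
    cb = ItemCodebook(("a", "b"))
    resp = np.zeros((30, 2, 2))
    resp[:, 0, 0] = np.tile([0, 1], 15)
    resp[:, 0, 1] = np.tile([0, 1], 15)
    resp[:, 1, 0] = np.tile([0, 1], 15)
    # item b at wave 2 stays all-zero -> constant outcome
    panel = PanelDataset(np.array([f"p{i}" for i in range(30)]), ("w1", "w2"), resp, cb)
    with pytest.raises(ValueError, match="'b'"):
        fit_clpn(panel, "w1", "w2", FitConfig(lambda_mode="fixed", lambda_value=0.1))


class TestSelectLambda:
    def test_path_head_zeroes_everything(self):
        X, rng = bernoulli_design(500, 8, 0.3, 3)
        y = logistic_outcome(X, -0.5, np.zeros(8), rng)
        path = lambda_path(X, y)
        b0, b = penalized_logistic(X, y, float(path[0]),
                                   FitConfig(standardize_predictors=False))
        assert np.all(b == 0.0)

    def test_pure_noise_outcome_mostly_shrunk(self):
        """y independent of X (n=2000): the selected model keeps at most
        2 of 8 noise coefficients."""
        X, rng = bernoulli_design(2000, 8, 0.3, 4)
        y = (rng.random(2000) < 0.4).astype(float)
        cfg = FitConfig(seed=4)
        lam = select_lambda(X, y, cfg)
        b0, b = penalized_logistic(X, y, lam, cfg)
        assert int(np.count_nonzero(b)) <= 2

    def test_strong_predictor_retained(self):
        X, rng = bernoulli_design(2000, 8, 0.3, 5)
        coefs = np.zeros(8)
        coefs[2] = 2.0
        y = logistic_outcome(X, -1.0, coefs, rng)
        cfg = FitConfig(seed=5)
        lam = select_lambda(X, y, cfg)
        b0, b = penalized_logistic(X, y, lam, cfg)
        assert b[2] > 0.5

    def test_cv_1se_at_least_as_sparse_as_cv_min(self):
        X, rng = bernoulli_design(1500, 8, 0.3, 6)
        coefs = np.zeros(8)
        coefs[0] = 1.0
        y = logistic_outcome(X, -0.8, coefs, rng)
        lam_min = select_lambda(X, y, FitConfig(lambda_mode="cv_min", seed=6))
        lam_1se = select_lambda(X, y, FitConfig(lambda_mode="cv_1se", seed=6))
        assert lam_1se >= lam_min


class TestFitCLPN:
    def test_node_relabeling_equivariance(self):
        """Permuting item order permutes rows and columns of B identically."""
        spec = small_edge_spec(seed=7, edges={(0, 2): 0.8, (1, 3): -0.6})
        panel = simulate_panel(spec, 1500)
        cfg = FitConfig(lambda_mode="fixed", lambda_value=0.02)
        net = fit_clpn(panel, "w1", "w2", cfg)

        perm = [2, 0, 3, 1]
        cb_p = ItemCodebook(tuple(panel.items[i] for i in perm))
        panel_p = PanelDataset(
            panel.persons, panel.waves, panel.responses[:, perm, :], cb_p
        )
        net_p = fit_clpn(panel_p, "w1", "w2", cfg)
        np.testing.assert_allclose(net_p.B, net.B[np.ix_(perm, perm)], atol=1e-8)

    def test_independent_items_rarely_coupled(self):
        """Two items with zero true coupling: the fitted edges between them
        are shrunk to zero in at least 95% of seeded reruns."""
        zero_edges = 0
        total = 0
        for seed in range(20):
            spec = small_edge_spec(seed=200 + seed, edges={}, p=3)
            panel = simulate_panel(spec, 2000)
            net = fit_clpn(panel, "w1", "w2", FitConfig(seed=seed))
            cross = net.B[~np.eye(3, dtype=bool)]
            zero_edges += int(np.sum(cross == 0.0))
            total += cross.size
        assert zero_edges / total >= 0.95

    def test_missing_wave_data_rejected(self):
        spec = small_edge_spec(seed=8, edges={})
        panel = simulate_panel(spec, 100)
        panel.responses[0, 0, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_clpn(panel, "w1", "w2", FitConfig(lambda_mode="fixed", lambda_value=0.1))

    def test_shrinkage_monotone_in_fixed_lambda(self):
        spec = small_edge_spec(seed=9, edges={(0, 1): 0.7, (2, 3): 0.5})
        panel = simulate_panel(spec, 1200)
        norms = []
        for lam in (0.002, 0.01, 0.05, 0.2):
            net = fit_clpn(panel, "w1", "w2",
                           FitConfig(lambda_mode="fixed", lambda_value=lam,
                                     standardize_predictors=False))
            norms.append(np.abs(net.B).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_odds_ratio_view_closed_form():
    from clpnet.clpn import CLPNetwork

    B = np.zeros((2, 2))
    B[0, 1] = np.log(2.0)
    B[1, 0] = -0.1054
    net = CLPNetwork(("a", "b"), B, np.zeros(2), 10, None, ("w1", "w2"))
    OR = to_odds_ratios(net)
    assert OR[0, 0] == 1.0  # exp(0) exactly
    assert OR[0, 1] == pytest.approx(2.0, abs=1e-12)
    assert OR[1, 0] == pytest.approx(0.90, abs=1e-3)
    # invariant: OR == exp(B) elementwise to machine precision
    np.testing.assert_array_equal(OR, np.exp(B))
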