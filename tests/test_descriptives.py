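"""Descriptives: Bernoulli moments, endorsement, KR-20, paired t-tests."""

import numpy as np
import pytest

from clpnet.descriptives import (
    bernoulli_moments,
    describe_panel,
    endorsement,
    kr20_alpha,
    paired_ttest,
)
from clpnet.io import ItemCodebook, PanelDataset
from clpnet.synthetic import default_fixture_spec, simulate_panel


class TestBernoulliMoments:
    def test_symmetric_point(self):
        skew, kurt = bernoulli_moments(0.5)
        assert skew == pytest.approx(0.0, abs=1e-14)
        assert kurt == pytest.approx(-2.0, abs=1e-14)

    @pytest.mark.parametrize(
        "p, skew, kurt",
        [
            (0.1213, 2.32, 3.38),  # rare symptom
            (0.3646, 0.56, -1.68),  # common symptom
            (0.1990, 1.51, 0.27),
            (0.1957, 1.53, 0.35),
            (0.1971, 1.52, 0.32),
            (0.4771, 0.09, -1.99),  # near-balanced item
        ],
    )
    def test_closed_form_values(self, p, skew, kurt):
        s, k = bernoulli_moments(p)
        assert round(s, 2) == pytest.approx(skew)
        assert round(k, 2) == pytest.approx(kurt)

    def test_reflection_property(self):
        for p in (0.1, 0.27, 0.44):
            s1, k1 = bernoulli_moments(p)
            s2, k2 = bernoulli_moments(1 - p)
            assert s1 == pytest.approx(-s2, abs=1e-12)
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_monte_carlo_agreement(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        for p in (0.15, 0.5, 0.83):
            x = (rng.random(1_000_000) < p).astype(float)
            s, k = bernoulli_moments(p)
            assert stats.skew(x) == pytest.approx(s, abs=0.03)
            assert stats.kurtosis(x) == pytest.approx(k, abs=0.1)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.2])
    def test_degenerate_rejected(self, p):
        with pytest.raises(ValueError):
            bernoulli_moments(p)


class TestEndorsement:
    def _panel(self, col_a, col_b):
        cb = ItemCodebook(("a", "b"))
        resp = np.stack([col_a, col_b], axis=1)[:, :, None]
        persons = np.array([f"p{i}" for i in range(len(col_a))])
        return PanelDataset(persons, ("w1",), resp, cb)

    def test_all_zero_column(self):
        panel = self._panel([0, 0, 0], [1, 0, 1])
        tab = endorsement(panel)
        row = tab[(tab["item"] == "a")].iloc[0]
        assert row["n_endorsed"] == 0
        assert row["prop_endorsed"] == 0.0
        assert np.isnan(row["skewness"])

    def test_missing_denominator(self):
        panel = self._panel([1, 1, 0, np.nan], [0, 0, 0, 0])
        row = endorsement(panel)[lambda t: t["item"] == "a"].iloc[0]
        assert row["n_endorsed"] == 2
        assert row["n_observed"] == 3
        assert row["prop_endorsed"] == pytest.approx(2 / 3)

    def test_matches_brute_force_tally(self):
        panel = simulate_panel(default_fixture_spec(seed=2), 300)
        tab = endorsement(panel)
        for _, row in tab.iterrows():
            col = panel.values(row["item"], row["wave"])
            assert row["n_endorsed"] == int(np.nansum(col))
            assert row["n_observed"] == int((~np.isnan(col)).sum())

    def test_fixture_prevalences_recovered(self):
        spec = default_fixture_spec(seed=3)
        panel = simulate_panel(spec, 20_000)
        tab = endorsement(panel)
        w1 = tab[tab["wave"] == "w1"].set_index("item")
        for item, target in zip(panel.items, spec.wave1_prevalence):
            assert w1.loc[item, "prop_endorsed"] == pytest.approx(target, abs=0.015)


class TestKR20:
    def test_identical_columns_alpha_one(self):
        rng = np.random.default_rng(4)
        col = (rng.random(200) < 0.4).astype(float)
        X = np.stack([col] * 4, axis=1)
        assert kr20_alpha(X) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(5)
        X = (rng.random((10_000, 5)) < 0.3).astype(float)
        assert abs(kr20_alpha(X)) <= 0.05

    def test_matches_covariance_formula(self):
        """Tiny worked matrix against the generic Cronbach covariance form
        (k/(k-1)) * (1 - sum item variances / variance of total), with
        population variances on both sides."""
        X = np.array(
            [[1, 0, 1], [1, 1, 1], [0, 0, 1], [0, 0, 0]], dtype=float
        )
        k = 3
        item_var = X.var(axis=0, ddof=0).sum()  # equals sum p*q for 0/1 items
        total_var = X.sum(axis=1).var(ddof=0)
        cronbach = k / (k - 1) * (1 - item_var / total_var)
        pq = (X.mean(axis=0) * (1 - X.mean(axis=0))).sum()
        assert item_var == pytest.approx(pq, abs=1e-14)
        assert kr20_alpha(X) == pytest.approx(cronbach, abs=1e-12)

    def test_item_order_invariant(self):
        rng = np.random.default_rng(6)
        X = (rng.random((500, 4)) < [0.2, 0.4, 0.6, 0.3]).astype(float)
        assert kr20_alpha(X) == pytest.approx(kr20_alpha(X[:, ::-1]), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total-score variance"):
            kr20_alpha(np.ones((10, 3)))

    def test_incomplete_rows_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        X = (rng.random((100, 3)) < 0.5).astype(float)
        X[0, 0] = np.nan
        with pytest.warns(UserWarning, match="incomplete rows"):
            a = kr20_alpha(X)
        assert a == pytest.approx(kr20_alpha(X[1:]), abs=1e-12)


class TestPairedTTest:
    def test_hand_computed_example(self):
        """Differences of 1.0 with one 1.1 (n=10): t = dbar / (sd/sqrt(n))."""
        a = np.arange(10, dtype=float)
        d = np.full(10, 1.0)
        d[-1] = 1.1
        b = a - d
        t, p, df = paired_ttest(a, b)
        dbar, sd = d.mean(), d.std(ddof=1)
        assert t == pytest.approx(dbar / (sd / np.sqrt(10)), abs=1e-10)
        assert df == 9

    def test_symmetric_construction_t_near_zero(self):
        a = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0])
        b = a[::-1].copy()  # pairing reversed: mean difference exactly 0
        t, p, df = paired_ttest(a, b)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_simulated_shift_detected(self):
        """A -0.3 point shift at n=5000 is detected (p < .001, negative t
        when testing later-minus-earlier direction reversed)."""
        rng = np.random.default_rng(8)
        base = rng.poisson(2.0, size=5000).astype(float)
        later = base + 0.3 + rng.normal(0, 1.0, 5000)
        t, p, df = paired_ttest(base, later)
        assert p < 0.001
        assert t < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest(np.ones(5), np.zeros(5))


def test_describe_panel_structure():
    panel = simulate_panel(default_fixture_spec(seed=9), 4000)
    desc = describe_panel(panel)
    assert set(desc["alpha"]["w1"]) == {"full", "depressed_affect", "somatic"}
    # the generator draws wave-1 items independently (documented limitation),
    # so baseline alpha is near zero; later waves inherit cross-sectional
    # dependence from shared wave-1 predecessors and alpha rises
    assert abs(desc["alpha"]["w1"]["full"]) < 0.1
    assert desc["alpha"]["w4"]["full"] > desc["alpha"]["w1"]["full"] + 0.05
    assert len(desc["endorsement"]) == 8 * 4
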