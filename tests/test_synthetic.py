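"""Generator: transition law, intercept calibration, MAR missingness."""

import numpy as np
import pytest
from scipy.special import expit, logit

from clpnet.io import ItemCodebook
from clpnet.synthetic import (
    MissingnessModel,
    SyntheticSpec,
    apply_missingness,
    calibrate_intercepts,
    default_fixture_spec,
    simulate_panel,
)

from conftest import null_spec, small_edge_spec


def test_saturated_negative_intercepts_give_zero_waves():
    """With intercepts at -20 and no transitions, waves >= 2 are all zero."""
    cb = ItemCodebook(("a", "b", "c"))
    spec = SyntheticSpec(
        cb, 3, (0.5, 0.5, 0.5), (np.zeros((3, 3)),),
        intercepts=(np.full(3, -20.0),), seed=1,
    )
    panel = simulate_panel(spec, 200)
    assert np.all(panel.responses[:, :, 1:] == 0.0)


def test_zero_logit_gives_half_prevalence():
    """B=0, c=0 makes every wave-2 item a fair coin (n=10000, +/-0.02)."""
    cb = ItemCodebook(("a", "b"))
    spec = SyntheticSpec(cb, 2, (0.3, 0.7), (np.zeros((2, 2)),),
                         intercepts=(np.zeros(2),), seed=2)
    panel = simulate_panel(spec, 10_000)
    prev = panel.wave_matrix("w2").mean(axis=0)
    assert np.all(np.abs(prev - 0.5) < 0.02)


def test_single_edge_conditional_probabilities_match_sigmoid():
    """One cross-lagged edge b_12=1, c_2=-1: P(x2'=1|x1) follows the
    closed-form sigmoid at both predictor levels (n=20000, +/-0.02)."""
    cb = ItemCodebook(("a", "b"))
    B = np.zeros((2, 2))
    B[0, 1] = 1.0
    spec = SyntheticSpec(cb, 2, (0.5, 0.5), (B,),
                         intercepts=(np.array([0.0, -1.0]),), seed=3)
    panel = simulate_panel(spec, 20_000)
    x1 = panel.values("a", "w1")
    y2 = panel.values("b", "w2")
    assert y2[x1 == 1].mean() == pytest.approx(expit(0.0), abs=0.02)
    assert y2[x1 == 0].mean() == pytest.approx(expit(-1.0), abs=0.02)


def test_determinism_bit_identical():
    spec = default_fixture_spec(seed=42)
    a = simulate_panel(spec, 300)
    b = simulate_panel(default_fixture_spec(seed=42), 300)
    np.testing.assert_array_equal(a.responses, b.responses)
    assert list(a.aux["ethnicity"]) == list(b.aux["ethnicity"])


class TestCalibrateIntercepts:
    def test_no_coupling_closed_form(self):
        c = calibrate_intercepts(np.zeros((2, 2)), np.array([0.1213, 0.5]),
                                 np.array([0.3, 0.3]))
        assert c[0] == pytest.approx(logit(0.1213), abs=1e-3)
        assert c[1] == pytest.approx(0.0, abs=1e-6)

    def test_enumeration_matches_grid_search(self):
        """3-item enumeration solution agrees with a brute-force grid scan
        of the exact expectation to 1e-4."""
        B = np.zeros((3, 3))
        B[0, 1] = 0.8
        pred = np.array([0.4, 0.2, 0.6])
        target = np.array([0.3, 0.35, 0.25])
        c = calibrate_intercepts(B, target, pred)

        states = ((np.arange(8)[:, None] >> np.arange(3)) & 1).astype(float)
        w = np.prod(np.where(states == 1, pred, 1 - pred), axis=1)
        grid = np.linspace(-6, 6, 1_200_001)
        for j in range(3):
            s = states @ B[:, j]
            # expectation over predecessor states for each candidate intercept
            gap = np.abs([w @ expit(g + s) - target[j] for g in grid[::400]])
            coarse = grid[::400][int(np.argmin(gap))]
            assert c[j] == pytest.approx(coarse, abs=1e-2)
            exact = w @ expit(c[j] + s)
            assert exact == pytest.approx(target[j], abs=1e-4)

    def test_probability_bounds_checked(self):
        with pytest.raises(ValueError):
            calibrate_intercepts(np.zeros((2, 2)), np.array([0.0, 0.5]),
                                 np.array([0.5, 0.5]))

    def test_simulated_prevalence_matches_target(self):
        """Calibrated fixture intercepts keep later-wave prevalences near
        the wave-1 targets."""
        spec = default_fixture_spec(seed=5)
        panel = simulate_panel(spec, 20_000)
        target = np.asarray(spec.wave1_prevalence)
        for wave in panel.waves[1:]:
            prev = panel.wave_matrix(wave).mean(axis=0)
            assert np.all(np.abs(prev - target) < 0.03)


class TestMissingness:
    def test_all_negative_coefficients_no_missingness(self):
        spec = default_fixture_spec(seed=6)
        spec = SyntheticSpec(
            spec.codebook, spec.n_waves, spec.wave1_prevalence, spec.B,
            missing_model=MissingnessModel(intercept=-20.0),
            aux_model=spec.aux_model, seed=6,
        )
        panel = apply_missingness(simulate_panel(spec, 500), spec)
        assert not np.isnan(panel.responses).any()

    def test_zero_logit_half_missing(self):
        spec = null_spec(seed=7)
        spec = SyntheticSpec(
            spec.codebook, 2, spec.wave1_prevalence, spec.B,
            intercepts=spec.intercepts,
            missing_model=MissingnessModel(intercept=0.0), seed=7,
        )
        panel = apply_missingness(simulate_panel(spec, 10_000), spec)
        miss_rate = np.isnan(panel.responses[:, 0, 1]).mean()
        assert miss_rate == pytest.approx(0.5, abs=0.02)
        # wave 1 untouched
        assert not np.isnan(panel.responses[:, :, 0]).any()

    def test_severity_driven_dropout_is_monotone(self):
        """Positive sum-score coefficient: wave-1 high scorers drop out
        more often than low scorers."""
        spec = null_spec(seed=8)
        spec = SyntheticSpec(
            spec.codebook, 2, spec.wave1_prevalence, spec.B,
            intercepts=spec.intercepts,
            missing_model=MissingnessModel(intercept=-1.5, sum_score_coef=0.5),
            seed=8,
        )
        panel = apply_missingness(simulate_panel(spec, 10_000), spec)
        sums = panel.sum_scores("w1")
        gone = np.isnan(panel.responses[:, 0, 1])
        high = gone[sums >= 4].mean()
        low = gone[sums <= 1].mean()
        assert high > low

    def test_missingness_seeded_deterministic(self):
        spec = default_fixture_spec(seed=9)
        a = apply_missingness(simulate_panel(spec, 400), spec)
        b = apply_missingness(simulate_panel(spec, 400), spec)
        np.testing.assert_array_equal(a.responses, b.responses)
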