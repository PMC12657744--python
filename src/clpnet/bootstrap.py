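"""Bootstrap accuracy and stability for cross-lagged panel networks.

Three procedures, following common practice in the symptom-network
literature (bootnet-style):

* nonparametric bootstrap of persons with replacement, refitting the
  network per resample, for percentile confidence intervals around each
  edge weight;
* case-drop bootstrap: subsample decreasing fractions of persons without
  replacement and correlate subsample centrality with the full-sample
  centrality, summarized by the correlation-stability (CS) coefficient;
* edge-weight and centrality difference tests from the bootstrap draws
  (a difference is "significant" when the percentile interval of the
  bootstrap distribution of the difference excludes zero).

No multiple-testing correction is applied in the difference tests — the
usual convention in this literature; treat the tests as descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .centrality import expected_influence, expected_influence_arrays
from .clpn import CLPNetwork, FitConfig, fit_clpn
from .io import PanelDataset

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "StabilityResult",
    "DifferenceTest",
    "bootstrap_edges",
    "casedrop_stability",
    "edge_difference_test",
    "centrality_difference_test",
    "edge_difference_matrix",
    "centrality_difference_matrix",
]

logger = logging.getLogger(__name__)


def _default_drop_grid() -> tuple[float, ...]:
    return tuple(round(0.10 + 0.05 * k, 2) for k in range(14))  # 0.10 .. 0.75


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 1000
    ci_level: float = 0.95
    drop_proportions: tuple[float, ...] = field(default_factory=_default_drop_grid)
    cs_correlation_threshold: float = 0.70
    cs_quantile: float = 0.95
    seed: int = 0
    reselect_lambda: bool = True  # False freezes per-outcome penalties at full-sample values
    max_redraws: int = 10

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        props = tuple(self.drop_proportions)
        if np.any(np.diff(props) <= 0) or props[0] <= 0 or props[-1] >= 1:
            raise ValueError("drop_proportions must be strictly increasing within (0, 1)")


@dataclass
class BootstrapResult:
    """Edge-weight bootstrap draws and percentile CIs for one network."""

    items: tuple[str, ...]
    wave_pair: tuple[str, str]
    full_network: CLPNetwork
    edge_draws: np.ndarray  # (n_boot, p, p) log-odds
    ci_level: float

    def edge_ci(self, level: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        level = self.ci_level if level is None else level
        alpha = (1.0 - level) / 2.0
        lower = np.quantile(self.edge_draws, alpha, axis=0)
        upper = np.quantile(self.edge_draws, 1.0 - alpha, axis=0)
        return lower, upper

    def _edge_index(self, edge: tuple[str, str]) -> tuple[int, int]:
        src, dst = edge
        if src not in self.items or dst not in self.items:
            raise KeyError(f"unknown edge {edge!r}")
        return self.items.index(src), self.items.index(dst)

    def edge_draw_vector(self, edge: tuple[str, str]) -> np.ndarray:
        i, j = self._edge_index(edge)
        return self.edge_draws[:, i, j]

    def ei_draws(self, index: str, include_autoregressive: bool = False) -> np.ndarray:
        """(n_boot, p) expected-influence draws recomputed from edge draws."""
        out = np.empty((self.edge_draws.shape[0], len(self.items)))
        for b in range(self.edge_draws.shape[0]):
            out_ei, in_ei = expected_influence_arrays(
                self.edge_draws[b], include_autoregressive
            )
            out[b] = out_ei if index == "out" else in_ei
        return out


@dataclass
class StabilityResult:
    """Case-drop stability curves and CS-coefficients per EI index."""

    proportions: tuple[float, ...]
    correlations: dict[str, np.ndarray]  # index -> (n_props, n_boot), NaN where skipped
    cs_coefficient: dict[str, float]
    threshold: float
    quantile: float

    def mean_curve(self, index: str) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.correlations[index], axis=1)

    def quantile_curve(self, index: str) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanquantile(self.correlations[index], 1.0 - self.quantile, axis=1)


@dataclass(frozen=True)
class DifferenceTest:
    significant: bool
    lower: float
    upper: float
    level: float


def _fit_resample(panel, indices, wave_pair, fit_config, frozen_lambdas):
    sub = PanelDataset(
        np.array([f"r{i}" for i in range(len(indices))]),
        panel.waves,
        panel.responses[indices],
        panel.codebook,
        None if panel.aux is None else panel.aux.iloc[indices],
    )
    if frozen_lambdas is None:
        return fit_clpn(sub, wave_pair[0], wave_pair[1], fit_config)
    # frozen penalties: refit each outcome at the full-sample lambda
    from . import clpn as _clpn
    from .io import recode_reverse as _rr

    work = sub
    if fit_config.direction_convention == "recode_reverse_first" and sub.codebook.reverse_keyed:
        work = _rr(sub)
    X = work.wave_matrix(wave_pair[0])
    p = work.codebook.n_items
    B = np.zeros((p, p))
    intercepts = np.zeros(p)
    for j, item in enumerate(work.items):
        y = work.wave_matrix(wave_pair[1])[:, j]
        factor = _clpn._penalty_factor(p, fit_config, j)
        b0, b = _clpn.penalized_logistic(
            X, y, frozen_lambdas[item], fit_config, penalty_factor=factor
        )
        B[:, j] = b
        intercepts[j] = b0
    return CLPNetwork(work.items, B, intercepts, len(indices), dict(frozen_lambdas), wave_pair)


def _resample_indices(rng, n, panel, wave_pair, boot_config):
    """Bootstrap person indices whose wave-pair columns are all
    non-constant (predictors and outcomes); redraws (logged) up to
    max_redraws then errors."""
    t1 = panel.wave_index(wave_pair[1])
    t0 = panel.wave_index(wave_pair[0])
    for attempt in range(boot_config.max_redraws + 1):
        idx = rng.integers(0, n, size=n)
        cols = panel.responses[idx][:, :, [t0, t1]]
        if np.all(cols.min(axis=0) < cols.max(axis=0)):
            if attempt:
                logger.warning("bootstrap: resample accepted after %d redraws", attempt)
            return idx
    raise RuntimeError(
        f"constant outcome column in {boot_config.max_redraws} consecutive resamples"
    )


def bootstrap_edges(
    panel: PanelDataset,
    wave_pair: tuple[str, str],
    fit_config: FitConfig | None = None,
    boot_config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap (persons resampled with replacement) of all
    edge weights; percentile CIs at ``boot_config.ci_level``."""
    fit_config = fit_config or FitConfig()
    boot_config = boot_config or BootstrapConfig()
    if not panel.is_complete(list(wave_pair)):
        raise ValueError("bootstrap needs a complete panel for the wave pair")
    full = fit_clpn(panel, wave_pair[0], wave_pair[1], fit_config)
    frozen = None if boot_config.reselect_lambda else full.lambda_used

    rng = np.random.default_rng(np.random.SeedSequence([boot_config.seed, 101]))
    n = panel.n_persons
    p = full.n_items
    draws = np.empty((boot_config.n_boot, p, p))
    for b in range(boot_config.n_boot):
        idx = _resample_indices(rng, n, panel, wave_pair, boot_config)
        draws[b] = _fit_resample(panel, idx, wave_pair, fit_config, frozen).B
    return BootstrapResult(
        items=full.items,
        wave_pair=wave_pair,
        full_network=full,
        edge_draws=draws,
        ci_level=boot_config.ci_level,
    )


def casedrop_stability(
    panel: PanelDataset,
    wave_pair: tuple[str, str],
    fit_config: FitConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    indices: tuple[str, ...] = ("out", "in"),
) -> StabilityResult:
    """Case-drop bootstrap of expected-influence stability.

    For each drop proportion p, draws ``n_boot`` subsamples of
    ``(1-p) * N`` persons without replacement, refits, and correlates the
    subsample EI vector with the full-sample EI.  The CS-coefficient is
    the largest p such that the (1 - cs_quantile) quantile of the
    correlations is >= the threshold at p and at every smaller grid point.
    Proportions whose retained sample would fall below 10 x items are
    skipped with a warning.
    """
    fit_config = fit_config or FitConfig()
    boot_config = boot_config or BootstrapConfig()
    if not panel.is_complete(list(wave_pair)):
        raise ValueError("case-drop bootstrap needs a complete panel for the wave pair")
    full = fit_clpn(panel, wave_pair[0], wave_pair[1], fit_config)
    frozen = None if boot_config.reselect_lambda else full.lambda_used
    full_tab = expected_influence(full)
    full_ei = {ix: full_tab.raw(ix) for ix in indices}

    rng = np.random.default_rng(np.random.SeedSequence([boot_config.seed, 202]))
    n = panel.n_persons
    props = tuple(boot_config.drop_proportions)
    corr = {ix: np.full((len(props), boot_config.n_boot), np.nan) for ix in indices}
    for pi, prop in enumerate(props):
        keep_n = int(round((1.0 - prop) * n))
        if keep_n < 10 * full.n_items:
            logger.warning(
                "case-drop: skipping proportion %.2f (retained n=%d < %d)",
                prop, keep_n, 10 * full.n_items,
            )
            continue
        for b in range(boot_config.n_boot):
            idx = rng.choice(n, size=keep_n, replace=False)
            try:
                net = _fit_resample(panel, idx, wave_pair, fit_config, frozen)
            except ValueError:
                continue  # constant outcome in this subsample; leave NaN
            out_ei, in_ei = expected_influence_arrays(net.B)
            sub = {"out": out_ei, "in": in_ei}
            for ix in indices:
                a, bvec = full_ei[ix], sub[ix]
                if a.std() == 0 or bvec.std() == 0:
                    continue
                corr[ix][pi, b] = np.corrcoef(a, bvec)[0, 1]

    cs: dict[str, float] = {}
    for ix in indices:
        cs[ix] = 0.0
        with np.errstate(invalid="ignore"):
            qcurve = np.nanquantile(corr[ix], 1.0 - boot_config.cs_quantile, axis=1)
        for pi, prop in enumerate(props):
            if np.isnan(qcurve[pi]) or qcurve[pi] < boot_config.cs_correlation_threshold:
                break
            cs[ix] = prop
    return StabilityResult(
        proportions=props,
        correlations=corr,
        cs_coefficient=cs,
        threshold=boot_config.cs_correlation_threshold,
        quantile=boot_config.cs_quantile,
    )


def _percentile_test(draws: np.ndarray, level: float) -> DifferenceTest:
    alpha = (1.0 - level) / 2.0
    lower = float(np.quantile(draws, alpha))
    upper = float(np.quantile(draws, 1.0 - alpha))
    significant = bool(lower > 0.0 or upper < 0.0)
    return DifferenceTest(significant, lower, upper, level)


def edge_difference_test(
    result: BootstrapResult,
    edge_a: tuple[str, str],
    edge_b: tuple[str, str],
    ci_level: float | None = None,
) -> DifferenceTest:
    """Bootstrap difference test between two edge weights.

    Significant iff the percentile interval of the bootstrap distribution
    of (w_a - w_b) excludes zero.  An edge compared with itself has a
    degenerate distribution at 0 and is never significant.
    """
    level = result.ci_level if ci_level is None else ci_level
    diff = result.edge_draw_vector(edge_a) - result.edge_draw_vector(edge_b)
    return _percentile_test(diff, level)


def centrality_difference_test(
    result: BootstrapResult,
    item_a: str,
    item_b: str,
    index: str = "out",
    ci_level: float | None = None,
) -> DifferenceTest:
    """Bootstrap difference test between two items' expected influence."""
    for item in (item_a, item_b):
        if item not in result.items:
            raise KeyError(f"unknown item {item!r}")
    level = result.ci_level if ci_level is None else ci_level
    ei = result.ei_draws(index)
    ia, ib = result.items.index(item_a), result.items.index(item_b)
    return _percentile_test(ei[:, ia] - ei[:, ib], level)


def edge_difference_matrix(result: BootstrapResult, ci_level: float | None = None) -> np.ndarray:
    """Symmetric boolean matrix of pairwise edge difference tests over the
    cross-lagged edges (flattened row-major, diagonal excluded)."""
    p = len(result.items)
    edges = [(i, j) for i in range(p) for j in range(p) if i != j]
    level = result.ci_level if ci_level is None else ci_level
    m = len(edges)
    out = np.zeros((m, m), dtype=bool)
    draws = result.edge_draws
    for a in range(m):
        ia, ja = edges[a]
        for b in range(a + 1, m):
            ib, jb = edges[b]
            test = _percentile_test(draws[:, ia, ja] - draws[:, ib, jb], level)
            out[a, b] = out[b, a] = test.significant
    return out


def centrality_difference_matrix(
    result: BootstrapResult, index: str = "out", ci_level: float | None = None
) -> np.ndarray:
    """Symmetric boolean items x items matrix of EI difference tests."""
    level = result.ci_level if ci_level is None else ci_level
    ei = result.ei_draws(index)
    p = len(result.items)
    out = np.zeros((p, p), dtype=bool)
    for a in range(p):
        for b in range(a + 1, p):
            test = _percentile_test(ei[:, a] - ei[:, b], level)
            out[a, b] = out[b, a] = test.significant
    return out
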