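"""Cross-network comparison: edge counts, edge-list correlations, top edges.

All comparisons operate on the cross-lagged (off-diagonal) entries by
default, since the autoregressive self-paths answer a different question;
flags expose the alternative conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centrality import expected_influence, centrality_correlation
from .clpn import CLPNetwork

__all__ = ["NetworkComparison", "count_nonzero", "edge_correlation", "top_edges", "compare_networks"]


def count_nonzero(net: CLPNetwork, include_autoregressive: bool = False) -> int:
    """Number of non-zero edges (cross-lagged only unless flagged)."""
    if include_autoregressive:
        return int(np.count_nonzero(net.B))
    return int(np.count_nonzero(net.B[net.cross_lagged_mask()]))


def _edge_vectors(net1: CLPNetwork, net2: CLPNetwork, scale: str):
    if net1.items != net2.items:
        raise ValueError("networks must share the same item set and order")
    mask = net1.cross_lagged_mask()
    if scale == "log_odds":
        return net1.B[mask], net2.B[mask]
    if scale == "odds_ratio":
        return net1.odds_ratios[mask], net2.odds_ratios[mask]
    raise ValueError("scale must be 'log_odds' or 'odds_ratio'")


def edge_correlation(
    net1: CLPNetwork,
    net2: CLPNetwork,
    scale: str = "log_odds",
    include_zeros: bool = True,
) -> float:
    """Pearson r over the vectorized cross-lagged entries of two networks.

    ``include_zeros=False`` restricts to entries non-zero in at least one
    network (on the log-odds scale, "zero" means no edge in both views).
    """
    a, b = _edge_vectors(net1, net2, scale)
    if not include_zeros:
        la, lb = _edge_vectors(net1, net2, "log_odds")
        keep = (la != 0) | (lb != 0)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 jointly non-zero edges")
        a, b = a[keep], b[keep]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an edge vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def top_edges(net: CLPNetwork, k: int = 5) -> list[tuple[str, str, float, float]]:
    """The k strongest cross-lagged edges by |log-odds|.

    Returns (source, target, log_odds, odds_ratio) tuples, strongest first;
    ties broken by (source, target) lexicographic order.  Zero entries are
    never reported, so fewer than k rows may come back.
    """
    entries = []
    for i, src in enumerate(net.items):
        for j, dst in enumerate(net.items):
            if i != j and net.B[i, j] != 0.0:
                w = float(net.B[i, j])
                entries.append((src, dst, w, float(np.exp(w))))
    entries.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return entries[:k]


@dataclass
class NetworkComparison:
    labels: tuple[str, ...]
    nonzero_counts: dict[str, int]
    edge_correlations: dict[tuple[str, str], float]
    centrality_correlations: dict[str, dict[tuple[str, str], float]]
    top_edges: dict[str, list[tuple[str, str, float, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "nonzero_counts": self.nonzero_counts,
            "edge_correlations": {f"{a}|{b}": r for (a, b), r in self.edge_correlations.items()},
            "centrality_correlations": {
                index: {f"{a}|{b}": r for (a, b), r in pairs.items()}
                for index, pairs in self.centrality_correlations.items()
            },
            "top_edges": {
                label: [
                    {"source": s, "target": t, "log_odds": w, "odds_ratio": orr}
                    for s, t, w, orr in edges
                ]
                for label, edges in self.top_edges.items()
            },
        }


def compare_networks(
    nets: list[CLPNetwork],
    labels: list[str] | None = None,
    k_top: int = 5,
    include_autoregressive: bool = False,
) -> NetworkComparison:
    """Pairwise comparison of two or more fitted networks on one item set."""
    if len(nets) < 2:
        raise ValueError("need at least two networks to compare")
    if labels is None:
        labels = [f"{n.wave_pair[0]}->{n.wave_pair[1]}" for n in nets]
    tabs = [expected_influence(n) for n in nets]
    edge_corr = {}
    cent_corr: dict[str, dict[tuple[str, str], float]] = {"out": {}, "in": {}}
    for a in range(len(nets)):
        for b in range(a + 1, len(nets)):
            key = (labels[a], labels[b])
            edge_corr[key] = edge_correlation(nets[a], nets[b])
            for index in ("out", "in"):
                cent_corr[index][key] = centrality_correlation(tabs[a], tabs[b], index)
    return NetworkComparison(
        labels=tuple(labels),
        nonzero_counts={
            lab: count_nonzero(n, include_autoregressive) for lab, n in zip(labels, nets)
        },
        edge_correlations=edge_corr,
        centrality_correlations=cent_corr,
        top_edges={lab: top_edges(n, k_top) for lab, n in zip(labels, nets)},
    )
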