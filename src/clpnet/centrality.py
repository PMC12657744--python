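"""Expected-influence centrality for directed symptom networks.

Out-expected influence of an item is the sum of its outgoing log-odds edge
weights to all *other* items (how strongly it predicts the rest of the
network); in-expected influence is the sum of its incoming weights (how
strongly it is predicted).  Sums are taken on the log-odds scale so that
"no edge" (odds ratio 1) contributes exactly 0; z-standardized columns are
provided for cross-network display.  The autoregressive self-path is
excluded by default — self-prediction is not inter-symptom influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clpn import CLPNetwork

__all__ = ["CentralityTable", "expected_influence", "centrality_correlation"]


@dataclass
class CentralityTable:
    items: tuple[str, ...]
    out_ei_raw: np.ndarray
    in_ei_raw: np.ndarray
    out_ei_z: np.ndarray
    in_ei_z: np.ndarray
    out_degenerate: bool  # True when the raw out-EI vector had zero spread
    in_degenerate: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "out_ei_raw": self.out_ei_raw,
                "in_ei_raw": self.in_ei_raw,
                "out_ei_z": self.out_ei_z,
                "in_ei_z": self.in_ei_z,
            }
        )

    def raw(self, index: str) -> np.ndarray:
        if index == "out":
            return self.out_ei_raw
        if index == "in":
            return self.in_ei_raw
        raise ValueError("index must be 'in' or 'out'")


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x), True
    return (x - x.mean()) / sd, False


def expected_influence_arrays(
    B: np.ndarray, include_autoregressive: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(out_ei, in_ei) raw sums for a weight matrix (rows=source, cols=target)."""
    B = np.asarray(B, dtype=float)
    if include_autoregressive:
        return B.sum(axis=1), B.sum(axis=0)
    diag = np.diag(B)
    return B.sum(axis=1) - diag, B.sum(axis=0) - diag


def expected_influence(net: CLPNetwork, include_autoregressive: bool = False) -> CentralityTable:
    """In/out expected influence per item, raw (log-odds sums) and z-scored.

    When a raw vector has zero spread (e.g. an empty network) its z column
    is reported as all zeros and the corresponding degenerate flag is set.
    """
    out_raw, in_raw = expected_influence_arrays(net.B, include_autoregressive)
    out_z, out_deg = _zscore(out_raw)
    in_z, in_deg = _zscore(in_raw)
    return CentralityTable(net.items, out_raw, in_raw, out_z, in_z, out_deg, in_deg)


def centrality_correlation(tab1: CentralityTable, tab2: CentralityTable, index: str) -> float:
    """Pearson correlation of raw expected-influence vectors across networks."""
    if tab1.items != tab2.items:
        raise ValueError("centrality tables must share the same item set and order")
    a, b = tab1.raw(index), tab2.raw(index)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a centrality vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
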