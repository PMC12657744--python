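"""Panel-data containers and file I/O.

A :class:`PanelDataset` holds binary (0/1, or missing) item responses for N
persons over ordered waves, optional per-person auxiliary covariates, and an
:class:`ItemCodebook` describing the items (including which are
reverse-keyed, e.g. positively worded wellbeing items on a depression
screener).  Long CSV (person, wave, item, value) is the canonical on-disk
layout; wide CSV (one row per person, ``item_wave`` columns) is accepted for
convenience.  Fitted networks are exported as edge-list CSV or GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .clpn import CLPNetwork

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("", "NA", "N/A", "NaN", "nan", ".", "missing")


@dataclass(frozen=True)
class ItemCodebook:
    """Item identifiers, labels and reverse-keying flags for one scale."""

    items: tuple[str, ...]
    labels: dict[str, str] = field(default_factory=dict)
    reverse_keyed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.items) < 2:
            raise ValueError("codebook needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item ids must be unique")
        unknown = set(self.reverse_keyed) - set(self.items)
        if unknown:
            raise ValueError(f"reverse_keyed references unknown items: {sorted(unknown)}")
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "reverse_keyed", frozenset(self.reverse_keyed))

    @property
    def n_items(self) -> int:
        return len(self.items)

    def label(self, item: str) -> str:
        return self.labels.get(item, item)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ItemCodebook":
        raw = yaml.safe_load(Path(path).read_text())
        items = [entry["item_id"] for entry in raw["items"]]
        labels = {e["item_id"]: e.get("label", e["item_id"]) for e in raw["items"]}
        reverse = frozenset(e["item_id"] for e in raw["items"] if e.get("reverse_keyed", False))
        return cls(tuple(items), labels, reverse)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "items": [
                {
                    "item_id": it,
                    "label": self.label(it),
                    "reverse_keyed": it in self.reverse_keyed,
                }
                for it in self.items
            ]
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class PanelDataset:
    """N persons x items x waves of {0, 1, missing} responses.

    ``responses`` is a float array of shape ``(N, n_items, n_waves)`` with
    ``NaN`` marking missing cells.  ``aux`` (optional) is a person-indexed
    DataFrame of covariates (categorical or numeric).
    """

    persons: np.ndarray
    waves: tuple[str, ...]
    responses: np.ndarray
    codebook: ItemCodebook
    aux: pd.DataFrame | None = None

    def __post_init__(self):
        self.persons = np.asarray(self.persons)
        self.waves = tuple(str(w) for w in self.waves)
        self.responses = np.asarray(self.responses, dtype=float)
        n, k, w = self.responses.shape
        if n != len(self.persons):
            raise ValueError("responses row count != number of persons")
        if k != self.codebook.n_items:
            raise ValueError("responses item axis != codebook size")
        if w != len(self.waves):
            raise ValueError("responses wave axis != number of waves")
        if len(set(map(str, self.persons))) != n:
            raise ValueError("person ids must be unique")
        if len(set(self.waves)) != w:
            raise ValueError("wave labels must be unique")
        vals = self.responses[~np.isnan(self.responses)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0))])
            raise ValueError(f"responses must be 0, 1 or missing; found {bad}")
        if self.aux is not None and len(self.aux) != n:
            raise ValueError("aux covariates must cover every person")

    # -- basic views ---------------------------------------------------------
    @property
    def items(self) -> tuple[str, ...]:
        return self.codebook.items

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def wave_index(self, wave: str) -> int:
        try:
            return self.waves.index(str(wave))
        except ValueError:
            raise KeyError(f"unknown wave {wave!r}; have {self.waves}") from None

    def item_index(self, item: str) -> int:
        try:
            return self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}; have {self.items}") from None

    def values(self, item: str, wave: str) -> np.ndarray:
        return self.responses[:, self.item_index(item), self.wave_index(wave)]

    def wave_matrix(self, wave: str) -> np.ndarray:
        """(N, n_items) matrix of one wave's responses."""
        return self.responses[:, :, self.wave_index(wave)]

    def is_complete(self, waves: Sequence[str] | None = None) -> bool:
        if waves is None:
            return not np.isnan(self.responses).any()
        idx = [self.wave_index(w) for w in waves]
        return not np.isnan(self.responses[:, :, idx]).any()

    def sum_scores(self, wave: str) -> np.ndarray:
        """Per-person sum score for one wave (NaN if any item missing)."""
        return self.wave_matrix(wave).sum(axis=1)

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            self.persons.copy(),
            self.waves,
            self.responses.copy(),
            self.codebook,
            None if self.aux is None else self.aux.copy(),
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for pi, person in enumerate(self.persons):
            for wi, wave in enumerate(self.waves):
                for ii, item in enumerate(self.items):
                    rows.append((person, wave, item, self.responses[pi, ii, wi]))
        frame = pd.DataFrame(rows, columns=["person", "wave", "item", "value"])
        if self.aux is not None:
            frame = frame.merge(
                self.aux.reset_index().rename(columns={self.aux.index.name or "index": "person"}),
                on="person",
                how="left",
            )
        return frame


def recode_reverse(panel: PanelDataset) -> PanelDataset:
    """Flip reverse-keyed items (0 <-> 1) so all items point the same way.

    The returned codebook has its reverse flags cleared, which makes the
    operation idempotent at the API level; missing stays missing.
    """
    out = panel.copy()
    for item in panel.codebook.reverse_keyed:
        ii = panel.item_index(item)
        col = out.responses[:, ii, :]
        mask = ~np.isnan(col)
        col[mask] = 1.0 - col[mask]
    out.codebook = ItemCodebook(panel.codebook.items, dict(panel.codebook.labels), frozenset())
    return out


# ---------------------------------------------------------------------------
# panel CSV I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw, missing_tokens: tuple[str, ...]) -> tuple[float, bool]:
    """Return (value, unparseable_flag); missing encoded as NaN."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, False
    text = str(raw).strip()
    if text in missing_tokens:
        return np.nan, False
    try:
        value = float(text)
    except ValueError:
        return np.nan, True
    if value not in (0.0, 1.0):
        raise ValueError(f"response value {value!r} is not 0/1; refusing to coerce")
    return value, False


def read_panel(
    path: str | Path,
    layout: str,
    codebook: ItemCodebook,
    *,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    aux_cols: Sequence[str] | None = None,
) -> PanelDataset:
    """Read a panel CSV in ``long`` (person,wave,item,value) or ``wide``
    (one row per person, ``item_wave`` columns) layout.

    Unparseable non-numeric values become missing (count logged); numeric
    values other than 0/1 raise.  Extra columns are treated as per-person
    auxiliary covariates.
    """
    tokens = tuple(missing_tokens)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if layout == "long":
        return _panel_from_long(frame, codebook, tokens, aux_cols)
    if layout == "wide":
        return _panel_from_wide(frame, codebook, tokens, aux_cols)
    raise ValueError(f"unknown layout {layout!r}; use 'long' or 'wide'")


def _panel_from_long(frame, codebook, tokens, aux_cols):
    required = {"person", "wave", "item", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"long layout needs columns {sorted(required)}")
    unknown = set(frame["item"]) - set(codebook.items)
    if unknown:
        raise ValueError(f"unknown item ids in file: {sorted(unknown)}")
    dup = frame.duplicated(subset=["person", "wave", "item"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate person-wave-item cells")

    persons = frame["person"].drop_duplicates().to_numpy()
    waves = tuple(frame["wave"].drop_duplicates())
    p_idx = {p: i for i, p in enumerate(persons)}
    w_idx = {w: i for i, w in enumerate(waves)}
    i_idx = {it: i for i, it in enumerate(codebook.items)}

    responses = np.full((len(persons), codebook.n_items, len(waves)), np.nan)
    n_unparseable = 0
    for person, wave, item, raw in frame[["person", "wave", "item", "value"]].itertuples(index=False):
        value, bad = _parse_cell(raw, tokens)
        n_unparseable += bad
        responses[p_idx[person], i_idx[item], w_idx[wave]] = value
    if n_unparseable:
        logger.warning("read_panel: %d unparseable values set to missing", n_unparseable)

    aux = None
    extra = aux_cols if aux_cols is not None else [
        c for c in frame.columns if c not in ("person", "wave", "item", "value")
    ]
    if extra:
        aux = frame[["person", *extra]].drop_duplicates("person").set_index("person").loc[persons]
        aux.index.name = "person"
    return PanelDataset(persons, waves, responses, codebook, aux)


def _panel_from_wide(frame, codebook, tokens, aux_cols):
    if "person" not in frame.columns:
        raise ValueError("wide layout needs a 'person' column")
    persons = frame["person"].to_numpy()
    cell_cols: dict[str, tuple[str, str]] = {}
    waves: list[str] = []
    for col in frame.columns:
        if col == "person":
            continue
        for item in codebook.items:
            if col.startswith(item + "_"):
                wave = col[len(item) + 1:]
                cell_cols[col] = (item, wave)
                if wave not in waves:
                    waves.append(wave)
                break
    if not cell_cols:
        raise ValueError("no item_wave columns found for this codebook")

    responses = np.full((len(persons), codebook.n_items, len(waves)), np.nan)
    i_idx = {it: i for i, it in enumerate(codebook.items)}
    w_idx = {w: i for i, w in enumerate(waves)}
    n_unparseable = 0
    for col, (item, wave) in cell_cols.items():
        for pi, raw in enumerate(frame[col]):
            value, bad = _parse_cell(raw, tokens)
            n_unparseable += bad
            responses[pi, i_idx[item], w_idx[wave]] = value
    if n_unparseable:
        logger.warning("read_panel: %d unparseable values set to missing", n_unparseable)

    extra = aux_cols if aux_cols is not None else [
        c for c in frame.columns if c != "person" and c not in cell_cols
    ]
    aux = None
    if extra:
        aux = frame[["person", *extra]].set_index("person")
        aux.index.name = "person"
    return PanelDataset(persons, tuple(waves), responses, codebook, aux)


def write_panel(panel: PanelDataset, path: str | Path, layout: str = "long") -> None:
    """Write a panel CSV (long layout canonical; wide for convenience)."""
    path = Path(path)
    if layout == "long":
        frame = panel.to_long_frame()
        frame["value"] = frame["value"].map(lambda v: "" if np.isnan(v) else str(int(v)))
        frame.to_csv(path, index=False)
    elif layout == "wide":
        data = {"person": panel.persons}
        for wi, wave in enumerate(panel.waves):
            for ii, item in enumerate(panel.items):
                col = panel.responses[:, ii, wi]
                data[f"{item}_{wave}"] = ["" if np.isnan(v) else str(int(v)) for v in col]
        frame = pd.DataFrame(data)
        if panel.aux is not None:
            for name in panel.aux.columns:
                frame[name] = panel.aux[name].to_numpy()
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

def export_network(net: "CLPNetwork", path: str | Path, fmt: str = "edge_list_csv") -> None:
    """Write a fitted network as an edge-list CSV or GraphML file.

    The edge list contains only non-zero entries (columns: source, target,
    log_odds, odds_ratio, is_autoregressive); GraphML additionally stores
    every node with its intercept, so the full weight matrix round-trips.
    """
    path = Path(path)
    if fmt == "edge_list_csv":
        rows = []
        for i, src in enumerate(net.items):
            for j, dst in enumerate(net.items):
                w = net.B[i, j]
                if w != 0.0:
                    rows.append((src, dst, w, float(np.exp(w)), i == j))
        pd.DataFrame(
            rows, columns=["source", "target", "log_odds", "odds_ratio", "is_autoregressive"]
        ).to_csv(path, index=False)
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        g.graph["wave_t"], g.graph["wave_t1"] = net.wave_pair
        g.graph["n_fit"] = int(net.n_fit)
        for j, item in enumerate(net.items):
            g.add_node(item, intercept=float(net.intercepts[j]), order=j)
        for i, src in enumerate(net.items):
            for j, dst in enumerate(net.items):
                w = net.B[i, j]
                if w != 0.0:
                    g.add_edge(
                        src,
                        dst,
                        log_odds=float(w),
                        odds_ratio=float(np.exp(w)),
                        is_autoregressive=bool(i == j),
                    )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "graphml", items: Sequence[str] | None = None):
    """Read a network written by :func:`export_network`.

    GraphML is self-contained; the edge-list CSV omits isolated nodes and
    intercepts, so ``items`` must be supplied for that format.
    """
    from .clpn import CLPNetwork

    path = Path(path)
    if fmt == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = sorted(g.nodes, key=lambda n: g.nodes[n].get("order", 0))
        idx = {n: i for i, n in enumerate(nodes)}
        B = np.zeros((len(nodes), len(nodes)))
        for src, dst, data in g.edges(data=True):
            B[idx[src], idx[dst]] = float(data["log_odds"])
        intercepts = np.array([float(g.nodes[n].get("intercept", 0.0)) for n in nodes])
        return CLPNetwork(
            items=tuple(nodes),
            B=B,
            intercepts=intercepts,
            n_fit=int(g.graph.get("n_fit", 0)),
            lambda_used=None,
            wave_pair=(str(g.graph.get("wave_t", "t")), str(g.graph.get("wave_t1", "t1"))),
        )
    if fmt == "edge_list_csv":
        if items is None:
            raise ValueError("edge_list_csv import needs the item list")
        frame = pd.read_csv(path)
        items = tuple(items)
        idx = {it: i for i, it in enumerate(items)}
        B = np.zeros((len(items), len(items)))
        for row in frame.itertuples(index=False):
            B[idx[row.source], idx[row.target]] = float(row.log_odds)
        return CLPNetwork(
            items=items,
            B=B,
            intercepts=np.zeros(len(items)),
            n_fit=0,
            lambda_used=None,
            wave_pair=("t", "t1"),
        )
    raise ValueError(f"unknown network format {fmt!r}")
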