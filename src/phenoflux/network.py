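"""Trait-photophysiology correlation network.

Fragment-level metric cubes are averaged to colony level (the replication
unit), every (photophysiological metric, cellular trait) pair is scored
with a Pearson correlation across colonies, and pairs with |r| above a
threshold (default 0.6) become signed edges of a bipartite network. The
network is exported as GraphML or a delimited edge list; no multiplicity
correction is applied to the correlation family, matching the screening
character of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TraitNetwork",
    "average_replicates",
    "correlate_traits",
    "export_graph",
    "load_graphml",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6


def average_replicates(
    wide: pd.DataFrame, colony_map: pd.Series
) -> pd.DataFrame:
    """Average fragment rows to colony level (missing-aware mean).

    ``wide`` is a samples x columns table; ``colony_map`` maps sample id to
    colony id. Every sample must have a colony.
    """
    colonies = colony_map.reindex(wide.index)
    if colonies.isna().any():
        unknown = list(wide.index[colonies.isna()])
        raise ValueError(f"fragments with unknown colony: {unknown}")
    return wide.groupby(colonies.values).mean()


@dataclass
class TraitNetwork:
    """Thresholded signed correlation network between traits and metrics."""

    edges: pd.DataFrame  # trait, metric, r, sign, n
    threshold: float
    traits: list[str] = field(default_factory=list)
    metrics: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def summary(self) -> pd.DataFrame:
        """Edge counts and sign split per cellular trait."""
        if self.edges.empty:
            return pd.DataFrame(columns=["trait", "n_edges", "n_positive", "n_negative"])
        g = self.edges.groupby("trait")
        return pd.DataFrame({
            "n_edges": g.size(),
            "n_positive": g.apply(lambda d: int((d["sign"] > 0).sum()), include_groups=False),
            "n_negative": g.apply(lambda d: int((d["sign"] < 0).sum()), include_groups=False),
        }).reset_index(names="trait")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold)
        for t in self.traits:
            g.add_node(t, kind="trait")
        for m in self.metrics:
            if (self.edges["metric"] == m).any():
                g.add_node(m, kind="metric", family=m.split("_")[0])
        for e in self.edges.itertuples():
            g.add_edge(e.trait, e.metric, r=float(e.r), sign=int(e.sign), n=int(e.n))
        return g


def correlate_traits(
    colony_metrics: pd.DataFrame,
    colony_traits: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> TraitNetwork:
    """Pearson-correlate every (metric, trait) pair across colonies.

    Both tables are indexed by colony id; only colonies present in both are
    used (>= 5 required). Pairs with |r| strictly above ``threshold`` become
    edges carrying the correlation, its sign and the number of colonies n.
    Zero-variance columns are skipped and logged.
    """
    common = colony_metrics.index.intersection(colony_traits.index)
    if len(common) < 5:
        raise ValueError(f"need >= 5 colonies with both tables, got {len(common)}")
    M = colony_metrics.loc[common]
    T = colony_traits.loc[common]

    rows = []
    t_arr = {c: T[c].to_numpy(dtype=float) for c in T.columns}
    for mcol in M.columns:
        x = M[mcol].to_numpy(dtype=float)
        for tcol in T.columns:
            y = t_arr[tcol]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                continue
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                logger.info("skipping zero-variance pair (%s, %s)", mcol, tcol)
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            if abs(r) > threshold:
                rows.append({"trait": tcol, "metric": mcol, "r": r,
                             "sign": 1 if r > 0 else -1, "n": n})
    edges = pd.DataFrame(rows, columns=["trait", "metric", "r", "sign", "n"])
    return TraitNetwork(edges=edges, threshold=threshold,
                        traits=list(T.columns), metrics=list(M.columns))


def export_graph(
    network: TraitNetwork,
    path: str | Path,
    fmt: str = "graphml",
    allow_empty: bool = False,
) -> Path:
    """Write the network as GraphML or a delimited edge list (byte-stable)."""
    if len(network) == 0 and not allow_empty:
        raise ValueError("refusing to export an empty network (pass allow_empty=True)")
    path = Path(path)
    if fmt == "graphml":
        g = network.to_graph()
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "edgelist":
        network.edges.sort_values(["trait", "metric"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'graphml' or 'edgelist')")
    return path


def load_graphml(path: str | Path) -> TraitNetwork:
    """Round-trip loader for GraphML exports."""
    g = nx.read_graphml(path)
    traits = sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "trait")
    metrics = sorted(n for n, d in g.nodes(data=True) if d.get("kind") == "metric")
    rows = []
    for u, v, d in g.edges(data=True):
        trait, metric = (u, v) if u in traits else (v, u)
        rows.append({"trait": trait, "metric": metric, "r": float(d["r"]),
                     "sign": int(d["sign"]), "n": int(d["n"])})
    edges = pd.DataFrame(rows, columns=["trait", "metric", "r", "sign", "n"])
    return TraitNetwork(edges=edges, threshold=float(g.graph.get("threshold", np.nan)),
                        traits=traits, metrics=metrics)
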