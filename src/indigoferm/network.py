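"""Spearman co-occurrence networks over genus abundance trajectories.

Genera whose relative abundances co-vary over the fermentation are
connected by signed edges: Spearman's rank correlation rs over the
day-ordered series, retained when |rs| exceeds a threshold (0.6) and
the two-sided p-value passes alpha (0.05). Fermentation series are
short (8-15 points), where the usual t-approximation to Spearman's null
is poor, so for n <= 8 the p-value is computed exactly by enumerating
all rank permutations. Ties receive average ranks and rs is Pearson's
correlation of the ranks, which remains correct under ties.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .tables_io import genus_of

#: Largest series length for which the exact permutation p-value is used.
EXACT_MAX_N = 8


def build_trajectories(rel: pd.DataFrame, taxonomy: dict[str, str],
                       metadata: pd.DataFrame,
                       average_replicates: bool = False) -> pd.DataFrame:
    """Aggregate taxa to genus and order samples by fermentation day.

    Replicates of a day are kept as separate ordered points by default
    (more points for rank correlation); with ``average_replicates`` they
    are collapsed to the day mean.
    """
    genera = pd.Index([genus_of(taxonomy.get(t, str(t))) for t in rel.index])
    traj = rel.groupby(genera.values).sum()
    days = metadata["day"].reindex(rel.columns)
    if days.isna().any():
        missing = days.index[days.isna()][0]
        raise InputError(f"no metadata day for sample {missing!r}")
    order = days.sort_values(kind="stable").index
    traj = traj[order]
    if average_replicates:
        traj = traj.T.groupby(days.loc[order].values).mean().T
        traj.columns = [f"day{d}" for d in traj.columns]
    if traj.shape[1] < 3:
        raise InputError("need at least 3 ordered sampling points")
    traj.index.name = "genus"
    return traj


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    """All n! orderings of positions 0..n-1, as one int array."""
    return np.array(list(permutations(range(n))), dtype=np.int64)


def spearman_rs(x, y) -> float:
    """Spearman's rs: Pearson correlation of average ranks."""
    xr = stats.rankdata(np.asarray(x, dtype=float))
    yr = stats.rankdata(np.asarray(y, dtype=float))
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def spearman_edge(x, y, exact_max_n: int = EXACT_MAX_N) -> tuple[float, float]:
    """(rs, two-sided p) for one pair of series.

    Exact p by full enumeration of rank permutations for n <= ``exact_max_n``
    (conditional on both observed tie patterns); t-approximation beyond.
    Zero-variance input gives (nan, nan): no edge can be formed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("series must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise InputError("need at least 3 points")
    rs = spearman_rs(x, y)
    if np.isnan(rs):
        return rs, float("nan")
    if n <= exact_max_n:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        perms = _rank_permutations(n)
        yp = yr[perms]  # (n!, n) permuted rank vectors
        xc = xr - xr.mean()
        ypc = yp - yp.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc ** 2).sum() * (ypc ** 2).sum(axis=1))
        rs_null = (ypc @ xc) / denom
        p = float(np.mean(np.abs(rs_null) >= abs(rs) - 1e-12))
    else:
        t = rs * np.sqrt((n - 2) / max(1e-300, 1.0 - rs ** 2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rs, p


def build_network(traj: pd.DataFrame, rs_threshold: float = 0.6,
                  alpha: float = 0.05,
                  exact_max_n: int = EXACT_MAX_N) -> nx.Graph:
    """Signed co-occurrence network over a trajectory matrix.

    Nodes carry ``weight`` = accumulated relative abundance over the
    period; edges (|rs| > rs_threshold and p < alpha) carry ``rs``,
    ``p`` and ``sign``.
    """
    graph = nx.Graph()
    for genus, series in traj.iterrows():
        graph.add_node(genus, weight=float(series.sum()))
    genera = list(traj.index)
    values = traj.to_numpy(dtype=float)
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            rs, p = spearman_edge(values[i], values[j], exact_max_n)
            if np.isnan(rs) or np.isnan(p):
                continue
            if abs(rs) > rs_threshold and p < alpha:
                graph.add_edge(genera[i], genera[j], rs=rs, p=p,
                               sign="positive" if rs > 0 else "negative")
    return graph


def components(graph: nx.Graph) -> list[nx.Graph]:
    """Connected components as subgraphs, largest first."""
    comps = [graph.subgraph(c).copy() for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda g: (-g.number_of_nodes(), sorted(g.nodes)[0]))


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Deterministically ordered edge list (genus_a, genus_b, rs, p, sign)."""
    rows = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((a, b))
        rows.append({"genus_a": a, "genus_b": b, "rs": data["rs"],
                     "p": data["p"], "sign": data["sign"]})
    out = pd.DataFrame(rows, columns=["genus_a", "genus_b", "rs", "p", "sign"])
    return out.sort_values(["genus_a", "genus_b"]).reset_index(drop=True)


def node_table(graph: nx.Graph) -> pd.DataFrame:
    rows = [{"genus": n, "accumulated_abundance": d.get("weight", float("nan"))}
            for n, d in graph.nodes(data=True)]
    return pd.DataFrame(rows).sort_values("genus").reset_index(drop=True)


def write_network(graph: nx.Graph, edge_path, node_path=None,
                  graphml_path=None) -> None:
    edge_table(graph).to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        node_table(graph).to_csv(node_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
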