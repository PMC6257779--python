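"""Graph-statistics panel for regulatory networks.

The panel follows common practice for sparse directed biological networks:

* path-based statistics (diameter ``Dia``, average path length ``l``,
  global efficiency ``E``, betweenness ``B_v``, maximum vulnerability
  ``Vu``) are computed on the **directed** graph;
* triplet/centralization statistics (clustering coefficient ``CC``,
  Freeman degree centralization ``Ce``) are computed on the **undirected
  projection**, since their defining formulas are undirected constructs.

Sparse regulatory graphs are rarely strongly connected, so unreachable
ordered pairs are excluded from the average path length and contribute
zero to global efficiency (1/infinity = 0); this is what keeps both finite
on an 800-gene network with hundreds of isolated genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import InsufficientDataError, ParameterError
from .network import RegulatoryNetwork

__all__ = [
    "StatsRow",
    "DegreeHistogram",
    "PowerLawFit",
    "degree_metrics",
    "path_metrics",
    "betweenness",
    "clustering_coefficient",
    "centralization",
    "max_vulnerability",
    "network_summary",
    "fit_power_law",
]

#: Column order used for stats tables (CC and N0 appended to the classic panel).
STATS_COLUMNS = ("K", "Dia", "l", "Ce", "Rn", "E", "Vu", "CC", "N0")


@dataclass(frozen=True)
class StatsRow:
    """One network's statistics panel.

    K: average total degree (2 Rn / N); Dia: diameter; l: average shortest
    path length over reachable ordered pairs; N0: isolated genes; Rn: edge
    count; E: global efficiency; Vu: maximum vulnerability; CC: clustering
    coefficient (transitivity); Ce: degree centralization.
    """

    label: str
    K: float
    Dia: float
    l: float
    N0: int
    Rn: int
    E: float
    Vu: float
    CC: float
    Ce: float

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in STATS_COLUMNS}


@dataclass(frozen=True)
class DegreeHistogram:
    """degree -> node-count maps for total, in- and out-degree."""

    total: Mapping[int, int]
    indeg: Mapping[int, int]
    outdeg: Mapping[int, int]


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares line on (log10 degree, log10 count)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def _counts(values: list[int]) -> dict[int, int]:
    out: dict[int, int] = {}
    for v in values:
        out[v] = out.get(v, 0) + 1
    return out


def degree_metrics(net: RegulatoryNetwork) -> dict:
    """Per-node degrees plus the degree-level panel entries K, N0, Rn.

    Total degree is indegree + outdegree, so K = 2 Rn / N exactly.
    """
    if net.n_genes == 0:
        raise ParameterError("network has an empty gene panel")
    indeg = {g: 0 for g in net.gene_ids}
    outdeg = {g: 0 for g in net.gene_ids}
    for pred, tgt in net.edges:
        outdeg[pred] += 1
        indeg[tgt] += 1
    total = {g: indeg[g] + outdeg[g] for g in net.gene_ids}
    n = net.n_genes
    hist = DegreeHistogram(
        _counts(list(total.values())),
        _counts(list(indeg.values())),
        _counts(list(outdeg.values())),
    )
    return {
        "indegree": indeg,
        "outdegree": outdeg,
        "degree": total,
        "K": sum(total.values()) / n,
        "N0": sum(1 for d in total.values() if d == 0),
        "Rn": net.n_edges,
        "histogram": hist,
    }


def _directed_distances(g: nx.DiGraph) -> list[int]:
    """Finite shortest-path lengths over ordered pairs i != j (BFS per source)."""
    out: list[int] = []
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        out.extend(d for tgt, d in lengths.items() if tgt != src)
    return out


def path_metrics(net: RegulatoryNetwork) -> dict:
    """Diameter, average path length and global efficiency (directed).

    ``Dia`` and ``l`` use finite distances only; ``E`` averages inverse
    distances over *all* ordered pairs with unreachable pairs counting 0.
    A network with no finite paths reports Dia = l = 0 and is flagged
    ``path_metrics_defined = False``.
    """
    g = net.to_digraph()
    n = g.number_of_nodes()
    dists = _directed_distances(g)
    if not dists or n < 2:
        return {"Dia": 0.0, "l": 0.0, "E": 0.0, "path_metrics_defined": False}
    inv_sum = float(np.sum(1.0 / np.asarray(dists, dtype=float)))
    return {
        "Dia": float(max(dists)),
        "l": float(np.mean(dists)),
        "E": inv_sum / (n * (n - 1)),
        "path_metrics_defined": True,
    }


def betweenness(net: RegulatoryNetwork) -> dict[str, float]:
    """Unnormalized directed betweenness: sum over ordered pairs i != v != j
    of the fraction of i -> j geodesics passing through v."""
    return dict(nx.betweenness_centrality(net.to_digraph(), normalized=False))


def clustering_coefficient(net: RegulatoryNetwork) -> float:
    """Transitivity of the undirected projection: 3 triangles / connected triples."""
    und = net.to_digraph().to_undirected()
    return float(nx.transitivity(und))


def centralization(net: RegulatoryNetwork) -> float:
    """Freeman degree centralization on the undirected projection.

    Ce = sum_v (d_max - d_v) / ((N - 1)(N - 2)); the star attains 1, any
    regular graph 0.  Undefined below N = 3 (returns 0).
    """
    n = net.n_genes
    if n < 3:
        return 0.0
    degrees = [d for _, d in net.to_digraph().to_undirected().degree()]
    d_max = max(degrees)
    return float(sum(d_max - d for d in degrees) / ((n - 1) * (n - 2)))


def _efficiency(g: nx.DiGraph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    dists = _directed_distances(g)
    if not dists:
        return 0.0
    return float(np.sum(1.0 / np.asarray(dists, dtype=float))) / (n * (n - 1))


def max_vulnerability(net: RegulatoryNetwork) -> float:
    """Largest relative efficiency loss from deleting one node.

    Vu = max_i (E - E_i) / E where E_i is the efficiency after removing
    node i and its incident edges.  Zero when the network has no finite
    paths at all (E = 0).
    """
    if net.n_genes < 2:
        raise ParameterError("vulnerability needs at least 2 nodes")
    g = net.to_digraph()
    e_full = _efficiency(g)
    if e_full == 0.0:
        return 0.0
    worst = -np.inf
    for node in net.gene_ids:
        h = g.copy()
        h.remove_node(node)
        worst = max(worst, (e_full - _efficiency(h)) / e_full)
    return float(worst)


def network_summary(net: RegulatoryNetwork, label: str = "") -> StatsRow:
    """Assemble the full panel for one network."""
    deg = degree_metrics(net)
    paths = path_metrics(net)
    return StatsRow(
        label=label,
        K=deg["K"],
        Dia=paths["Dia"],
        l=paths["l"],
        N0=deg["N0"],
        Rn=deg["Rn"],
        E=paths["E"],
        Vu=max_vulnerability(net) if net.n_genes >= 2 else 0.0,
        CC=clustering_coefficient(net),
        Ce=centralization(net),
    )


def fit_power_law(hist: DegreeHistogram | Mapping[int, int]) -> PowerLawFit:
    """Log-log least-squares fit to a degree histogram.

    Fits ``log10 count = slope * log10 degree + intercept`` over degrees
    >= 1 with positive counts (degree-0 nodes have no log-degree and are
    excluded).  ``r_squared`` is the coefficient of determination of that
    line — the goodness-of-fit figure used to compare how scale-free-like
    different networks are.
    """
    counts = hist.total if isinstance(hist, DegreeHistogram) else hist
    pts = sorted((d, c) for d, c in counts.items() if d >= 1 and c >= 1)
    if len(pts) < 2:
        raise InsufficientDataError(
            "power-law fit needs at least 2 distinct positive degrees"
        )
    x = np.log10([d for d, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(float(slope), float(intercept), float(r2), len(pts))
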