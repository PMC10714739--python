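"""Complexity, topology and trophic-structure metrics of a food web.

Complexity: species count S, links L, linkage density LD = L/S, and
directed connectance C = L/S^2. Topology: mean local clustering (CC),
characteristic path length (CPL) and Newman modularity (Mod), all on the
symmetrized graph since neighbourhood structure has no trophic direction.
Trophic structure: prey-averaged trophic levels solved as a linear system
(so feeding loops are handled), mean TL, and the omnivory fraction — the
share of species feeding at more than one trophic level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import networkx as nx
import numpy as np

from .io import FoodWeb

__all__ = [
    "ComplexityMetrics",
    "complexity",
    "clustering_coefficient",
    "characteristic_path_length",
    "trophic_levels",
    "omnivory",
    "modularity",
    "degree_stats",
    "WebMetrics",
    "compute_all",
]


class ComplexityMetrics(NamedTuple):
    S: int
    L: int
    LD: float
    C: float


def complexity(web: FoodWeb) -> ComplexityMetrics:
    """(S, L, LD, C) with LD = L/S and directed connectance C = L/S**2."""
    S, L = web.S, web.L
    if S == 0:
        raise ValueError("complexity undefined for an empty web")
    return ComplexityMetrics(S, L, L / S, L / S**2)


def clustering_coefficient(web: FoodWeb) -> float:
    """Mean local clustering on the symmetrized graph.

    Nodes of degree < 2 contribute 0 to the mean (they close no triangle).
    """
    if web.S < 1:
        raise ValueError("clustering undefined for an empty web")
    return float(nx.average_clustering(web.to_undirected(), count_zeros=True))


def characteristic_path_length(web: FoodWeb):
    """Mean shortest-path length over reachable unordered pairs.

    Works on the symmetrized graph. Pairs in different components are
    excluded from the mean; their count is returned alongside. Raises if
    no pair is reachable at all.
    """
    if web.S < 2:
        raise ValueError("path length needs at least two nodes")
    G = web.to_undirected()
    total, n_pairs = 0.0, 0
    for comp in nx.connected_components(G):
        k = len(comp)
        if k < 2:
            continue
        sub = G.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        n_pairs += k * (k - 1) // 2
    if n_pairs == 0:
        raise ValueError("no reachable pair of nodes")
    all_pairs = web.S * (web.S - 1) // 2
    cpl = total / (2 * n_pairs)  # each unordered pair counted twice above
    return cpl, all_pairs - n_pairs


def _prey_average_matrix(web: FoodWeb) -> np.ndarray:
    """Row-stochastic diet matrix W with W[j, i] = 1/n_prey(j) for prey i."""
    A = web.adjacency.astype(float)
    n_prey = A.sum(axis=0)
    W = np.zeros_like(A)
    consumers = n_prey > 0
    # a[i, j]=1 means j eats i: node j's diet is column j
    W[:, consumers] = A[:, consumers] / n_prey[consumers]
    return W.T  # W[j, i]: weight of prey i in j's diet


def trophic_levels(web: FoodWeb, on_singular: str = "error"):
    """Prey-averaged trophic levels and their mean.

    Basal nodes (no prey) sit at TL 1; a consumer sits one level above the
    mean of its prey: ``TL_j = 1 + mean_i in diet(j) TL_i``. Solved as the
    linear system ``(I - W) TL = 1`` so feeding loops are handled exactly.

    A consumer cycle with no path down to a basal resource makes the
    system singular. With ``on_singular="error"`` (default) the offending
    nodes are named; ``"lstsq"`` returns the minimum-norm least-squares
    solution instead (used inside randomization ensembles, where degree-
    preserving shuffles occasionally produce such cycles).
    """
    S = web.S
    if S == 0:
        return np.zeros(0), float("nan")
    W = _prey_average_matrix(web)
    M = np.eye(S) - W
    b = np.ones(S)
    try:
        tl = np.linalg.solve(M, b)
        ok = np.isfinite(tl).all()
    except np.linalg.LinAlgError:
        ok = False
        tl = None
    if not ok or np.abs(M @ tl - b).max() > 1e-6:
        if on_singular == "lstsq":
            tl, *_ = np.linalg.lstsq(M, b, rcond=None)
        else:
            bad = _nodes_without_basal_support(web)
            raise ValueError(
                "trophic levels undefined: consumer loop with no basal "
                f"input involving nodes {sorted(bad)}"
            )
    return tl, float(tl.mean())


def _nodes_without_basal_support(web: FoodWeb) -> set:
    """Ids of nodes from which no basal resource is reachable via prey links."""
    # the system is solvable iff every node can be reached from some basal
    # resource walking prey -> predator arcs; report the unreachable ones
    A = web.adjacency
    supported = set(np.flatnonzero(web.basal_mask()))
    frontier = list(supported)
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(A[i, :]):  # predators of i
            if j not in supported:
                supported.add(int(j))
                frontier.append(int(j))
    return {web.nodes[j].node_id for j in range(web.S) if j not in supported}


def omnivory(
    web: FoodWeb,
    denominator: str = "all",
    tol: float = 1e-9,
    tl: Optional[np.ndarray] = None,
    on_singular: str = "error",
) -> float:
    """Fraction of species feeding at more than one trophic level.

    A node is omnivorous when it has at least two prey whose trophic
    levels differ by more than ``tol``. ``denominator="all"`` divides by
    S (percentage-of-omnivory convention); ``"consumers"`` divides by the
    number of consumers only.
    """
    if denominator not in ("all", "consumers"):
        raise ValueError("denominator must be 'all' or 'consumers'")
    if tl is None:
        tl, _ = trophic_levels(web, on_singular=on_singular)
    A = web.adjacency
    n_omni = 0
    n_consumers = 0
    for j in range(web.S):
        prey = np.flatnonzero(A[:, j])
        if len(prey) == 0:
            continue
        n_consumers += 1
        if len(prey) >= 2 and np.ptp(tl[prey]) > tol:
            n_omni += 1
    if denominator == "all":
        return n_omni / web.S if web.S else 0.0
    return n_omni / n_consumers if n_consumers else 0.0


def modularity(web: FoodWeb):
    """Newman modularity Q of a greedy agglomerative partition.

    Clauset–Newman–Moore greedy merging on the symmetrized graph; the
    procedure is deterministic for a fixed node order, so repeated calls
    return the same Q and partition. An edgeless web gets the singleton
    partition with Q = 0.
    """
    if web.S < 2:
        raise ValueError("modularity needs at least two nodes")
    G = web.to_undirected()
    if G.number_of_edges() == 0:
        return 0.0, [{n} for n in web.node_ids]
    communities = nx.community.greedy_modularity_communities(G)
    communities = [set(c) for c in communities]
    q = nx.community.modularity(G, communities)
    return float(q), communities


@dataclass
class DegreeStats:
    node_ids: list
    n_prey: np.ndarray
    n_predators: np.ndarray
    total_degree: np.ndarray
    AD: float


def degree_stats(web: FoodWeb) -> DegreeStats:
    """Per-node prey/predator/total degrees and the average degree AD = 2L/S."""
    if web.S < 1:
        raise ValueError("degree stats undefined for an empty web")
    k_prey = web.n_prey()
    k_pred = web.n_predators()
    total = k_prey + k_pred
    return DegreeStats(web.node_ids, k_prey, k_pred, total, float(total.mean()))


@dataclass
class WebMetrics:
    """One web's complexity / topology / structure numbers."""

    label: str
    S: int
    L: int
    LD: float
    C: float
    CC: float
    CPL: float
    CPL_excluded_pairs: int
    Mod: float
    TL: np.ndarray
    meanTL: float
    O: float

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "S": self.S,
            "L": self.L,
            "LD": self.LD,
            "C": self.C,
            "CC": self.CC,
            "CPL": self.CPL,
            "Mod": self.Mod,
            "meanTL": self.meanTL,
            "O": self.O,
        }


def compute_all(web: FoodWeb, on_singular: str = "error") -> WebMetrics:
    """All scalar metrics of one web in a single pass."""
    S, L, LD, C = complexity(web)
    cc = clustering_coefficient(web)
    cpl, excluded = characteristic_path_length(web) if S >= 2 else (float("nan"), 0)
    q, _ = modularity(web) if S >= 2 else (float("nan"), [])
    tl, mean_tl = trophic_levels(web, on_singular=on_singular)
    o = omnivory(web, tl=tl)
    return WebMetrics(
        label=web.label,
        S=S,
        L=L,
        LD=LD,
        C=C,
        CC=cc,
        CPL=cpl,
        CPL_excluded_pairs=excluded,
        Mod=q,
        TL=tl,
        meanTL=mean_tl,
        O=o,
    )
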