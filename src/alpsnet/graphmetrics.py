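"""Network topology measures for structural connectomes.

Conventions (fixed, since weighted-graph practice varies):

- Edge weight -> distance by reciprocal: d_ij = 1/w_ij, infinity where
  w_ij = 0 (i != j).
- Global efficiency Eg = mean over ordered node pairs of 1/d_ij with
  1/inf = 0, so disconnected pairs pull Eg down rather than being skipped.
- Characteristic path length Lp = mean shortest-path distance over the
  *connected* ordered pairs only; the number of excluded pairs is reported.
- Local efficiency Eloc = mean over nodes of the global efficiency of the
  subgraph induced by each node's neighbours (same reciprocal distances).
- Clustering Cp = mean Onnela geometric-mean weighted clustering (reduces
  to per-node triangle density on binary graphs).
- Small-worldness sigma = (Cp/Cp_null)/(Lp/Lp_null) against
  degree-preserving Maslov-Sneppen rewired nulls that carry edge weights
  with the rewired edges (100 nulls by default, seeded).

Shortest paths use Dijkstra (scipy.sparse.csgraph); the default analysis
weight for connectomes is the streamline count (fiber_number).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .tract import Connectome

log = logging.getLogger(__name__)

WEIGHT_KINDS = ("fiber_number", "mean_fa", "binary")


@dataclass
class WeightedNetwork:
    node_ids: np.ndarray
    W: np.ndarray  # symmetric, non-negative, zero diagonal
    weight_kind: str = "fiber_number"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        n = len(self.node_ids)
        if self.W.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.W.shape} != ({n}, {n})")
        if np.any(self.W < 0):
            raise ValueError("edge weights must be non-negative")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("self-loops are not allowed (diagonal must be zero)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int((np.count_nonzero(self.W) - np.count_nonzero(np.diag(self.W))) // 2)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        iu, ju = np.nonzero(np.triu(self.W, 1))
        G.add_weighted_edges_from(
            (int(i), int(j), float(self.W[i, j])) for i, j in zip(iu, ju)
        )
        return G


def from_connectome(conn: Connectome, weight: str = "fiber_number") -> WeightedNetwork:
    """Build the analysis network from a connectome with the chosen weight."""
    if weight not in WEIGHT_KINDS:
        raise ValueError(f"weight must be one of {WEIGHT_KINDS}")
    if weight == "fiber_number":
        W = conn.fiber_number.astype(float)
    elif weight == "mean_fa":
        W = conn.mean_fa.astype(float)
    else:
        W = (conn.fiber_number > 0).astype(float)
    return WeightedNetwork(conn.region_ids, W, weight)


def to_distance(net: WeightedNetwork) -> np.ndarray:
    """Reciprocal-weight distance matrix: 1/w off-diagonal, inf where w=0."""
    W = net.W
    with np.errstate(divide="ignore"):
        d = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def _shortest_paths(net: WeightedNetwork) -> np.ndarray:
    d = to_distance(net)
    finite = np.where(np.isfinite(d), d, 0.0)
    graph = csr_matrix(finite)
    return dijkstra(graph, directed=False)


def _efficiency_from_sp(sp: np.ndarray) -> float:
    n = sp.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(sp > 0, 1.0 / sp, 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def network_metrics(net: WeightedNetwork) -> dict[str, float]:
    """Eg, Eloc, Lp, Cp (and the excluded disconnected-pair count for Lp)."""
    if net.n_nodes < 2:
        raise ValueError("network metrics require at least 2 nodes")
    sp = _shortest_paths(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    eg = _efficiency_from_sp(sp)
    finite = np.isfinite(sp) & off
    n_disconnected = int(off.sum() - finite.sum())
    lp = float(sp[finite].mean()) if finite.any() else np.inf
    if n_disconnected:
        log.warning(
            "Lp computed over connected pairs only (%d ordered pairs excluded)",
            n_disconnected,
        )

    # local efficiency: Eg of each node's neighbour-induced subgraph
    eloc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(net.W[i] > 0)
        if len(nbrs) < 2:
            continue
        sub = WeightedNetwork(net.node_ids[nbrs], net.W[np.ix_(nbrs, nbrs)],
                              net.weight_kind)
        eloc_terms[i] = _efficiency_from_sp(_shortest_paths(sub))
    eloc = float(eloc_terms.mean())

    G = net.to_networkx()
    is_binary = np.all(np.isin(net.W, (0.0, 1.0)))
    cp_dict = nx.clustering(G, weight=None if is_binary else "weight")
    cp = float(np.mean(list(cp_dict.values()))) if cp_dict else 0.0

    return {"Eg": eg, "Eloc": eloc, "Lp": lp, "Cp": cp,
            "n_disconnected_pairs": n_disconnected}


def _cp_lp(net: WeightedNetwork) -> tuple[float, float]:
    """Cp and Lp only (the pair needed per null network)."""
    sp = _shortest_paths(net)
    off = ~np.eye(net.n_nodes, dtype=bool)
    finite = np.isfinite(sp) & off
    lp = float(sp[finite].mean()) if finite.any() else np.inf
    G = net.to_networkx()
    is_binary = np.all(np.isin(net.W, (0.0, 1.0)))
    cp_dict = nx.clustering(G, weight=None if is_binary else "weight")
    cp = float(np.mean(list(cp_dict.values()))) if cp_dict else 0.0
    return cp, lp


def rewire_null(net: WeightedNetwork, seed=None, swap_factor: int = 10) -> WeightedNetwork:
    """Maslov-Sneppen degree-preserving null: attempted double-edge swaps.

    ``swap_factor * |E|`` swaps are attempted; each swap replaces edges
    (a, b), (c, d) by (a, d), (c, b) when neither new edge exists, carrying
    each weight with its surviving endpoint-pair.  The degree sequence is
    preserved exactly by construction.  On graphs where no legal swap
    exists (e.g. complete graphs) an identical copy is returned with a
    notice.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(net.W, 1))
    edges = [[int(a), int(b)] for a, b in zip(iu, ju)]
    weights = [float(net.W[a, b]) for a, b in edges]
    m = len(edges)
    if m < 2:
        raise ValueError("rewiring requires at least 2 edges")
    present = {frozenset(e) for e in edges}
    successes = 0
    for _ in range(swap_factor * m):
        i, j = rng.choice(m, size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((a, b)))
        present.discard(frozenset((c, d)))
        present.add(e1)
        present.add(e2)
        edges[i] = [a, d]
        edges[j] = [c, b]
        successes += 1
    if successes == 0:
        log.info("rewire_null: no legal swap possible; returning identical copy")
        return WeightedNetwork(net.node_ids.copy(), net.W.copy(), net.weight_kind)
    W = np.zeros_like(net.W)
    for (a, b), w in zip(edges, weights):
        W[a, b] = w
        W[b, a] = w
    return WeightedNetwork(net.node_ids.copy(), W, net.weight_kind)


def largest_component(net: WeightedNetwork) -> WeightedNetwork:
    graph = csr_matrix(np.where(net.W > 0, 1.0, 0.0))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp == 1:
        return net
    sizes = np.bincount(labels)
    keep = np.flatnonzero(labels == sizes.argmax())
    return WeightedNetwork(net.node_ids[keep], net.W[np.ix_(keep, keep)],
                           net.weight_kind)


def small_worldness(
    net: WeightedNetwork, n_null: int = 100, seed=None
) -> dict[str, float]:
    """gamma = Cp/mean(Cp_null), lambda = Lp/mean(Lp_null), sigma = gamma/lambda.

    Requires a connected network; disconnected inputs are reduced to the
    largest component with a warning.  Null seeds are spawned from ``seed``
    so results are bit-for-bit reproducible.
    """
    base = network_metrics(net)
    if base["n_disconnected_pairs"] > 0:
        log.warning("small_worldness: disconnected network, using largest component")
        net = largest_component(net)
        base = network_metrics(net)
    ss = np.random.SeedSequence(seed)
    cps, lps = [], []
    for child in ss.spawn(n_null):
        null = rewire_null(net, seed=child)
        cp, lp = _cp_lp(null)
        cps.append(cp)
        lps.append(lp)
    cp_null = float(np.mean(cps))
    lp_null = float(np.mean(lps))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null Cp or Lp is zero; sigma undefined")
    gamma = base["Cp"] / cp_null
    lam = base["Lp"] / lp_null
    return {"gamma": gamma, "lambda": lam, "sigma": gamma / lam,
            "n_null": n_null}


@dataclass
class GraphMetricsSet:
    Eg: float
    Eloc: float
    Lp: float
    Cp: float
    gamma: float
    lambda_: float
    sigma: float
    n_null: int
    null_seed: object = None

    def as_row(self) -> dict:
        return {
            "Eg": self.Eg, "Eloc": self.Eloc, "Lp": self.Lp, "Cp": self.Cp,
            "gamma": self.gamma, "lambda": self.lambda_, "sigma": self.sigma,
        }


def compute_all(net: WeightedNetwork, n_null: int = 100, seed=None) -> GraphMetricsSet:
    """Full per-subject metric set: Eg, Eloc, Lp, Cp, gamma, lambda, sigma."""
    base = network_metrics(net)
    sw = small_worldness(net, n_null=n_null, seed=seed)
    return GraphMetricsSet(
        Eg=base["Eg"], Eloc=base["Eloc"], Lp=base["Lp"], Cp=base["Cp"],
        gamma=sw["gamma"], lambda_=sw["lambda"], sigma=sw["sigma"],
        n_null=n_null, null_seed=seed,
    )
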