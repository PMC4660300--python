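"""Weighted-directed topological descriptors of the functional graph.

Five descriptors summarize the significant-link functional network:
total strength, global efficiency, local efficiency, weighted clustering
coefficient and degree assortativity.  Weights are first rescaled to
(0, 1] by the maximum weight; geodesics use edge length 1/weight, so both
efficiencies are bounded by 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .connectivity import FunctionalGraph

__all__ = ["TopologyDescriptors", "topology_descriptors", "topology_ratios"]

DESCRIPTOR_NAMES = (
    "strength",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "assortativity",
)


@dataclass(frozen=True)
class TopologyDescriptors:
    """The five weighted-directed descriptors plus per-node strengths."""

    strength: float                  # total strength (sum of in+out over nodes)
    node_strength: np.ndarray        # (N,) in+out strength per node
    global_efficiency: float
    local_efficiency: float
    clustering_coefficient: float
    assortativity: float             # NaN when undefined

    def as_dict(self) -> dict:
        return {
            "strength": self.strength,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "clustering_coefficient": self.clustering_coefficient,
            "assortativity": self.assortativity,
        }


def _weight_matrix(graph) -> np.ndarray:
    if isinstance(graph, FunctionalGraph):
        a = graph.significant_weights() if graph.sig_mask is not None else graph.W
        a = np.maximum(a, 0.0)
    else:
        a = np.asarray(graph, dtype=float)
        if np.any(a < 0):
            raise ValueError("weights must be non-negative")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    return a


def _efficiency(a: np.ndarray) -> float:
    """Mean over ordered node pairs of 1/geodesic, lengths = 1/weight."""
    n = a.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    d = dijkstra(csr_array(lengths), directed=True)
    np.fill_diagonal(d, np.inf)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d), 1.0 / d, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def topology_descriptors(graph) -> TopologyDescriptors:
    """Compute the five descriptors on a significant-link functional graph.

    Accepts a :class:`FunctionalGraph` (z-scored significant weights) or a
    raw non-negative weight matrix.  Weights are normalized by the maximum
    weight before any geodesic computation.  Conventions for the directed
    generalizations: a node's neighborhood is the union of its in- and
    out-neighbors; local efficiency averages over nodes with >= 2
    neighbors; clustering is Fagiolo's weighted-directed coefficient
    averaged over all nodes; assortativity is the Pearson correlation of
    total (in+out) weighted degree across all directed links.
    """
    a = _weight_matrix(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    node_strength = a.sum(axis=0) + a.sum(axis=1)
    if not np.any(a > 0):
        warnings.warn("empty graph: descriptors are zero, assortativity undefined")
        return TopologyDescriptors(
            strength=0.0,
            node_strength=node_strength,
            global_efficiency=0.0,
            local_efficiency=0.0,
            clustering_coefficient=0.0,
            assortativity=float("nan"),
        )
    a = a / a.max()

    geff = _efficiency(a)

    neighbors = [np.flatnonzero((a[i] > 0) | (a[:, i] > 0)) for i in range(n)]
    local = [
        _efficiency(a[np.ix_(nb, nb)]) for nb in neighbors if nb.size >= 2
    ]
    leff = float(np.mean(local)) if local else 0.0

    G = nx.from_numpy_array(a, create_using=nx.DiGraph)
    cc = nx.clustering(G, weight="weight")
    clustering = float(np.mean(list(cc.values())))

    src, dst = np.nonzero(a > 0)
    x, y = node_strength[src], node_strength[dst]
    if src.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        assort = float("nan")
    else:
        assort = float(np.corrcoef(x, y)[0, 1])

    return TopologyDescriptors(
        strength=float(node_strength.sum()),
        node_strength=node_strength,
        global_efficiency=geff,
        local_efficiency=leff,
        clustering_coefficient=clustering,
        assortativity=assort,
    )


def topology_ratios(after: TopologyDescriptors, before: TopologyDescriptors) -> dict:
    """Element-wise after/before descriptor ratios; NaN where undefined."""
    ratios = {}
    b = before.as_dict()
    a = after.as_dict()
    for name in DESCRIPTOR_NAMES:
        if b[name] == 0 or np.isnan(b[name]) or np.isnan(a[name]):
            ratios[name] = float("nan")
        else:
            ratios[name] = a[name] / b[name]
    return ratios
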