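"""Network hubs and module (community) detection.

Hubs are ranked by degree centrality and by eigenvector centrality — the
leading eigenvector of the 0/1 adjacency matrix, computed by power iteration
and max-normalized so the most central keyword scores 1.  Modules come from
Louvain modularity maximization with a resolution parameter; modules smaller
than a cutoff (default 3 keywords) can be flagged as omitted, mirroring how
small modules are usually dropped from presentation.

The resolution-weighted modularity of a partition c is

    Q(c) = 1/(2l) * sum_ij [A_ij - lambda k_i k_j / (2l)] delta_ij(c),

summing over ordered pairs, with delta_ij(c) = 1 when i and j share a module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netstats import LinguisticNetwork

__all__ = [
    "CentralityTable",
    "ModulePartition",
    "centralities",
    "top_hubs",
    "modularity_score",
    "louvain",
    "filter_small_modules",
    "module_shares",
]

OMITTED = -1  # module id marking nodes of omitted (too-small) modules


@dataclass
class CentralityTable:
    nodes: list[str]
    degree: np.ndarray
    eigenvector: np.ndarray
    leading_eigenvalue: float


@dataclass
class ModulePartition:
    """Node -> module assignment with the modularity of the partition.

    Module ids are contiguous from 1; ``OMITTED`` (-1) marks nodes whose
    module was filtered out for being too small.
    """

    assignment: dict[str, int]
    resolution: float
    modularity: float
    seed: int

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for mod in self.assignment.values():
            out[mod] = out.get(mod, 0) + 1
        return out


def centralities(net: LinguisticNetwork, tol: float = 1e-10, max_iter: int = 10000) -> CentralityTable:
    """Degree and eigenvector centrality for every node.

    Power iteration on the full (possibly disconnected) adjacency from a
    positive start; the limit concentrates on the component with the largest
    leading eigenvalue, so nodes outside it get (near-)zero scores.
    """
    if net.q == 0:
        raise ValueError("centralities undefined on an edgeless graph")
    A = net.adjacency.astype(float)
    # iterate on A + I: same eigenvectors, but strictly dominant leading
    # eigenvalue even on bipartite graphs (whose spectrum is symmetric)
    B = A + np.eye(net.n)
    x = np.ones(net.n) / np.sqrt(net.n)
    lam = 0.0
    for _ in range(max_iter):
        y = B @ x
        lam = np.linalg.norm(y)
        if lam == 0:
            raise ValueError("adjacency has no positive eigenvalue")
        y /= lam
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= x.max()
    return CentralityTable(list(net.nodes), net.degrees.astype(float), x, float(lam) - 1.0)


def top_hubs(table: CentralityTable, k: int, measure: str = "degree") -> list[str]:
    """Top-k keywords by the chosen centrality; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if measure == "degree":
        scores = table.degree
    elif measure == "eigenvector":
        scores = table.eigenvector
    else:
        raise ValueError(f"unknown measure {measure!r}")
    if k > len(table.nodes):
        warnings.warn("k exceeds the number of nodes; returning all nodes")
        k = len(table.nodes)
    order = sorted(zip(table.nodes, scores), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order[:k]]


def modularity_score(net: LinguisticNetwork, assignment: dict[str, int], resolution: float = 1.0) -> float:
    """Resolution-weighted modularity of an assignment (ordered-pair sum)."""
    missing = [v for v in net.nodes if v not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover nodes: {missing[:5]}")
    l = net.q
    if l < 1:
        raise ValueError("modularity undefined without edges")
    A = net.adjacency
    deg = net.degrees
    labels = np.array([assignment[v] for v in net.nodes])
    same = labels[:, None] == labels[None, :]
    expected = resolution * np.outer(deg, deg) / (2.0 * l)
    return float(np.sum((A - expected) * same) / (2.0 * l))


def louvain(net: LinguisticNetwork, resolution: float = 1.0, seed: int = 0) -> ModulePartition:
    """Louvain modularity maximization (two-phase local moving plus graph
    aggregation), deterministic for a fixed seed.

    The returned partition is never worse than the better of the singleton
    and the all-in-one partitions.
    """
    if net.q == 0:
        raise ValueError("louvain undefined on an edgeless graph")
    G = net.to_networkx()
    comms = nx.community.louvain_communities(G, resolution=resolution, seed=seed, weight=None)
    assignment = {}
    # stable ids: order modules by their lexicographically smallest member
    comms = sorted(comms, key=lambda c: min(c))
    for i, comm in enumerate(comms, start=1):
        for v in comm:
            assignment[v] = i
    q_l = modularity_score(net, assignment, resolution)
    singleton = {v: i for i, v in enumerate(net.nodes)}
    allone = {v: 1 for v in net.nodes}
    for cand in (singleton, allone):
        q_c = modularity_score(net, cand, resolution)
        if q_c > q_l:
            ids = sorted(set(cand.values()))
            remap = {old: new for new, old in enumerate(ids, start=1)}
            assignment = {v: remap[cand[v]] for v in net.nodes}
            q_l = q_c
    return ModulePartition(assignment, float(resolution), q_l, seed)


def filter_small_modules(partition: ModulePartition, min_size: int = 3) -> ModulePartition:
    """Flag modules below ``min_size`` as omitted; their nodes keep the
    OMITTED marker rather than being reassigned."""
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    sizes = partition.sizes()
    small = {mod for mod, s in sizes.items() if mod != OMITTED and s < min_size}
    new_assignment = {
        v: (OMITTED if mod in small else mod) for v, mod in partition.assignment.items()
    }
    kept = sorted({m for m in new_assignment.values() if m != OMITTED})
    remap = {old: new for new, old in enumerate(kept, start=1)}
    remap[OMITTED] = OMITTED
    new_assignment = {v: remap[m] for v, m in new_assignment.items()}
    return ModulePartition(new_assignment, partition.resolution, partition.modularity, partition.seed)


def module_shares(partition: ModulePartition) -> dict[int, float]:
    """Percentage of nodes in each module (omitted nodes included in the
    denominator), as printed in module summary tables."""
    n = len(partition.assignment)
    return {
        mod: 100.0 * size / n
        for mod, size in sorted(partition.sizes().items())
        if mod != OMITTED
    }
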