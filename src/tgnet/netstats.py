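"""Per-phase linguistic networks and their topological indicators.

A fitted precision matrix defines an undirected keyword network: nodes are
keywords and an edge joins i and j when the off-diagonal entry theta_ij is
nonzero, i.e. the two keywords are conditionally dependent given all others.
This module builds that graph and computes the standard indicator bundle:
average degree, average shortest-path length (ASPL), clustering coefficient
(CC), the matching Erdos-Renyi baselines ASPLr and CCr, the small-world
coefficient sigma = (CC/CCr)/(ASPL/ASPLr), and a discrete maximum-likelihood
power-law exponent gamma for the degree distribution.

Conventions (chosen so the arithmetic of sparse phases is self-consistent):
ASPL averages over pairs at finite distance only; the Erdos-Renyi baselines
use the number of *non-isolated* nodes; CC averages over non-isolated nodes,
with degree-1 nodes contributing zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar

__all__ = [
    "LinguisticNetwork",
    "NetworkIndicators",
    "build_network",
    "average_degree",
    "aspl",
    "clustering_coefficient",
    "er_baselines",
    "small_world_sigma",
    "powerlaw_gamma",
    "powerlaw_fit",
    "sample_discrete_powerlaw",
    "indicators",
]


@dataclass
class LinguisticNetwork:
    """Undirected keyword graph with 0/1 adjacency.

    ``weights`` keeps the |theta| magnitudes for export; every indicator is
    computed on the unweighted graph.
    """

    nodes: list[str]
    adjacency: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] != len(self.nodes):
            raise ValueError("adjacency must be square and match the node list")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = A.astype(int)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def q(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_active(self) -> int:
        """Number of non-isolated nodes."""
        return int(np.count_nonzero(self.degrees))

    def edges(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        out = []
        for a, b in zip(*iu):
            if self.adjacency[a, b]:
                out.append((self.nodes[a], self.nodes[b]))
        return out

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        iu = np.triu_indices(self.n, k=1)
        for a, b in zip(*iu):
            if self.adjacency[a, b]:
                w = float(self.weights[a, b]) if self.weights is not None else 1.0
                G.add_edge(self.nodes[a], self.nodes[b], weight=w)
        return G


@dataclass
class NetworkIndicators:
    """The per-phase indicator bundle; NaN marks an undefined entry
    (e.g. gamma on a degenerate degree sequence)."""

    avg_degree: float
    aspl: float
    cc: float
    aspl_r: float
    cc_r: float
    sigma: float
    gamma: float
    n_active: int
    gamma_degenerate: bool = False


def build_network(theta_hat: np.ndarray, threshold: float = 1e-8, nodes=None) -> LinguisticNetwork:
    """Edge iff |theta_ij| > threshold for i != j.

    The lasso produces exact zeros, so the default threshold is only a
    numerical safety net.
    """
    T = np.asarray(theta_hat, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("theta_hat must be square")
    if np.max(np.abs(T - T.T)) > 1e-8:
        raise ValueError("theta_hat is asymmetric beyond 1e-8")
    T = 0.5 * (T + T.T)
    p = T.shape[0]
    if nodes is None:
        nodes = [f"w{i+1}" for i in range(p)]
    A = (np.abs(T) > threshold).astype(int)
    np.fill_diagonal(A, 0)
    W = np.abs(T) * A
    return LinguisticNetwork(list(nodes), A, W)


def average_degree(net: LinguisticNetwork) -> float:
    """Mean degree 2q/n over *all* nodes, isolated included."""
    if net.n == 0:
        raise ValueError("empty node set")
    return 2.0 * net.q / net.n


def aspl(net: LinguisticNetwork) -> float:
    """Average shortest-path length over pairs at finite distance
    (pairs within one connected component)."""
    if net.q == 0:
        raise ValueError("ASPL undefined: the graph has no edges")
    G = net.to_networkx()
    total = 0
    npairs = 0
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        sub = G.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            npairs += len(dists) - 1
    # every pair counted twice in the loop above
    return (total / 2) / (npairs / 2)


def clustering_coefficient(net: LinguisticNetwork) -> float:
    """Mean local clustering over non-isolated nodes; a node of degree < 2
    contributes zero."""
    deg = net.degrees
    active = deg > 0
    if not active.any():
        raise ValueError("clustering coefficient undefined: all nodes isolated")
    A = net.adjacency
    tri = np.diag(A @ A @ A) / 2.0  # edges among neighbours of each node
    terms = np.zeros(net.n)
    mask = deg >= 2
    terms[mask] = tri[mask] / (deg[mask] * (deg[mask] - 1) / 2.0)
    return float(terms[active].mean())


def er_baselines(n_active: int, q: int) -> tuple[float, float]:
    """Erdos-Renyi reference values on the non-isolated node set:
    ASPLr = ln(n)/(ln(2q) - ln(n)) and CCr = 2q/(n(n-1))."""
    if n_active < 2:
        raise ValueError("er_baselines undefined: fewer than 2 non-isolated nodes")
    if q < 1:
        raise ValueError("er_baselines undefined: no edges")
    if 2 * q == n_active:
        raise ValueError("er_baselines undefined: ln(2q) = ln(n), zero denominator")
    aspl_r = math.log(n_active) / (math.log(2 * q) - math.log(n_active))
    cc_r = 2.0 * q / (n_active * (n_active - 1))
    return aspl_r, cc_r


def small_world_sigma(cc: float, cc_r: float, aspl_: float, aspl_r: float) -> float:
    """Small-world coefficient (CC/CCr)/(ASPL/ASPLr); > 1 indicates
    small-world structure.  Zero when CC is zero."""
    if cc_r <= 0 or aspl_r <= 0:
        raise ValueError("reference values must be positive")
    if cc < 0 or aspl_ <= 0:
        raise ValueError("cc must be non-negative and aspl positive")
    if cc == 0:
        return 0.0
    return (cc / cc_r) / (aspl_ / aspl_r)


# ---------------------------------------------------------------------------
# discrete power-law exponent

def _powerlaw_negloglik(gamma: float, degrees: np.ndarray) -> float:
    # zeta-normalized likelihood with x_min = 1: P(k) = k^-gamma / zeta(gamma)
    n = len(degrees)
    return n * math.log(special.zeta(gamma, 1.0)) + gamma * float(np.log(degrees).sum())


def powerlaw_fit(degree_sequence) -> tuple[float, bool]:
    """Discrete ML power-law exponent over positive degrees, x_min = 1.

    Returns (gamma_hat, degenerate).  ``degenerate`` flags a boundary
    solution (all degrees equal 1 pushes gamma to the upper bracket; no
    power-law signal).
    """
    deg = np.asarray(degree_sequence, dtype=float)
    deg = deg[deg >= 1]
    if len(deg) < 5:
        raise ValueError("insufficient tail: fewer than 5 positive degrees")
    lo, hi = 1.0 + 1e-6, 20.0
    res = minimize_scalar(
        _powerlaw_negloglik, bounds=(lo, hi), args=(deg,), method="bounded",
        options={"xatol": 1e-8},
    )
    gamma_hat = float(res.x)
    degenerate = bool(gamma_hat > hi - 1e-3 or gamma_hat < lo + 1e-3)
    if degenerate:
        warnings.warn("degenerate degree sequence: power-law exponent at bound")
    return gamma_hat, degenerate


def powerlaw_gamma(degree_sequence) -> float:
    """Exponent only; see :func:`powerlaw_fit`."""
    return powerlaw_fit(degree_sequence)[0]


def sample_discrete_powerlaw(gamma: float, size: int, rng) -> np.ndarray:
    """Draw from P(k) = k^-gamma / zeta(gamma), k = 1, 2, ... by inverse CDF
    over a truncated support with an aggregated tail bucket."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    kmax = 100000
    k = np.arange(1, kmax + 1, dtype=float)
    pmf = k ** (-gamma) / special.zeta(gamma, 1.0)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0
    u = rng.random(size)
    return (np.searchsorted(cdf, u) + 1).astype(int)


def powerlaw_gof_pvalue(degree_sequence, gamma_hat: float, n_boot: int = 100, seed: int = 0) -> float:
    """Bootstrap Kolmogorov-Smirnov goodness-of-fit p-value for the fitted
    discrete power law (x_min = 1)."""
    deg = np.asarray(degree_sequence, dtype=float)
    deg = deg[deg >= 1].astype(int)
    n = len(deg)
    rng = np.random.default_rng(seed)

    def ks_stat(sample, gamma):
        kmax = int(sample.max())
        k = np.arange(1, kmax + 1, dtype=float)
        cdf_model = np.cumsum(k ** (-gamma)) / special.zeta(gamma, 1.0)
        counts = np.bincount(sample, minlength=kmax + 1)[1:]
        cdf_emp = np.cumsum(counts) / n
        return float(np.max(np.abs(cdf_emp - cdf_model)))

    d_obs = ks_stat(deg, gamma_hat)
    exceed = 0
    for _ in range(n_boot):
        sim = sample_discrete_powerlaw(gamma_hat, n, rng)
        g_sim, _ = powerlaw_fit(sim)
        if ks_stat(sim, g_sim) >= d_obs:
            exceed += 1
    return exceed / n_boot


def indicators(net: LinguisticNetwork, *, gof: bool = False, seed: int = 0) -> NetworkIndicators:
    """Compute the full indicator bundle for one phase network."""
    k_bar = average_degree(net)
    if net.q == 0:
        raise ValueError("indicators undefined on an edgeless graph")
    L = aspl(net)
    C = clustering_coefficient(net)
    Lr, Cr = er_baselines(net.n_active, net.q)
    sig = small_world_sigma(C, Cr, L, Lr)
    deg = net.degrees
    try:
        gamma_hat, degen = powerlaw_fit(deg)
    except ValueError:
        gamma_hat, degen = float("nan"), True
    if gof and not math.isnan(gamma_hat):
        p = powerlaw_gof_pvalue(deg, gamma_hat, seed=seed)
        degen = degen or (p < 0.1)
    return NetworkIndicators(k_bar, L, C, Lr, Cr, sig, gamma_hat, net.n_active, degen)
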