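"""Signed Spearman co-occurrence network, modules, centralities, keystones.

The network is built from all pairwise Spearman correlations between the
selected dominant OTUs; edges survive only when both the correlation
magnitude and significance thresholds are met (defaults |rho| >= 0.8,
p <= 0.01). Modules come from a seeded Louvain-style modularity heuristic;
keystone taxa are the nodes ranking jointly high on degree and closeness
and low on betweenness.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_table import RelativeAbundanceTable

__all__ = [
    "CorrelationResult",
    "ModulePartition",
    "KeystoneSet",
    "spearman_xy",
    "spearman_matrix",
    "filter_edges",
    "network_density",
    "detect_modules",
    "centralities",
    "select_keystones",
]

#: sample-size boundary below which exact permutation p-values are used
EXACT_P_MAX_N = 9


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho / p matrices over the selected OTUs."""

    otu_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        k = len(self.otu_ids)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("rho/p must be square over otu_ids")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("p must be symmetric")


@dataclass
class ModulePartition:
    """Node -> module id map plus size-ranked main-module ids.

    Module ids are 1-based, assigned in decreasing module size (ties broken
    by smallest member node id). ``main_modules`` lists the ids of modules
    whose size reaches the ``min_size`` used at detection time.
    """

    module_of_node: dict[str, int]
    main_modules: list[int]
    modularity: float = float("nan")

    def members(self, module_id: int) -> list[str]:
        return sorted(n for n, m in self.module_of_node.items() if m == module_id)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.module_of_node.values():
            out[m] = out.get(m, 0) + 1
        return out


@dataclass
class KeystoneSet:
    """Nodes ordered by composite rank-sum score (smaller is more keystone)."""

    nodes: list[str]
    scores: list[float] = field(default_factory=list)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry) / denom


def _exact_two_sided_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """p by full enumeration of the n! permutations of one rank vector."""
    n = len(ry)
    rx_c = rx - rx.mean()
    sx = math.sqrt(float(rx_c @ rx_c))
    ry_c = ry - ry.mean()
    sy = math.sqrt(float(ry_c @ ry_c))
    if sx == 0 or sy == 0:
        return 1.0
    perms = np.array(list(itertools.permutations(ry_c)))
    rhos = perms @ rx_c / (sx * sy)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_xy(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p for a single pair of vectors.

    rho is the product-moment correlation of average ranks. For
    ``n <= EXACT_P_MAX_N`` samples the p-value is exact (full permutation
    enumeration); otherwise the t-approximation with n-2 df is used.
    Constant vectors give (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("Spearman correlation requires >= 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx, ry = _rank(x), _rank(y)
    rho = _pearson_on_ranks(rx, ry)
    if n <= EXACT_P_MAX_N:
        return rho, _exact_two_sided_p(rx, ry, rho)
    return rho, _t_approx_p(rho, n)


def _t_approx_p(rho: float, n: int) -> float:
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_matrix(
    rel: RelativeAbundanceTable | pd.DataFrame, otu_ids: list[str] | None = None
) -> CorrelationResult:
    """All-pairs Spearman rho/p over the (optionally restricted) OTU columns.

    Accepts a :class:`RelativeAbundanceTable` or a plain samples x OTUs
    DataFrame. Constant columns yield rho = 0, p = 1 against everything.
    """
    df = rel.to_frame() if isinstance(rel, RelativeAbundanceTable) else rel
    if otu_ids is not None:
        df = df[list(otu_ids)]
    ids = [str(c) for c in df.columns]
    X = df.to_numpy(dtype=float)
    n, k = X.shape
    if n < 4:
        raise ValueError("Spearman correlation requires >= 4 samples")
    if k < 2:
        raise ValueError("need at least 2 OTUs")

    ranks = np.apply_along_axis(_rank, 0, X)
    constant = np.ptp(X, axis=0) == 0
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    safe = np.where(norms == 0, 1.0, norms)
    rho = (centered / safe).T @ (centered / safe)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    if n <= EXACT_P_MAX_N:
        p = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                if constant[i] or constant[j]:
                    continue
                p[i, j] = p[j, i] = _exact_two_sided_p(
                    ranks[:, i], ranks[:, j], rho[i, j]
                )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(otu_ids=ids, rho=rho, p=p, n_samples=n)


def filter_edges(
    corr: CorrelationResult, r_min: float = 0.8, p_max: float = 0.01
) -> nx.Graph:
    """Keep edge (i, j) iff |rho_ij| >= r_min and p_ij <= p_max.

    Nodes with no surviving edge are retained as isolates (they are later
    excluded from module detection). Each edge carries ``rho`` and a
    ``sign`` attribute ("positive"/"negative").
    """
    if not (0 < r_min <= 1) or not (0 < p_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(corr.otu_ids)
    k = len(corr.otu_ids)
    for i in range(k):
        for j in range(i + 1, k):
            r = corr.rho[i, j]
            if abs(r) >= r_min and corr.p[i, j] <= p_max:
                g.add_edge(
                    corr.otu_ids[i],
                    corr.otu_ids[j],
                    rho=float(r),
                    sign="positive" if r > 0 else "negative",
                )
    return g


def network_density(
    net: nx.Graph, node_subset: list[str] | None = None, positive_only: bool = False
) -> float:
    """2E / (N(N-1)) over the induced subgraph.

    With ``positive_only`` only edges whose ``sign`` is "positive" are
    counted (the reported core-module figure uses this variant).
    """
    g = net if node_subset is None else net.subgraph(node_subset)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    if positive_only:
        e = sum(1 for _, _, d in g.edges(data=True) if d.get("sign") == "positive")
    else:
        e = g.number_of_edges()
    return 2.0 * e / (n * (n - 1))


def detect_modules(net: nx.Graph, seed: int, min_size: int = 5) -> ModulePartition:
    """Modularity-maximizing partition of the non-isolated nodes.

    Louvain-style multilevel heuristic on the unweighted edge set,
    deterministic under ``seed``. Modules are renumbered 1..M by
    decreasing size; modules smaller than ``min_size`` are kept in the
    partition but excluded from ``main_modules``.
    """
    if net.number_of_edges() == 0:
        raise ValueError("cannot detect modules on an edgeless graph")
    core = net.subgraph([n for n, d in net.degree() if d > 0])
    communities = nx.community.louvain_communities(core, weight=None, seed=seed)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    module_of_node = {
        node: idx + 1 for idx, comm in enumerate(communities) for node in comm
    }
    q = nx.community.modularity(core, communities, weight=None)
    main = [i + 1 for i, c in enumerate(communities) if len(c) >= min_size]
    return ModulePartition(module_of_node=module_of_node, main_modules=main, modularity=q)


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, Wasserman-Faust closeness, and normalized betweenness.

    All measures are computed on the unweighted graph; isolates get
    closeness 0 and betweenness 0.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("centralities need at least 2 nodes")
    nodes = sorted(net.nodes())
    deg = dict(net.degree())
    clo = nx.closeness_centrality(net, wf_improved=True)
    bet = nx.betweenness_centrality(net, normalized=True)
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
            "betweenness": [bet[n] for n in nodes],
        },
        index=nodes,
    )


def select_keystones(cent: pd.DataFrame, k: int = 20) -> KeystoneSet:
    """Top-k nodes by composite rank sum.

    Composite score = rank(degree, descending) + rank(closeness,
    descending) + rank(betweenness, ascending), average ranks for ties;
    the k smallest scores win, ties broken by node id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(cent)
    if k > n:
        warnings.warn(f"k={k} exceeds node count {n}; returning all nodes")
        k = n
    score = (
        _rank(-cent["degree"].to_numpy())
        + _rank(-cent["closeness"].to_numpy())
        + _rank(cent["betweenness"].to_numpy())
    )
    order = sorted(range(n), key=lambda i: (score[i], str(cent.index[i])))
    chosen = order[:k]
    return KeystoneSet(
        nodes=[str(cent.index[i]) for i in chosen],
        scores=[float(score[i]) for i in chosen],
    )
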