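"""Weighted co-expression networks, topological overlap, consensus modules.

Samples are cell lines (around 10), genes are network nodes.  Adjacency is
``|cor|^beta`` (unsigned, the historical default) or ``((1+cor)/2)^beta``
(signed).  The topological overlap matrix (TOM) combines direct adjacency
with shared-neighbour structure and ``1 - TOM`` serves as the clustering
dissimilarity.  Modules are detected with average-linkage hierarchical
clustering and a static cut, which is deterministic; this diverges from the
dynamic hybrid tree cut used by the reference R implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "NetworkModel",
    "ModuleSet",
    "ConsensusComparison",
    "soft_power",
    "scale_free_fit",
    "adjacency_tom",
    "consensus_tom",
    "detect_modules",
    "compare_conditions",
]


@dataclass
class NetworkModel:
    genes: list[str]
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    condition: str  # "pre" | "post" | "consensus"

    def __post_init__(self) -> None:
        for name, m in (("adjacency", self.adjacency), ("tom", self.tom)):
            if m.shape != (len(self.genes), len(self.genes)):
                raise ValueError(f"{name} shape does not match gene list")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if m.min() < -1e-10 or m.max() > 1 + 1e-10:
                raise ValueError(f"{name} entries must lie in [0, 1]")


@dataclass
class ModuleSet:
    modules: list[tuple[str, frozenset]]
    unassigned: frozenset
    cut_height: float
    min_size: int

    def gene_universe(self) -> frozenset:
        u = set(self.unassigned)
        for _, members in self.modules:
            u |= members
        return frozenset(u)

    def membership(self) -> dict[str, str]:
        out = {}
        for mod_id, members in self.modules:
            for g in members:
                out[g] = mod_id
        return out


@dataclass
class ConsensusComparison:
    unaffected_modules: list[tuple[str, frozenset]]
    pre_only_modules: list[tuple[str, frozenset]]
    post_only_modules: list[tuple[str, frozenset]]
    gene_labels: dict[str, str]
    jaccard_threshold: float


def _correlation(expr: np.ndarray) -> np.ndarray:
    """Genewise Pearson correlation; zero-variance genes correlate 0."""
    sd = expr.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s): correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(expr)
    cor[flat, :] = 0.0
    cor[:, flat] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free-topology fit index.

    Bins log10 connectivity into equal-width bins, regresses log10 frequency
    on log10 mean connectivity and returns ``-sign(slope) * R^2`` so that the
    value is positive only for the decreasing degree distribution expected of
    a scale-free network.
    """
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.ptp(np.log10(k)) == 0:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        xs.append(np.log10(np.mean(k[sel])))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    res = linregress(xs, ys)
    return float(-np.sign(res.slope) * res.rvalue ** 2)


def soft_power(
    expr: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    target_r2: float = 0.8,
    signed: bool = False,
) -> tuple[int, bool]:
    """Smallest candidate power reaching the scale-free fit target.

    Returns ``(beta, reached_target)``; when no candidate qualifies the power
    maximising the fit index is returned with ``reached_target=False``.
    """
    mat = expr.to_numpy(dtype=float)
    if mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    if np.all(mat.std(axis=1) == 0):
        raise ValueError("expression matrix is constant")
    cor = _correlation(mat)
    base = (1 + cor) / 2 if signed else np.abs(cor)
    fits = []
    for p in candidate_powers:
        a = base ** p
        np.fill_diagonal(a, 0.0)
        fits.append(scale_free_fit(a.sum(axis=1)))
    for p, r2 in zip(candidate_powers, fits):
        if r2 >= target_r2:
            return int(p), True
    best = int(candidate_powers[int(np.argmax(fits))])
    warnings.warn(f"no candidate power reached R2 >= {target_r2}; using argmax {best}")
    return best, False


def adjacency_tom(
    expr: pd.DataFrame, beta: int, signed: bool = False, condition: str = "pre"
) -> NetworkModel:
    """Adjacency and topological overlap from a gene x sample matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k the connectivity (row sum excluding the diagonal); the diagonal is 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    mat = expr.to_numpy(dtype=float)
    cor = _correlation(mat)
    adj = ((1 + cor) / 2) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)

    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2, 0.0, 1.0)
    return NetworkModel(list(expr.index), int(beta), adj, tom, condition)


def consensus_tom(
    tom_pre: NetworkModel, tom_post: NetworkModel, scale_quantile: float = 0.95
) -> NetworkModel:
    """Elementwise minimum of the pre TOM and the quantile-scaled post TOM.

    The post TOM is rescaled so its ``scale_quantile`` off-diagonal quantile
    matches the pre TOM's, compensating for overall connectivity differences
    between the two condition networks.
    """
    if tom_pre.genes != tom_post.genes:
        diff = set(tom_pre.genes) ^ set(tom_post.genes)
        raise ValueError(f"gene universes differ (or ordering differs): {sorted(diff)[:10]}")
    iu = np.triu_indices(len(tom_pre.genes), k=1)
    q_pre = np.quantile(tom_pre.tom[iu], scale_quantile)
    q_post = np.quantile(tom_post.tom[iu], scale_quantile)
    scale = q_pre / q_post if q_post > 0 else 1.0
    cons = np.minimum(tom_pre.tom, tom_post.tom * scale)
    np.fill_diagonal(cons, 1.0)
    cons = np.clip(cons, 0.0, 1.0)
    adj = np.minimum(tom_pre.adjacency, tom_post.adjacency)
    np.fill_diagonal(adj, 1.0)
    return NetworkModel(list(tom_pre.genes), tom_pre.beta, adj, cons, "consensus")


def detect_modules(
    network: NetworkModel, cut_height: float = 0.6, min_size: int = 30
) -> ModuleSet:
    """Average-linkage clustering of 1-TOM with a static cut.

    ``cut_height`` is a fraction of the tallest merge in the dendrogram.
    Clusters smaller than ``min_size`` go to ``unassigned``.  Module ids are
    M1, M2, ... by decreasing size, ties broken by the lexicographically
    smallest member gene.
    """
    genes = network.genes
    if len(genes) < 2:
        return ModuleSet([], frozenset(genes), cut_height, min_size)
    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    z = average(squareform(np.clip((diss + diss.T) / 2, 0.0, None), checks=False))
    height = cut_height * z[:, 2].max() if z[:, 2].max() > 0 else 0.0
    labels = fcluster(z, t=height, criterion="distance")
    clusters: dict[int, set] = {}
    for g, lab in zip(genes, labels):
        clusters.setdefault(int(lab), set()).add(g)
    kept = [frozenset(m) for m in clusters.values() if len(m) >= min_size]
    kept.sort(key=lambda m: (-len(m), min(m)))
    modules = [(f"M{i + 1}", m) for i, m in enumerate(kept)]
    assigned = set().union(*kept) if kept else set()
    return ModuleSet(modules, frozenset(set(genes) - assigned), cut_height, min_size)


def dendrogram_newick(network: NetworkModel) -> str:
    """Average-linkage dendrogram of 1-TOM as a Newick string (inspection aid)."""
    from scipy.cluster.hierarchy import to_tree

    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    z = average(squareform(np.clip((diss + diss.T) / 2, 0.0, None), checks=False))
    root = to_tree(z)
    labels = network.genes

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - (node.dist if not node.is_leaf() else 0.0), 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
        return f"{inner}:{length:.6g}"

    return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def compare_conditions(
    modules_pre: ModuleSet,
    modules_post: ModuleSet,
    modules_consensus: ModuleSet,
    jaccard_threshold: float = 0.5,
) -> ConsensusComparison:
    """Label modules treatment-unaffected, pre-only or post-only.

    Consensus modules are unaffected by construction.  A pre module is
    pre-only when its best Jaccard overlap with every post module is strictly
    below the threshold (an overlap exactly at the threshold counts as
    matched), and symmetrically for post-only.  Gene labels follow the
    precedence unaffected > pre_only > post_only.
    """
    unaffected = list(modules_consensus.modules)
    pre_only = [
        (mid, m)
        for mid, m in modules_pre.modules
        if all(_jaccard(m, pm) < jaccard_threshold for _, pm in modules_post.modules)
        or not modules_post.modules
    ]
    post_only = [
        (mid, m)
        for mid, m in modules_post.modules
        if all(_jaccard(m, pm) < jaccard_threshold for _, pm in modules_pre.modules)
        or not modules_pre.modules
    ]
    labels: dict[str, str] = {}
    for _, m in post_only:
        for g in m:
            labels[g] = "post_only"
    for _, m in pre_only:
        for g in m:
            labels[g] = "pre_only"
    for _, m in unaffected:
        for g in m:
            labels[g] = "unaffected"
    return ConsensusComparison(unaffected, pre_only, post_only, labels, jaccard_threshold)
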