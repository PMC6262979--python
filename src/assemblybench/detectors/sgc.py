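"""Similarity-graph-clustering (SGC) assembly detector.

High-coactivity binary activity patterns become nodes of an unweighted
mutual k-nearest-neighbour graph under cosine distance (k starts at
⌈ln n⌉ and grows until the graph is connected).  The number of communities
is chosen by minimising the description length of a degree-corrected
stochastic block model over an agglomerative merge hierarchy with seeded
spectral restarts; the graph is then split with normalised-Laplacian
spectral clustering, and the groups go through the multi-stage core-pattern
refinement (size filters, binarised preliminary cores, recursive merging,
reassignment, final size filter) before thresholding the averaged core
patterns into assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from sklearn.cluster import KMeans

from ..arrays import Assembly, AssemblyConfiguration
from ..preprocess import ActivityPatternSet, binarize_dff, select_high_activity

__all__ = [
    "DetectionEmpty",
    "PatternGraph",
    "CorePattern",
    "build_knn_graph",
    "dcsbm_description_length",
    "infer_n_communities",
    "spectral_split",
    "refine_groups",
    "cores_to_assemblies",
    "detect_sgc",
]


class DetectionEmpty(RuntimeError):
    """No patterns / groups survive; the detector reports no assemblies."""


@dataclass
class PatternGraph:
    """Unweighted mutual k-NN graph over activity patterns."""

    adjacency: csr_matrix  # symmetric, no self-loops
    k: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class CorePattern:
    """Averaged activity pattern of a refined group (per-neuron affinity)."""

    alpha: np.ndarray        # mean activity per neuron, in [0, 1]
    member_patterns: np.ndarray  # indices into the pattern set


def _cosine_distance(patterns: np.ndarray) -> np.ndarray:
    x = patterns.astype(float)
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    sim = (x @ x.T) / np.outer(norms, norms)
    return 1.0 - np.clip(sim, -1.0, 1.0)


def build_knn_graph(patterns: ActivityPatternSet | np.ndarray) -> PatternGraph:
    """Mutualised (undirected union) k-NN graph, k grown until connected."""
    pats = patterns.patterns if isinstance(patterns, ActivityPatternSet) else patterns
    n = len(pats)
    if n < 2:
        raise DetectionEmpty("need at least 2 activity patterns")
    dist = _cosine_distance(np.asarray(pats))
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    k = max(1, math.ceil(math.log(n)))
    while True:
        kk = min(k, n - 1)
        rows = np.repeat(np.arange(n), kk)
        cols = order[:, :kk].ravel()
        adj = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        adj = ((adj + adj.T) > 0).astype(np.int8)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1 or kk == n - 1:
            return PatternGraph(adjacency=adj, k=kk)
        k += 1


def _entropy_dcsbm(e: np.ndarray, er: np.ndarray) -> float:
    """-(1/2)Σ e_rs·ln(e_rs/(e_r·e_s)) over non-empty blocks."""
    mask = e > 0
    if not mask.any():
        return 0.0
    outer = np.outer(er, er)
    return -0.5 * float(np.sum(e[mask] * np.log(e[mask] / outer[mask])))


def dcsbm_description_length(
    adjacency: csr_matrix, labels: np.ndarray
) -> float:
    """MDL of a degree-corrected SBM fit for a given node partition.

    Microcanonical DC-SBM entropy S = −E − Σ ln k_i! − ½Σ e_rs ln(e_rs/e_r e_s)
    plus the model description cost E·h(B(B+1)/2E) + N·ln B with
    h(x) = (1+x)ln(1+x) − x·ln x and B the number of occupied blocks.
    """
    labels = np.asarray(labels)
    n = adjacency.shape[0]
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    E = degrees.sum() / 2.0
    blocks, labels_c = np.unique(labels, return_inverse=True)
    B = len(blocks)
    C = csr_matrix(
        (np.ones(n), (np.arange(n), labels_c)), shape=(n, B)
    )
    e = np.asarray((C.T @ adjacency @ C).todense(), dtype=float)
    er = e.sum(axis=1)
    S = -E - float(gammaln(degrees + 1).sum()) + _entropy_dcsbm(e, er)
    x = B * (B + 1) / (2.0 * E) if E > 0 else 0.0
    h = (1 + x) * math.log1p(x) - x * math.log(x) if x > 0 else 0.0
    return S + E * h + n * math.log(B) if B >= 1 else S


def _merge_hierarchy_dl(
    adjacency: csr_matrix, labels: np.ndarray
) -> dict[int, float]:
    """Greedy agglomerative merges; best description length per block count."""
    n = adjacency.shape[0]
    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    E = degrees.sum() / 2.0
    log_k_fact = float(gammaln(degrees + 1).sum())
    blocks, lab = np.unique(labels, return_inverse=True)
    B = len(blocks)
    C = csr_matrix((np.ones(n), (np.arange(n), lab)), shape=(n, B))
    e = np.asarray((C.T @ adjacency @ C).todense(), dtype=float)

    def total_dl(e_mat: np.ndarray) -> float:
        er = e_mat.sum(axis=1)
        nb = int((er > 0).sum()) or 1
        S = -E - log_k_fact + _entropy_dcsbm(e_mat, er)
        x = nb * (nb + 1) / (2.0 * E) if E > 0 else 0.0
        h = (1 + x) * math.log1p(x) - x * math.log(x) if x > 0 else 0.0
        return S + E * h + n * math.log(nb)

    out = {int((e.sum(axis=1) > 0).sum()): total_dl(e)}
    while e.shape[0] > 1:
        b = e.shape[0]
        best_dl, best_pair = np.inf, None
        for r in range(b):
            for s in range(r + 1, b):
                idx = [i for i in range(b) if i not in (r, s)]
                merged = e[np.ix_(idx, idx)]
                row = e[r, idx] + e[s, idx]
                corner = e[r, r] + e[s, s] + 2 * e[r, s]
                new_e = np.empty((b - 1, b - 1))
                new_e[:-1, :-1] = merged
                new_e[-1, :-1] = row
                new_e[:-1, -1] = row
                new_e[-1, -1] = corner
                dl = total_dl(new_e)
                if dl < best_dl:
                    best_dl, best_pair = dl, (r, s, new_e)
        r, s, e = best_pair[0], best_pair[1], best_pair[2]
        nb = int((e.sum(axis=1) > 0).sum()) or 1
        if best_dl < out.get(nb, np.inf):
            out[nb] = best_dl
    return out


def _laplacian_embedding(adjacency: csr_matrix) -> np.ndarray:
    """Eigenvectors of the symmetric normalised Laplacian, ascending."""
    n = adjacency.shape[0]
    A = np.asarray(adjacency.todense(), dtype=float)
    d = A.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    lsym = np.eye(n) - dinv[:, None] * A * dinv[None, :]
    _, vecs = np.linalg.eigh(lsym)
    return vecs


def _embedding_labels(vecs: np.ndarray, n_clusters: int, seed: int) -> np.ndarray:
    if n_clusters == 1:
        return np.zeros(vecs.shape[0], dtype=int)
    emb = vecs[:, :n_clusters]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    return KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(emb).labels_


def infer_n_communities(
    graph: PatternGraph,
    rng_seed: int | np.random.Generator = 0,
    n_restarts: int = 10,
    b_max: int | None = None,
) -> int:
    """Most likely community count by DC-SBM description-length minimisation.

    The search combines (a) a sweep of spectral partitions at every
    candidate block count, scored directly, and (b) greedy agglomerative
    merge hierarchies started from seeded spectral partitions at ``b_max``;
    the best description length per block count over all candidates decides.
    """
    rng = np.random.default_rng(rng_seed)
    n = graph.n_nodes
    if b_max is None:
        b_max = max(1, min(50, n // 5))
    b_max = min(b_max, n)
    vecs = _laplacian_embedding(graph.adjacency)
    best: dict[int, float] = {}
    for b in range(1, b_max + 1):
        labels = _embedding_labels(vecs, b, int(rng.integers(2**31 - 1)))
        dl = dcsbm_description_length(graph.adjacency, labels)
        nb = len(np.unique(labels))
        if dl < best.get(nb, np.inf):
            best[nb] = dl
    for _ in range(n_restarts):
        seed = int(rng.integers(2**31 - 1))
        labels = _embedding_labels(vecs, b_max, seed)
        for nb, dl in _merge_hierarchy_dl(graph.adjacency, labels).items():
            if dl < best.get(nb, np.inf):
                best[nb] = dl
    return min(best, key=best.get)


def spectral_split(
    graph: PatternGraph,
    n_communities: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Normalised-Laplacian spectral clustering into ``n_communities`` groups."""
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    n = graph.n_nodes
    if n_communities == 1:
        return np.zeros(n, dtype=int)
    rng = np.random.default_rng(rng_seed)
    A = np.asarray(graph.adjacency.todense(), dtype=float)
    d = A.sum(axis=1)
    d[d == 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    lsym = np.eye(n) - dinv[:, None] * A * dinv[None, :]
    vals, vecs = np.linalg.eigh(lsym)
    emb = vecs[:, :n_communities]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(
        n_clusters=n_communities,
        n_init=10,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(emb)
    return km.labels_


def _binarise_core(patterns: np.ndarray, members: np.ndarray, s: float) -> np.ndarray:
    return (patterns[members].mean(axis=0) >= s).astype(float)


def refine_groups(
    groups: list[np.ndarray],
    patterns: np.ndarray,
    s: float = 1.0 / 5.0,
    p_merge: float = 2.0 / 3.0,
    p_assign: float = 1.0 / 2.0,
    min_size: int = 5,
) -> list[CorePattern]:
    """Multi-stage refinement of spectral groups into core patterns.

    Stages, in order: drop groups with fewer than ``min_size`` patterns;
    drop groups more than 1.5 SD below the mean group size; form
    preliminary cores by binarising group means at ``s``; recursively merge
    core pairs whose similarity ratio exceeds ``p_merge`` (pairs processed
    by descending similarity, lowest-index tie-break, to a fixed point);
    reassign every pattern to its most similar preliminary core when both
    ``p_assign`` conditions hold, else reject it; drop reassigned groups
    more than 1.5 SD below the mean size; average the survivors.
    """
    pats = np.asarray(patterns, dtype=float)
    groups = [np.asarray(g) for g in groups if len(g) >= min_size]
    if not groups:
        raise DetectionEmpty("all groups below the minimum size")
    sizes = np.array([len(g) for g in groups], dtype=float)
    keep = sizes >= sizes.mean() - 1.5 * sizes.std()
    groups = [g for g, k in zip(groups, keep) if k]
    if not groups:
        raise DetectionEmpty("all groups rejected by the size filter")

    cores = [_binarise_core(pats, g, s) for g in groups]
    # recursive pairwise merging to a fixed point
    while len(cores) > 1:
        best = None  # (similarity, i, j)
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                a, b = cores[i], cores[j]
                na, nb = a @ a, b @ b
                if na == 0 or nb == 0:
                    continue
                ratio = min((a @ b) / na, (a @ b) / nb)
                if ratio > p_merge and (best is None or ratio > best[0]):
                    best = (ratio, i, j)
        if best is None:
            break
        _, i, j = best
        merged = np.concatenate([groups[i], groups[j]])
        groups = [g for idx, g in enumerate(groups) if idx not in (i, j)] + [merged]
        cores = [c for idx, c in enumerate(cores) if idx not in (i, j)] + [
            _binarise_core(pats, merged, s)
        ]

    # reassignment of every activity pattern against the preliminary cores
    new_groups: list[list[int]] = [[] for _ in cores]
    core_norms = np.array([c @ c for c in cores])
    for tau in range(len(pats)):
        x = pats[tau]
        xn = x @ x
        best_i, best_sim = None, -np.inf
        for i, c in enumerate(cores):
            if core_norms[i] == 0:
                continue
            sim = (c @ x) / core_norms[i]
            if sim > p_assign and xn / core_norms[i] > p_assign and sim > best_sim:
                best_i, best_sim = i, sim
        if best_i is not None:
            new_groups[best_i].append(tau)
    survivors = [np.asarray(g) for g in new_groups if len(g) > 0]
    if not survivors:
        raise DetectionEmpty("no pattern assigned to any preliminary core")
    sizes = np.array([len(g) for g in survivors], dtype=float)
    keep = sizes >= sizes.mean() - 1.5 * sizes.std()
    survivors = [g for g, k in zip(survivors, keep) if k]
    if not survivors:
        raise DetectionEmpty("all refined groups rejected by the size filter")
    return [
        CorePattern(alpha=pats[g].mean(axis=0), member_patterns=g) for g in survivors
    ]


def cores_to_assemblies(
    cores: list[CorePattern], s: float = 1.0 / 5.0
) -> AssemblyConfiguration:
    """Neuron n joins assembly r iff its affinity alpha_r(n) >= s."""
    assemblies = []
    for core in cores:
        members = np.flatnonzero(core.alpha >= s)
        if members.size == 0:
            continue
        assemblies.append(Assembly(frozenset(int(i) for i in members)))
    return AssemblyConfiguration(assemblies=assemblies)


def detect_sgc(
    dff,
    rng_seed: int = 0,
    n_perm: int = 1000,
    percentile: float = 0.95,
    affinity_s: float = 1.0 / 5.0,
    n_restarts: int = 10,
):
    """Full SGC pipeline on a ΔF/F matrix (empty configuration when nothing survives)."""
    x = dff.dff if hasattr(dff, "dff") else np.asarray(dff, dtype=float)
    rng = np.random.default_rng(rng_seed)
    binary = binarize_dff(x)
    pattern_set = select_high_activity(
        binary, n_perm=n_perm, percentile=percentile, rng_seed=rng
    )
    try:
        graph = build_knn_graph(pattern_set)
        n_comm = infer_n_communities(graph, rng_seed=rng, n_restarts=n_restarts)
        labels = spectral_split(graph, n_comm, rng_seed=rng)
        groups = [np.flatnonzero(labels == c) for c in np.unique(labels)]
        cores = refine_groups(groups, pattern_set.patterns, s=affinity_s)
    except DetectionEmpty:
        return AssemblyConfiguration(assemblies=[])
    return cores_to_assemblies(cores, s=affinity_s)
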