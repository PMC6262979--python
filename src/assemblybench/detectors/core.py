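"""CORE assembly detector: similarity-based core ensembles + Hamming k-means.

High-coactivity patterns (from deconvolved, thresholded ΔF/F) are compared
pairwise with Pearson correlation against a 50 000-draw permutation null;
each pattern's significantly-similar set is averaged and binarised at 1/2
into a core ensemble.  Core ensembles are clustered with Hamming-distance
k-means, the cluster count picked by the best silhouette over seeded
rounds, and per-cluster mean patterns thresholded at 1/2 give the
assemblies.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score

from ..arrays import Assembly, AssemblyConfiguration
from ..preprocess import ActivityPatternSet, deconvolve_binarize, select_high_activity
from ..simulate import SimulationParams

__all__ = [
    "similar_ensembles",
    "build_core_ensembles",
    "cluster_cores",
    "detect_core",
]


def _pearson_null_threshold(
    patterns: np.ndarray,
    active: np.ndarray,
    n_perm: int,
    percentile: float,
    rng: np.random.Generator,
) -> float:
    """Permutation-null 95th percentile of Pearson r between binary patterns.

    Under independent entry permutations of two binary patterns with a and
    b active entries, the overlap is Hypergeometric(N, a, b) and r is a
    deterministic function of it — the null is sampled from that exact law.
    """
    n = patterns.shape[1]
    counts = patterns[active].sum(axis=1)
    i = rng.integers(0, len(counts), size=n_perm)
    j = rng.integers(0, len(counts), size=n_perm)
    a, b = counts[i].astype(float), counts[j].astype(float)
    o = rng.hypergeometric(a.astype(int), (n - a).astype(int), b.astype(int))
    denom = np.sqrt(a * (n - a) * b * (n - b))
    r = (n * o - a * b) / np.where(denom > 0, denom, 1.0)
    return float(np.percentile(r, 100.0 * percentile))


def similar_ensembles(
    patterns: ActivityPatternSet | np.ndarray,
    n_perm: int = 50_000,
    percentile: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Per-pattern sets of significantly-correlated patterns (self included).

    Constant patterns (all active or all inactive) have undefined
    correlation and are excluded with a warning; their similarity set is
    just themselves.
    """
    pats = patterns.patterns if isinstance(patterns, ActivityPatternSet) else patterns
    pats = np.asarray(pats)
    if len(pats) < 2:
        raise ValueError("need at least 2 patterns")
    rng = np.random.default_rng(rng_seed)
    sums = pats.sum(axis=1)
    active = (sums > 0) & (sums < pats.shape[1])
    if (~active).any():
        warnings.warn(
            f"{int((~active).sum())} constant pattern(s) excluded from correlation"
        )
    threshold = _pearson_null_threshold(pats, active, n_perm, percentile, rng)
    x = pats.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[~active, :] = -np.inf
    corr[:, ~active] = -np.inf
    out = []
    for tau in range(len(pats)):
        similar = np.flatnonzero(corr[tau] > threshold)
        similar = similar[similar != tau]
        out.append(np.r_[tau, similar])
    return out


def build_core_ensembles(
    patterns: ActivityPatternSet | np.ndarray,
    similarity_sets: list[np.ndarray],
    s: float = 0.5,
) -> np.ndarray:
    """Core ensemble per pattern: mean over its similarity set, binarised at s."""
    pats = patterns.patterns if isinstance(patterns, ActivityPatternSet) else patterns
    pats = np.asarray(pats, dtype=float)
    cores = np.empty_like(pats[: len(similarity_sets)])
    for tau, members in enumerate(similarity_sets):
        cores[tau] = pats[members].mean(axis=0) >= s
    return cores.astype(np.uint8)


def _kmeans_hamming(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100
) -> np.ndarray:
    """Binary k-means under Hamming distance with majority-vote centroids.

    Assignment ties go to the lowest centroid index (argmin); centroid bits
    tied at exactly 0.5 are set to 0.  The objective is non-increasing.
    """
    n = len(X)
    centroids = X[rng.choice(n, size=k, replace=False)].astype(np.uint8)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        dist = (X[:, None, :] != centroids[None, :, :]).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = X[labels == c]
            if len(members) == 0:
                centroids[c] = X[rng.integers(n)]
            else:
                centroids[c] = (members.mean(axis=0) > 0.5).astype(np.uint8)
    return labels


def cluster_cores(
    cores: np.ndarray,
    k_range: range | None = None,
    n_rounds: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    affinity_s: float = 0.5,
) -> AssemblyConfiguration:
    """Silhouette-selected Hamming k-means of core ensembles into assemblies.

    For each k the best of ``n_rounds`` seeded runs (by mean silhouette on
    Hamming distances) is kept; the best k is refined with another
    ``n_rounds`` runs; assemblies are the per-cluster mean core patterns
    thresholded at ``affinity_s``.
    """
    cores = np.asarray(cores)
    if len(cores) < 2:
        raise ValueError("need at least 2 core ensembles")
    rng = np.random.default_rng(rng_seed)
    unique = np.unique(cores, axis=0)
    if len(unique) == 1:
        # degenerate: a single assembly
        members = np.flatnonzero(unique[0] >= affinity_s)
        return AssemblyConfiguration(
            assemblies=[Assembly(frozenset(int(i) for i in members))]
            if members.size
            else []
        )
    if k_range is None:
        k_range = range(2, min(20, len(unique) - 1) + 1)
    ks = [k for k in k_range]
    if ks == [1]:
        # forced single cluster: silhouette is undefined, average everything
        alpha = cores.mean(axis=0)
        members = np.flatnonzero(alpha >= affinity_s)
        return AssemblyConfiguration(
            assemblies=[Assembly(frozenset(int(i) for i in members))]
            if members.size
            else []
        )
    dist = (cores[:, None, :] != cores[None, :, :]).sum(axis=2).astype(float)

    def best_of(k: int, rounds: int) -> tuple[float, np.ndarray | None]:
        best_score, best_labels = -np.inf, None
        for _ in range(rounds):
            labels = _kmeans_hamming(cores, k, rng)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score:
                best_score, best_labels = score, labels
        return best_score, best_labels

    scores = {}
    for k in k_range:
        if k >= len(cores):
            continue
        scores[k], _ = best_of(k, n_rounds)
    if not scores:
        raise ValueError("k_range contains no feasible cluster count")
    k_star = max(scores, key=scores.get)
    _, labels = best_of(k_star, n_rounds)
    if labels is None:
        raise ValueError("k-means failed to produce a non-trivial clustering")
    assemblies = []
    for c in np.unique(labels):
        alpha = cores[labels == c].mean(axis=0)
        members = np.flatnonzero(alpha >= affinity_s)
        if members.size:
            assemblies.append(Assembly(frozenset(int(i) for i in members)))
    return AssemblyConfiguration(assemblies=assemblies)


def detect_core(
    dff,
    params: SimulationParams | None = None,
    rng_seed: int = 0,
    n_perm_coactivity: int = 1000,
    percentile_coactivity: float = 0.95,
    n_perm_corr: int = 50_000,
    n_rounds: int = 1000,
    k_range: range | None = None,
):
    """Full CORE pipeline on a ΔF/F matrix."""
    if params is None:
        params = SimulationParams()
    rng = np.random.default_rng(rng_seed)
    binary = deconvolve_binarize(dff, params)
    pattern_set = select_high_activity(
        binary, n_perm=n_perm_coactivity, percentile=percentile_coactivity,
        rng_seed=rng,
    )
    if len(pattern_set) < 2:
        return AssemblyConfiguration(assemblies=[])
    sets = similar_ensembles(pattern_set, n_perm=n_perm_corr, rng_seed=rng)
    cores = build_core_ensembles(pattern_set, sets)
    nonzero = cores.any(axis=1)
    cores = cores[nonzero]
    if len(cores) < 2:
        return AssemblyConfiguration(assemblies=[])
    return cluster_cores(cores, k_range=k_range, n_rounds=n_rounds, rng_seed=rng)
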