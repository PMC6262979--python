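"""Best-Match scoring of assembly configurations, with analytic chance level.

The Best-Match distance between two clusterings sums, both ways, each
cluster's minimal Jaccard distance to the other clustering; the score
normalises it to [0, 1] (1 = identical collections).  Because random subset
intersections are hypergeometric, the expected score between uniformly
random configurations has a closed form, which serves as the chance level
on every benchmark curve.  A greedy optimal sub-clustering bounds the score
from the "best matching subset" side, and a reference-configuration
estimator recovers stimulus-evoked assemblies from trial-averaged
responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .arrays import AssemblyConfiguration, Assembly

__all__ = [
    "BestMatchReport",
    "set_difference_measure",
    "best_match_score",
    "chance_level",
    "optimal_best_match",
    "reference_configuration",
    "score_report",
]


@dataclass
class BestMatchReport:
    """Score, optimal score, chance level and the matched pairs."""

    score: float
    optimal_score: float
    chance_level: float
    matched_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    no_assemblies: bool = False


def _as_sets(config) -> list[frozenset[int]]:
    if isinstance(config, AssemblyConfiguration):
        return config.member_sets()
    return [frozenset(a) for a in config]


def set_difference_measure(a, b) -> float:
    """Jaccard distance d(A, A') = 1 − |A∩A'| / |A∪A'|."""
    sa = a.members if isinstance(a, Assembly) else frozenset(a)
    sb = b.members if isinstance(b, Assembly) else frozenset(b)
    if not sa or not sb:
        raise ValueError("set difference undefined for empty sets")
    return 1.0 - len(sa & sb) / len(sa | sb)


def best_match_distance(truth, found) -> float:
    """Two-way sum of minimal Jaccard distances between the collections."""
    ts, fs = _as_sets(truth), _as_sets(found)
    if not ts or not fs:
        raise ValueError("both configurations must be non-empty")
    d = np.array([[set_difference_measure(a, b) for b in fs] for a in ts])
    return float(d.min(axis=1).sum() + d.min(axis=0).sum())


def best_match_score(truth, found, flag_empty: bool = True) -> float:
    """Best-Match score = 1 − BestMatch_d / (|truth| + |found|), in [0, 1].

    An empty ``found`` scores 0 (with a warning) so that benchmark curves
    over detector failures stay plottable.
    """
    ts, fs = _as_sets(truth), _as_sets(found)
    if not ts:
        raise ValueError("truth configuration must be non-empty")
    if not fs:
        if flag_empty:
            warnings.warn("no assemblies found; score set to 0")
        return 0.0
    return 1.0 - best_match_distance(ts, fs) / (len(ts) + len(fs))


def _dist_pmf_min(
    N: int,
    sizes_a: Mapping[int, float],
    sizes_b: Mapping[int, float],
    m: int,
) -> float:
    """E[min over m i.i.d. random sets B of d(A, B)] for random A.

    d(A,B) = 1 − i/(n_a+n_b−i) with i ~ Hypergeom(N, n_a, n_b); sizes are
    distributions over set cardinalities.  The min law is
    P[min = u] = P[d ≥ u]^m − P[d > u]^m.
    """
    pmf: dict[float, float] = {}
    for na, pa in sizes_a.items():
        for nb, pb in sizes_b.items():
            imax = min(na, nb)
            imin = max(0, na + nb - N)
            for i in range(imin, imax + 1):
                u = round(1.0 - i / (na + nb - i), 12)
                p = pa * pb * stats.hypergeom.pmf(i, N, na, nb)
                pmf[u] = pmf.get(u, 0.0) + p
    us = np.array(sorted(pmf))
    ps = np.array([pmf[u] for u in us])
    ps = ps / ps.sum()
    # P[d >= u] and P[d > u] on the discrete support
    tail_ge = np.cumsum(ps[::-1])[::-1]
    tail_gt = tail_ge - ps
    p_min = tail_ge**m - tail_gt**m
    return float((us * p_min).sum())


def _size_dist(sizes: Sequence[int] | Mapping[int, float]) -> dict[int, float]:
    if isinstance(sizes, Mapping):
        total = sum(sizes.values())
        return {int(k): v / total for k, v in sizes.items()}
    vals, counts = np.unique(np.asarray(sizes, dtype=int), return_counts=True)
    return {int(v): c / counts.sum() for v, c in zip(vals, counts)}


def chance_level(
    N: int,
    size_dist_truth: Sequence[int] | Mapping[int, float],
    size_dist_found: Sequence[int] | Mapping[int, float],
    n_truth: int,
    n_found: int,
) -> float:
    """Exact expected Best-Match score between uniformly random configurations.

    ``size_dist_*`` give the set-size distributions (list of sizes or
    size -> probability); ``n_truth``/``n_found`` the collection sizes.
    """
    da = _size_dist(size_dist_truth)
    db = _size_dist(size_dist_found)
    if any(k > N or k < 1 for k in list(da) + list(db)):
        raise ValueError("set sizes must lie in 1..N")
    e_min_a = _dist_pmf_min(N, da, db, n_found)   # E[min_{A'} d(A, A')]
    e_min_b = _dist_pmf_min(N, db, da, n_truth)   # E[min_{A} d(A', A)]
    return 1.0 - (n_truth * e_min_a + n_found * e_min_b) / (n_truth + n_found)


def optimal_best_match(
    truth,
    found,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, list[int]]:
    """Greedy optimal sub-clustering score.

    Repeatedly pick the (truth, found) pair at minimal Jaccard distance
    (random tie-break) without replacement, for min(|truth|, |found|)
    rounds; the optimal score is the Best-Match score between truth and the
    selected found subset.  Returns (score, selected found indices).
    """
    ts, fs = _as_sets(truth), _as_sets(found)
    if not ts or not fs:
        raise ValueError("both configurations must be non-empty")
    rng = np.random.default_rng(rng_seed)
    d = np.array([[set_difference_measure(a, b) for b in fs] for a in ts])
    avail_t = np.ones(len(ts), dtype=bool)
    avail_f = np.ones(len(fs), dtype=bool)
    selected: list[int] = []
    for _ in range(min(len(ts), len(fs))):
        sub = d[np.ix_(avail_t, avail_f)]
        mn = sub.min()
        cand = np.argwhere(sub == mn)
        pick = cand[rng.integers(len(cand))]
        t_idx = np.flatnonzero(avail_t)[pick[0]]
        f_idx = np.flatnonzero(avail_f)[pick[1]]
        selected.append(int(f_idx))
        avail_t[t_idx] = False
        avail_f[f_idx] = False
    subset = [fs[i] for i in selected]
    return best_match_score(ts, subset), selected


def score_report(
    truth,
    found,
    N: int,
    rng_seed: int | np.random.Generator = 0,
) -> BestMatchReport:
    """Full report: score, optimal score, analytic chance level, matched pairs."""
    ts, fs = _as_sets(truth), _as_sets(found)
    if not fs:
        return BestMatchReport(
            score=0.0, optimal_score=0.0, chance_level=np.nan, no_assemblies=True
        )
    score = best_match_score(ts, fs)
    optimal, _ = optimal_best_match(ts, fs, rng_seed)
    chance = chance_level(
        N,
        [len(s) for s in ts],
        [len(s) for s in fs],
        len(ts),
        len(fs),
    )
    d = np.array([[set_difference_measure(a, b) for b in fs] for a in ts])
    pairs = [
        (i, int(d[i].argmin()), float(d[i].min())) for i in range(len(ts))
    ]
    return BestMatchReport(
        score=score, optimal_score=optimal, chance_level=chance, matched_pairs=pairs
    )


def reference_configuration(
    dff,
    stimulus_onsets: Mapping[int, Sequence[int]] | Sequence[Sequence[int]],
    p: float = 2.0,
    response_frames: tuple[int, int] = (3, 7),
) -> AssemblyConfiguration:
    """Stimulus-evoked reference assemblies from trial-averaged responses.

    Per stimulus, the response is the mean ΔF/F over frames 3–7 after each
    onset (1-based, the onset frame being frame 1), averaged over
    repetitions; a neuron joins the assembly of stimulus s when its average
    response there exceeds its mean + p·SD across all stimuli.  Onsets too
    close to the end of the recording are skipped with a warning.
    """
    x = dff.dff if hasattr(dff, "dff") else np.asarray(dff, dtype=float)
    onset_lists = (
        list(stimulus_onsets.values())
        if isinstance(stimulus_onsets, Mapping)
        else list(stimulus_onsets)
    )
    if len(onset_lists) < 2:
        raise ValueError("need at least 2 stimuli")
    lo, hi = response_frames
    n_bins = x.shape[1]
    responses = []
    for onsets in onset_lists:
        reps = []
        for onset in onsets:
            start, stop = onset + lo - 1, onset + hi  # 1-based inclusive window
            if stop > n_bins or onset < 0:
                warnings.warn(f"onset {onset} too close to recording end; skipped")
                continue
            reps.append(x[:, start:stop].mean(axis=1))
        if not reps:
            raise ValueError("a stimulus has no usable repetitions")
        responses.append(np.mean(reps, axis=0))
    resp = np.column_stack(responses)  # neurons x stimuli
    mu = resp.mean(axis=1, keepdims=True)
    sd = resp.std(axis=1, keepdims=True)
    member = resp > mu + p * sd
    assemblies = [
        Assembly(frozenset(int(i) for i in np.flatnonzero(member[:, s])))
        for s in range(resp.shape[1])
    ]
    return AssemblyConfiguration(
        assemblies=[a for a in assemblies if len(a) > 0]
    )
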