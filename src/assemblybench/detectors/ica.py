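"""PCA/ICA assembly detectors on the neuron-neuron correlation matrix.

Both variants z-score each neuron's ΔF/F trace, take the eigenspectrum of
the autocorrelation matrix (1/P)·XXᵀ and keep the components whose
eigenvalues exceed a null threshold: either the 95th percentile of a
circular-shift surrogate spectrum (ICA-CS) or the analytic upper edge of
the Marčenko-Pastur distribution (ICA-MP).  The retained components are
rotated with fastICA into assembly vectors, ICA-MP additionally discards
vectors whose z-scored loadings are indistinguishable from a standard
normal (one-sample KS test at alpha=1e-10), and members are the neurons
whose |loading| exceeds mean + 2 SD of that vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ..arrays import Assembly, AssemblyConfiguration

__all__ = [
    "EigenReport",
    "zscore_rows",
    "circular_shift_null",
    "mp_threshold",
    "ica_rotate",
    "ks_filter",
    "threshold_vectors",
    "detect_ica",
]


@dataclass
class EigenReport:
    """Eigenspectrum of (1/P)XXᵀ with its null threshold."""

    eigenvalues: np.ndarray       # descending
    null_threshold: float
    n_significant: int
    significant_components: np.ndarray  # (N, n_significant) loading vectors


def zscore_rows(dff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (X, kept_row_indices).

    Zero-variance rows carry no correlation information and are dropped
    with a warning.
    """
    x = np.asarray(dff, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 bins")
    sd = x.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < x.shape[0]:
        warnings.warn(f"dropping {x.shape[0] - kept.size} zero-variance row(s)")
    xk = x[kept]
    return (xk - xk.mean(axis=1, keepdims=True)) / sd[kept, None], kept


def _spectrum(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of (1/P)XXᵀ, ascending (numpy eigh order)."""
    P = X.shape[1]
    return np.linalg.eigvalsh(X @ X.T / P)


def circular_shift_null(
    X: np.ndarray,
    n_rounds: int = 500,
    percentile: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
) -> float:
    """Null eigenvalue threshold from per-neuron circular shifts.

    Each round circularly shifts every row by an independent uniform offset
    (preserving each neuron's autocorrelation, destroying cross-neuron
    correlation), computes the eigenspectrum, and the null distribution is
    the round-averaged sorted spectrum; the threshold is its stated
    percentile.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(rng_seed)
    N, P = X.shape
    cols = np.arange(P)
    acc = np.zeros(N)
    for _ in range(n_rounds):
        offsets = rng.integers(0, P, size=N)
        idx = (cols[None, :] - offsets[:, None]) % P
        Xs = np.take_along_axis(X, idx, axis=1)
        acc += _spectrum(Xs)
    mean_spectrum = acc / n_rounds
    return float(np.percentile(mean_spectrum, 100.0 * percentile))


def mp_threshold(N: int, P: int) -> float:
    """Upper Marčenko-Pastur support edge (1 + sqrt(N/P))² for unit-variance rows."""
    if P <= 0:
        raise ValueError("P must be positive")
    if not (0 < N < P):
        raise ValueError("requires P > N >= 1")
    return (1.0 + np.sqrt(N / P)) ** 2


def ica_rotate(
    components: np.ndarray,
    X: np.ndarray,
    n_iter: int = 500,
    rng_seed: int | np.random.Generator = 0,
    max_restarts: int = 3,
) -> np.ndarray:
    """Rotate significant PCs into assembly vectors with fastICA.

    ``components`` is (N, m); fastICA (tanh/logcosh contrast, symmetric
    decorrelation) runs on the data projected into the PC subspace, and the
    mixing matrix maps the sources back to neuron space.  Each returned row
    is unit-norm with its largest-magnitude entry positive, and lies in the
    span of the input components by construction.
    """
    comps = np.atleast_2d(np.asarray(components, dtype=float))
    if comps.shape[1] == 0:
        raise ValueError("need at least one significant component")
    rng = np.random.default_rng(rng_seed)
    m = comps.shape[1]
    if m == 1:
        vecs = comps.T.copy()
    else:
        Y = (comps.T @ X).T  # (P, m) projection onto the significant subspace
        mixing = None
        for attempt in range(max_restarts):
            seed = int(rng.integers(2**31 - 1))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                ica = FastICA(
                    n_components=m,
                    fun="logcosh",
                    max_iter=n_iter,
                    whiten="unit-variance",
                    random_state=seed,
                )
                ica.fit(Y)
                converged = not any(
                    issubclass(w.category, ConvergenceWarning) for w in caught
                )
            mixing = ica.mixing_
            if converged:
                break
        else:
            warnings.warn("fastICA did not converge; using best iterate")
        vecs = (comps @ mixing).T  # (m, N)
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    vecs = vecs / np.where(norms > 0, norms, 1.0)
    for v in vecs:
        if v[np.argmax(np.abs(v))] < 0:
            v *= -1.0
    return vecs


def ks_filter(vectors: np.ndarray, alpha: float = 1e-10) -> np.ndarray:
    """Keep vectors whose z-scored loadings reject standard normality (KS)."""
    keep = []
    for v in np.atleast_2d(vectors):
        sd = v.std()
        if sd == 0:
            continue
        z = (v - v.mean()) / sd
        if stats.kstest(z, "norm").pvalue < alpha:
            keep.append(v)
    return np.array(keep) if keep else np.empty((0, np.atleast_2d(vectors).shape[1]))


def threshold_vectors(
    vectors: np.ndarray,
    neuron_indices: np.ndarray | None = None,
) -> AssemblyConfiguration:
    """Members = neurons with |loading| > mean + 2 SD of that vector.

    ``neuron_indices`` maps vector positions back to original neuron ids
    (identity when omitted); empty member sets are dropped.
    """
    vecs = np.atleast_2d(vectors)
    assemblies = []
    for v in vecs:
        a = np.abs(v)
        thr = a.mean() + 2.0 * a.std()
        members = np.flatnonzero(a > thr)
        if members.size == 0:
            continue
        if neuron_indices is not None:
            members = neuron_indices[members]
        assemblies.append(Assembly(frozenset(int(i) for i in members)))
    return AssemblyConfiguration(assemblies=assemblies)


def detect_ica(
    dff,
    variant: str = "MP",
    rng_seed: int = 0,
    n_rounds: int = 500,
    percentile: float = 0.95,
    n_iter: int = 500,
    ks_alpha: float = 1e-10,
    return_report: bool = False,
):
    """Full ICA-CS / ICA-MP pipeline on a ΔF/F matrix."""
    if variant not in ("CS", "MP"):
        raise ValueError("variant must be 'CS' or 'MP'")
    x = dff.dff if hasattr(dff, "dff") else np.asarray(dff, dtype=float)
    rng = np.random.default_rng(rng_seed)
    X, kept = zscore_rows(x)
    N, P = X.shape
    eigvals, eigvecs = np.linalg.eigh(X @ X.T / P)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    if variant == "CS":
        threshold = circular_shift_null(X, n_rounds, percentile, rng)
    else:
        threshold = mp_threshold(N, P)
    sig = eigvals > threshold
    report = EigenReport(
        eigenvalues=eigvals,
        null_threshold=float(threshold),
        n_significant=int(sig.sum()),
        significant_components=eigvecs[:, sig],
    )
    if report.n_significant == 0:
        config = AssemblyConfiguration(assemblies=[])
        return (config, report) if return_report else config
    vectors = ica_rotate(report.significant_components, X, n_iter=n_iter, rng_seed=rng)
    if variant == "MP":
        vectors = ks_filter(vectors, alpha=ks_alpha)
    config = threshold_vectors(vectors, neuron_indices=kept)
    return (config, report) if return_report else config
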