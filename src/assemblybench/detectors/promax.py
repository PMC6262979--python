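"""Promax-rotation assembly detectors (Promax-MP / Promax-CS).

Unlike the ICA detectors these first fit a per-neuron Gaussian noise model
to ΔF/F, keep only the statistically significant calcium transients
(zeroing everything else), and then run PCA on the cleaned matrix.  The
significant-component threshold is either the Marčenko-Pastur edge with a
Tracy-Widom finite-size correction (MP variant) or a circular-shift null
(CS variant).  The retained components are rotated obliquely with Promax
(power 4); a neuron joins the assembly of its largest z-scored loading if
that loading exceeds a cut-off found as the first local minimum of the
kernel-smoothed distribution of maximal loadings.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal, stats

from ..arrays import Assembly, AssemblyConfiguration
from ..simulate import SimulationParams
from .ica import circular_shift_null, mp_threshold, zscore_rows

__all__ = [
    "NoiseModelError",
    "clean_transients",
    "tw_mp_threshold",
    "varimax",
    "promax",
    "zmax_cutoff",
    "detect_promax",
]

#: 95th percentile of the Tracy-Widom TW1 distribution.
_TW1_Q95 = 0.9793


class NoiseModelError(RuntimeError):
    """The Gaussian noise model cannot be fitted to the fluorescence data."""


def _noise_sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row noise SD from below-median fluctuations (half-normal fit)."""
    med = np.median(x, axis=1)
    sd = np.empty(len(x))
    for i, row in enumerate(x):
        below = row[row <= med[i]] - med[i]
        sd[i] = math.sqrt(np.mean(below**2)) if below.size else 0.0
    return med, sd


def clean_transients(
    dff: np.ndarray,
    params: SimulationParams,
    confidence: float = 0.95,
) -> np.ndarray:
    """Zero every sample not belonging to a significant calcium transient.

    Noise is modelled per neuron as Gaussian with SD estimated from the
    below-median fluctuations.  Candidate transients are maximal runs above
    median + z(confidence)·SD; a run of length L is significant when either
    noise alone is unlikely to sustain the run (n_bins·(1−conf)^L < 1−conf)
    or its peak clears the length-adjusted amplitude threshold
    median + SD·Φ⁻¹(1 − ((1−conf)/n_bins)^{1/L}).  The indicator decay
    constant τ½/ln2 sets the shortest credible transient; when it falls
    below half a frame the model is declared unfittable.

    Raises :class:`NoiseModelError` when the decay time cannot be resolved
    or almost no neuron carries a significant transient.
    """
    x = np.asarray(dff, dtype=float)
    n_neurons, n_bins = x.shape
    decay_const = params.tau_half / math.log(2.0)
    if decay_const < params.dT / 2.0:
        raise NoiseModelError(
            "indicator decay time is below the temporal resolution; "
            "noise model cannot be fitted"
        )
    min_frames = max(1, int(round(0.5 * decay_const / params.dT)))
    z_base = stats.norm.ppf(confidence)
    alpha = 1.0 - confidence
    # run length beyond which noise alone cannot plausibly sustain the run
    auto_len = 1 + math.log(n_bins) / (-math.log(alpha))
    med, sd = _noise_sd(x)
    # ΔF/F cannot fall below -1 (fluorescence is non-negative); a Gaussian
    # noise model whose lower confidence tail crosses that floor is
    # internally inconsistent at the working significance level
    typical_sd = float(np.median(sd[sd > 0])) if (sd > 0).any() else 0.0
    if typical_sd > 1.0 / z_base:
        raise NoiseModelError(
            f"estimated noise SD {typical_sd:.2f} dF/F units places more than "
            f"{1 - confidence:.0%} of the Gaussian below the dF/F floor of -1; "
            "noise model cannot be fitted"
        )
    cleaned = np.zeros_like(x)
    n_active = 0
    for i in range(n_neurons):
        if sd[i] == 0:
            continue
        above = x[i] > med[i] + z_base * sd[i]
        if not above.any():
            continue
        # maximal runs of consecutive supra-threshold samples
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            ends = np.r_[ends, n_bins]
        any_sig = False
        for s, e in zip(starts, ends):
            length = e - s
            if length < min_frames:
                continue
            if length >= auto_len:
                sig = True
            else:
                p_tail = (alpha / n_bins) ** (1.0 / length)
                theta = med[i] + sd[i] * stats.norm.ppf(1.0 - p_tail)
                sig = x[i, s:e].max() > theta
            if sig:
                cleaned[i, s:e] = x[i, s:e]
                any_sig = True
        n_active += any_sig
    if n_active < max(2, int(0.05 * n_neurons)):
        raise NoiseModelError(
            f"significant transients found for only {n_active} of "
            f"{n_neurons} neurons; noise model cannot be fitted"
        )
    return cleaned


def tw_mp_threshold(N: int, P: int, quantile_tw1: float = _TW1_Q95) -> float:
    """Marčenko-Pastur upper edge with Tracy-Widom finite-size correction.

    The largest eigenvalue of a white-Wishart spectrum fluctuates around
    the MP edge on the scale σ_NP = (√N+√P)/P·(1/√N+1/√P)^{1/3}; the edge
    is inflated by the TW1 95th percentile times that scale.
    """
    edge = mp_threshold(N, P)
    sigma_np = (math.sqrt(N) + math.sqrt(P)) / P * (
        1.0 / math.sqrt(N) + 1.0 / math.sqrt(P)
    ) ** (1.0 / 3.0)
    return edge + quantile_tw1 * sigma_np


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation of a (N, m) loading matrix."""
    L = np.asarray(loadings, dtype=float)
    n, m = L.shape
    if m < 2:
        return L.copy()
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / n)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R


def promax(loadings: np.ndarray, power: int = 4) -> np.ndarray:
    """Oblique Promax rotation (varimax start, target |Λ|^{power−1}·Λ)."""
    L = varimax(loadings)
    m = L.shape[1]
    if m < 2:
        return L
    target = np.abs(L) ** (power - 1) * L
    Q = np.linalg.lstsq(L, target, rcond=None)[0]
    d = np.diag(np.linalg.inv(Q.T @ Q))
    Q = Q * np.sqrt(d)[None, :]
    return L @ Q


def zmax_cutoff(
    zmax: np.ndarray,
    n_grid: int = 10_000,
    bandwidth_factor: float = 0.5,
    fallback_percentile: float = 95.0,
) -> float:
    """Cut-off = first local minimum of the KDE-smoothed max-loading density.

    The density of per-neuron maximal z-scored loadings is smoothed with a
    Gaussian KDE at half the standard (Scott) bandwidth on a 10 000-point
    grid.  If the density has no interior local minimum the cut-off falls
    back to a global percentile with a warning (unattended mode).
    """
    zmax = np.asarray(zmax, dtype=float)
    if zmax.size < 3 or np.ptp(zmax) == 0:
        warnings.warn("degenerate max-loading distribution; percentile fallback")
        return float(np.percentile(zmax, fallback_percentile))
    kde = stats.gaussian_kde(zmax)
    kde.set_bandwidth(kde.factor * bandwidth_factor)
    grid = np.linspace(zmax.min(), zmax.max(), n_grid)
    dens = kde(grid)
    # first *genuine* valley: shallow half-bandwidth wiggles are ignored by
    # requiring a minimal prominence relative to the density range
    minima, _ = signal.find_peaks(
        -dens, prominence=0.10 * (dens.max() - dens.min())
    )
    if minima.size == 0:
        warnings.warn("no local minimum in max-loading density; percentile fallback")
        return float(np.percentile(zmax, fallback_percentile))
    return float(grid[minima[0]])


def detect_promax(
    dff,
    variant: str = "MP",
    params: SimulationParams | None = None,
    rng_seed: int = 0,
    n_rounds: int = 500,
    percentile: float = 0.95,
    confidence: float = 0.95,
    power: int = 4,
):
    """Full Promax-MP / Promax-CS pipeline on a ΔF/F matrix.

    Raises :class:`NoiseModelError` when the transient noise model cannot
    be fitted (the harness records such runs as ``no_result``).
    """
    if variant not in ("CS", "MP"):
        raise ValueError("variant must be 'CS' or 'MP'")
    if params is None:
        params = SimulationParams()
    x = dff.dff if hasattr(dff, "dff") else np.asarray(dff, dtype=float)
    rng = np.random.default_rng(rng_seed)
    cleaned = clean_transients(x, params, confidence=confidence)
    X, kept = zscore_rows(cleaned)
    N, P = X.shape
    eigvals, eigvecs = np.linalg.eigh(X @ X.T / P)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    if variant == "MP":
        threshold = tw_mp_threshold(N, P)
    else:
        threshold = circular_shift_null(X, n_rounds, percentile, rng)
    sig = eigvals > threshold
    m = int(sig.sum())
    if m == 0:
        return AssemblyConfiguration(assemblies=[])
    loadings = eigvecs[:, sig] * np.sqrt(eigvals[sig])[None, :]
    rotated = promax(loadings, power=power)
    # z-score loadings per component, over neurons
    sd = rotated.std(axis=0)
    sd[sd == 0] = 1.0
    z = (rotated - rotated.mean(axis=0)) / sd
    # orient each component so its dominant tail is positive
    for j in range(z.shape[1]):
        if np.abs(z[:, j].min()) > np.abs(z[:, j].max()):
            z[:, j] *= -1.0
    zmax = z.max(axis=1)
    cutoff = zmax_cutoff(zmax)
    winners = np.argmax(z, axis=1)
    assemblies = []
    for j in range(m):
        members = np.flatnonzero((winners == j) & (zmax > cutoff))
        if members.size == 0:
            continue
        assemblies.append(Assembly(frozenset(int(i) for i in kept[members])))
    return AssemblyConfiguration(assemblies=assemblies)
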