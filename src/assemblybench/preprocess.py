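"""Front-end shared by the pattern-based detectors (SGC / CORE / SVD).

ΔF/F is turned into a binary activity matrix either by direct thresholding
(mean + 2 SD per neuron) or by non-negative deconvolution followed by
thresholding, and the high-coactivity time bins are selected with a
per-neuron permutation test on the coactivity level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import DffMatrix, SimulationParams

__all__ = [
    "BinaryActivity",
    "ActivityPatternSet",
    "binarize_dff",
    "deconvolve_binarize",
    "select_high_activity",
]


@dataclass
class BinaryActivity:
    """Binary activity, neurons x bins, plus the method that produced it."""

    bits: np.ndarray
    method: str


@dataclass
class ActivityPatternSet:
    """High-coactivity binary population vectors with their frame indices."""

    patterns: np.ndarray  # (n_patterns, n_neurons), uint8
    frame_indices: np.ndarray
    coactivity_threshold: float

    def __len__(self) -> int:
        return len(self.patterns)


def binarize_dff(dff: DffMatrix | np.ndarray) -> BinaryActivity:
    """Threshold each neuron's ΔF/F at two SD above its mean."""
    x = dff.dff if isinstance(dff, DffMatrix) else np.asarray(dff, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 bins")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = sd.ravel() == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance neuron(s); rows all zero")
    bits = (x > mu + 2.0 * sd).astype(np.uint8)
    bits[flat] = 0
    return BinaryActivity(bits=bits, method="dff_threshold")


def deconvolve_binarize(
    dff: DffMatrix | np.ndarray,
    params: SimulationParams,
) -> BinaryActivity:
    """Non-negative AR(1) deconvolution, max-normalise, threshold at 3 SD.

    The deconvolved signal is s_t = max(x_t − γ·x_{t−1}, 0) with
    γ = exp(−ln2·ΔT/τ½) — the exact inverse of the exponential calcium
    kernel for clean traces, clipped to non-negative spike "probabilities".
    Each row is divided by its maximum; bits are 1 where the normalised
    value exceeds three standard deviations (computed over the whole row,
    zeros included) from 0.
    """
    x = dff.dff if isinstance(dff, DffMatrix) else np.asarray(dff, dtype=float)
    if params.tau_half > 0:
        gamma = math.exp(-math.log(2.0) * params.dT / params.tau_half)
    else:
        gamma = 0.0
    s = np.empty_like(x)
    s[:, 0] = np.maximum(x[:, 0], 0.0)
    s[:, 1:] = np.maximum(x[:, 1:] - gamma * x[:, :-1], 0.0)
    peak = s.max(axis=1, keepdims=True)
    nz = peak.ravel() > 0
    s[nz] /= peak[nz]
    sd = np.sqrt(np.mean(s**2, axis=1, keepdims=True))  # SD from 0
    bits = (s > 3.0 * sd).astype(np.uint8)
    bits[~nz] = 0
    return BinaryActivity(bits=bits, method="deconv_threshold")


def select_high_activity(
    binary: BinaryActivity | np.ndarray,
    n_perm: int = 1000,
    percentile: float = 0.95,
    rng_seed: int | np.random.Generator = 0,
) -> ActivityPatternSet:
    """Keep bins whose coactivity exceeds a permutation-null percentile.

    The null pools the per-bin coactivity (popcount) over ``n_perm``
    independent permutations of every neuron's binary signal; the threshold
    is the stated percentile of the pooled distribution, and survival is
    strict (> threshold).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bits = binary.bits if isinstance(binary, BinaryActivity) else np.asarray(binary)
    rng = np.random.default_rng(rng_seed)
    coactivity = bits.sum(axis=0)
    n_bins = bits.shape[1]
    null = np.empty((n_perm, n_bins), dtype=np.int64)
    work = bits.copy()
    for p in range(n_perm):
        work = rng.permuted(work, axis=1, out=work)
        null[p] = work.sum(axis=0)
    threshold = float(np.percentile(null.ravel(), 100.0 * percentile))
    keep = coactivity > threshold
    return ActivityPatternSet(
        patterns=bits[:, keep].T.astype(np.uint8).copy(),
        frame_indices=np.flatnonzero(keep),
        coactivity_threshold=threshold,
    )
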