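# Methods

This note documents the models behind `assemblybench`, the parameters
that matter, and the design decisions taken where the procedure was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Ground-truth assembly generation

Neurons occupy a hexagonal lattice of unit spacing; `rings` rings around
the origin give 3·rings² + 3·rings + 1 neurons (default rings = 12 →
469). An assembly is sampled by drawing a centre μ uniformly from a disc
of radius `centre_radius`, scattering `n_draws` points from N(μ, σ²I),
and admitting every neuron whose lattice point lies strictly within
Euclidean distance ½ of at least one point. The strict inequality at the
½ boundary is a determinism convention; the tie set has measure zero.
Empty draws are resampled with a fresh centre.

Positions exist only for generation and plotting. No detector sees them.

**Calibration.** The spatial spread σ, the draw count and the centre-disc
radius are not physical constants; they are calibrated so the generator
reproduces the benchmark's summary statistics. The shipped defaults —
σ = 1.0 lattice units, n_draws = 40, centre_radius = 10.0 on the 12-ring
array — give a mean assembly size of ≈16 neurons over 10⁴ draws, and
k = 10 assemblies typically land in the default mean-overlap window
[0, 0.05] (Szymkiewicz–Simpson coefficient |A∩A′|/min(|A|,|A′|),
averaged over pairs). `calibrate_generator` re-derives such constants
for other targets. Overlap is enforced at the configuration level by
rejection sampling whole configurations (cap 10⁴ attempts, then an
explicit convergence error): the generator controls overlap only
statistically, and the rejection loop turns the statistical tendency
into a guaranteed window. Tighter windows are reached by shrinking
`centre_radius`.

## Calcium-fluorescence simulation

All parameters live in `SimulationParams` (defaults in parentheses):
duration T (3600 s), bin width ΔT (0.5 s), spike resolution δT (1 ms),
indicator half-life τ½ (1 s), saturation constant κ (∞ = off),
background-rate interval R ([1, 6] Hz), event duration ΔT* (0.5 s),
event frequency f* (10 mHz), event rate multiplier λ (6), noise SD σ (0).

1. **Rates.** Each neuron gets a constant background rate r₀ ~ U(R).
   Each assembly — and each neuron belonging to no assembly — receives
   independent Bernoulli(f*·ΔT) event onsets per bin; an onset covers the
   next ⌊ΔT*/ΔT⌋−1 bins deterministically and one further bin with
   probability ΔT*/ΔT − ⌊ΔT*/ΔT⌋, independently per event. During an
   event every member's rate is λ·r₀. A neuron in two simultaneously
   active assemblies still gets λ·r₀ once: the rate model has exactly two
   states per neuron-bin, so elevation does not compound.
2. **Spikes.** Counts per bin are Poisson(r·ΔT); each bin's spikes are
   placed into distinct δT slots uniformly without replacement
   (implemented by collision re-drawing, which reproduces the
   without-replacement law; counts above the slot budget are clipped
   with a warning — unreachable at sane rates).
3. **Fluorescence.** Spikes are convolved with exp(−ln2·t·δT/τ½),
   truncated at lag ⌈2·log₂10·τ½/δT⌉ (i.e. where the kernel reaches
   10⁻²; 6644 samples at defaults), passed through the saturation
   S_κ(x) = κx/(x+κ) (identity at κ=∞), and i.i.d. N(0, σ²) noise is
   added *after* saturation. The trace is then downsampled in steps of
   ΔT/δT (the last δT sample of each bin). A warm-up of 2·τ½ is
   simulated and stripped so the calcium level is stationary from the
   first reported bin. τ½ = 0 collapses the kernel to a single-sample
   impulse (documented limit, not an error).

   *Memory note.* At default scale the fine-resolution trace would be
   469 × 3.6·10⁶ doubles (~13 GB). The spike train is therefore stored
   sparsely and the kernel sum is evaluated exactly at the ΔT sample
   points only; noise is drawn at those points (i.i.d., hence
   distributionally identical to downsampling a dense noise stream). A
   dense path exists for small problems and matches the fast path
   bit-for-bit at σ = 0 (tested); at σ > 0 the two paths consume the
   RNG differently and agree in distribution only.
4. **ΔF/F.** The baseline F₀ is a per-neuron random-walk (local-level)
   state-space fit by Kalman filtering plus RTS smoothing. The
   observation variance is estimated from first differences; the process
   variance is observation variance / w² with width factor w = 15 s/ΔT,
   giving an effective ~15 s averaging window. ΔF/F = (F − F₀)/F₀ with
   F₀ floored at 1 fluorescence a.u. (background spiking keeps true
   baselines ≳ 1.4 at the default rate range; the floor only guards the
   simulation edges). All-zero traces produce ΔF/F = 0 with a warning.

## Shared preprocessing (SGC / CORE / SVD)

* **Direct binarisation** (SGC): bit = 1 where ΔF/F > mean + 2 SD per
  neuron.
* **Deconvolution binarisation** (CORE, SVD): a first-order non-negative
  AR(1) inversion s_t = max(x_t − γ·x_{t−1}, 0) with
  γ = exp(−ln2·ΔT/τ½) — the exact inverse of the calcium kernel for
  clean traces — normalised per neuron to maximum 1 and thresholded at
  three standard deviations from 0 (SD computed over the whole row,
  zeros included).
* **High-coactivity selection:** every neuron's binary signal is
  permuted independently (1000 permutations); the coactivity (popcount)
  values of all permuted bins are pooled, and bins of the original
  matrix whose coactivity *strictly exceeds* the 95th percentile of
  that pooled null survive (99th percentile for SVD). The pooled-null
  reading (rather than per-permutation maxima) matches a percentile of
  the permuted coactivity-level distribution.

## Detectors

All detectors share the signature `(dff, params..., rng_seed)` →
`AssemblyConfiguration` and never emit empty member sets.

### ICA-CS / ICA-MP

Rows of ΔF/F are z-scored (zero-variance rows dropped with a warning);
the eigenspectrum of (1/P)XXᵀ is compared against a null:

* **CS:** each row circularly shifted by an independent uniform offset
  (preserving per-neuron autocorrelation, destroying cross-neuron
  correlation), 500 rounds; the null is the round-averaged sorted
  spectrum and the threshold its 95th percentile. This is a bulk
  percentile, so ~5 % of eigenvalues exceed it even on independent data
  — the level of the test.
* **MP:** the analytic Marčenko–Pastur upper edge (1 + √(N/P))².

Significant components are rotated by fastICA (tanh/logcosh contrast,
symmetric decorrelation, 500 iterations, up to 3 seeded restarts on
non-convergence, then the best iterate with a warning — symmetric
fastICA commonly oscillates on near-binary sources without affecting
the unmixing quality). The mixing matrix maps sources back to neuron
space; vectors are unit-norm with the largest-magnitude entry positive.
ICA-MP additionally drops any vector whose z-scored loadings fail to
reject standard normality in a one-sample KS test at α = 10⁻¹⁰ (the MP
edge alone admits occasional structureless components). Members are the
neurons with |loading| > mean + 2 SD of that vector.

### Promax-MP / Promax-CS

1. **Noise model and transient cleaning.** Per neuron, the Gaussian
   noise SD is estimated from below-median fluctuations (half-normal
   moment fit). Candidate transients are maximal runs above
   median + z₀.₉₅·SD; a run of length L is significant when noise alone
   cannot plausibly sustain it (n_bins·0.05^L < 0.05) or when its peak
   clears the length-adjusted threshold
   median + SD·Φ⁻¹(1 − (0.05/n_bins)^{1/L}). Runs shorter than half the
   indicator decay constant τ½/ln2 (in frames) are discarded — a real
   transient cannot vanish faster than the indicator. Samples outside
   significant transients are set to 0; the zeroing direction (keep the
   transients, zero the rest) is forced by the subsequent PCA needing to
   see the transients.
   **Failure rule.** `NoiseModelError` is raised when (a) the decay
   constant falls below half a frame (the kernel cannot be resolved at
   the imaging rate), or (b) the median estimated noise SD exceeds
   1/z₀.₉₅ ≈ 0.61 ΔF/F units — beyond that point a Gaussian noise model
   puts more than the method's own 5 % significance mass below the
   physical ΔF/F floor of −1 and is internally inconsistent — or
   (c) fewer than max(2, 5 % of N) neurons carry any significant
   transient. At otherwise-default parameters rule (b) trips from
   σ ≈ 3 upward; the harness records such runs as `no_result`.
2. **PCA and null.** On the z-scored cleaned matrix; threshold = MP edge
   plus a Tracy–Widom finite-size correction (variant MP):
   edge + q₉₅(TW1)·σ_NP with σ_NP = (√N+√P)/P·(1/√N+1/√P)^{1/3} and
   q₉₅(TW1) = 0.9793 — or the circular-shift null of ICA-CS (variant
   CS).
3. **Rotation and membership.** Loadings (eigenvectors scaled by √λ) are
   varimax-rotated then Promax-transformed with power m = 4 (the
   conventional default). Loadings are z-scored per component over
   neurons and sign-oriented so the dominant tail is positive; each
   neuron's maximal z-scored loading forms the zMax distribution. The
   cut-off is the first local minimum of its Gaussian-KDE density
   (10 000-point grid, half the Scott bandwidth) whose prominence
   exceeds 10 % of the density range — measured separations between
   spurious half-bandwidth wiggles (≤ 5 %) and genuine valleys (≥ 23 %)
   leave a wide margin on both sides. With no qualifying valley the
   unattended fallback is the 95th-percentile cut-off, with a warning.
   Neurons above the cut-off join the assembly of their arg-max
   component.

### SGC

High-coactivity patterns become nodes of an unweighted mutual k-NN graph
under cosine distance, k starting at ⌈ln n⌉ and growing by 1 until the
graph is connected. The community count B is chosen by minimising the
description length of a degree-corrected stochastic block model:
microcanonical entropy
S = −E − Σᵢ ln kᵢ! − ½ Σ_{rs} e_{rs} ln(e_{rs}/(e_r e_s))
plus the model cost E·h(B(B+1)/2E) + N·ln B, h(x) = (1+x)ln(1+x) − x ln x.
The search combines a sweep of spectral partitions at every candidate B
(scored directly — the Laplacian embedding is computed once) with greedy
agglomerative merge hierarchies from seeded spectral partitions at B_max
= min(50, n/5); the best description length per block count decides.
Agglomerative merging alone can stall on partitions whose blocks
straddle communities, which the direct spectral sweep repairs.

The graph is split by normalised-Laplacian spectral clustering (B
eigenvectors — the B-versus-B−1 choice is not canonical and is fixed at
B — row-normalised, k-means with 10 seeded restarts), and the groups go
through the refinement pipeline in this order: drop groups with < 5
patterns; drop groups more than 1.5 SD below the mean group size (mean
and SD over the groups present at that stage); binarise group means at
s = 1/5 into preliminary cores; recursively merge core pairs whose
similarity ratio min(⟨α̂,α̂′⟩/‖α̂‖², ⟨α̂,α̂′⟩/‖α̂′‖²) exceeds 2/3 —
pairs processed by descending similarity with lowest-index tie-break, to
a fixed point, so the result is order-independent; reassign *every*
pattern to its most similar preliminary core when both ⟨α̂,x⟩/‖α̂‖² > ½
and ‖x‖²/‖α̂‖² > ½, else reject it; drop reassigned groups more than
1.5 SD below the mean size; average the survivors into core patterns.
A neuron joins assembly r iff its affinity α_r(n) ≥ 1/5.

### CORE

Patterns are compared with Pearson correlation. The permutation null —
independent entry permutations of both patterns — makes the overlap
Hypergeometric(N, a, b), so the null correlation is sampled from that
exact law (50 000 draws over random pattern pairs) rather than by
materialising shuffled matrices; the threshold is the 95th percentile.
Constant patterns are excluded with a warning. Each pattern's core
ensemble is the mean over its significantly-similar set binarised at
s = 1/2 (the stricter s = 1 produces near-empty cores on noisy data).
Core ensembles are clustered by Hamming-distance k-means with
majority-vote binary centroids (centroid bits tied at exactly 0.5 go to
0; equidistant points go to the lowest centroid index); for each k in
2..min(20, #cores−1) the best of 1000 seeded rounds by mean silhouette
is kept, the best k refined with another 1000 rounds. All-identical
cores short-circuit to a single assembly, and a k-range of exactly {1}
forces a single averaged assembly (silhouette is undefined there).
Assemblies are per-cluster mean patterns thresholded at affinity 1/2 —
the membership threshold reuses the core-binarisation s, and the
averaged patterns are the core ensembles of the cluster (the natural
reading, since the clustering operates on core ensembles).

### SVD

Patterns (selected at the 99th-percentile coactivity level) are TF-IDF
weighted — binary term frequency times log(#patterns/#patterns
containing the neuron), the canonical IR weighting — and their cosine
similarity map is binarised at the 98th percentile of 20
entry-permutation surrogates. The Jaccard similarities between columns
of the binary map are thresholded the same way. The number of
significant singular values of the resulting matrix is the count above
the maximal singular value of 20 surrogates built by permuting the
*binary similarity map* and pushing it through the same
Jaccard-and-threshold chain — permuting the final matrix instead would
preserve its overall density and hence its density-driven leading
singular value, masking the block structure the test is meant to
detect. Each pattern is assigned to the significant right-singular
vector on which it loads most strongly (in absolute value); each
group's mean pattern thresholded at affinity 1/2 is an assembly. The
pattern-to-vector assignment rule and the final threshold are explicit
configuration knobs: the upstream description of "corresponding"
patterns admits several readings, and this is the simplest one.

## Scoring

`best_match_score` implements the two-way minimal-Jaccard-distance sum
normalised to [0, 1]. An empty recovered configuration scores 0 with a
flag (and a warning) rather than raising, so sweep curves over detector
failures remain plottable; empty *sets* inside a configuration are an
error — detectors never emit them. The analytic chance level enumerates
the distance support u = 1 − i/(n_A+n_A′−i) over size pairs and
hypergeometric intersections (accumulated on a float grid rounded at
12 decimals — exact for the set sizes in play), applies the min-law
P[min = u] = P[d ≥ u]^m − P[d > u]^m, and combines both directions by
linearity. The greedy optimal sub-clustering picks min-distance pairs
without replacement, random tie-break from the run's seed, for
min(|𝒜|,|𝒜′|) rounds; the optimal score is *not* guaranteed to be
above the plain score and neither is asserted anywhere.

The evoked-data reference estimator averages ΔF/F over frames 3–7 after
each stimulus onset (1-based inclusive, the onset frame being frame 1 —
offsets +2..+6), means over repetitions (onsets too near the recording
end are skipped with a warning), and admits a neuron into a stimulus
assembly when its response exceeds its own mean + p·SD across stimuli.

## Sweep harness

A sweep varies one parameter over a value list (validated against the
benchmark variation ranges unless explicitly overridden), with
`n_datasets` replicates per value. Child seeds derive from
SHA-256(base seed | parameter | value | replicate | role), truncated
below 2³¹ — independent reproducible streams per cell, shared
simulation per (value, replicate) across detectors. Promax noise-model
failures are recorded as `no_result`, other detector exceptions as
`error`; a sweep never aborts. Summaries report per-(value, detector)
means and SDs of counts and scores with the chance level alongside.

## What the surrogate data does and does not capture

The simulator reproduces the statistical skeleton of population calcium
imaging: Poisson background spiking, coordinated rate-elevation events,
indicator kernel dynamics, saturation, additive sensor noise, and slow
baseline drift handled by the ΔF/F extraction. It deliberately omits
neuropil contamination, ROI cross-talk between neighbouring cells,
non-uniform indicator expression, motion artefacts, and any temporal
structure within assembly events (no sequences). Detector rankings
established here therefore speak to the algorithms' core statistical
machinery, not to their robustness against those imaging-specific
nuisances; several algorithms already separate clearly without them.

## Numerical conventions and desk-scale profiles

* Default test and example profiles run at rings = 8 (217 neurons) and
  T = 1200–1800 s with few replicates; the full-default profile
  (469 neurons, T = 3600 s, 10 replicates) is exercised by the
  acceptance script and one dedicated test. These sizes are the
  package's own desk-scale choices; all thresholds and procedures are
  identical across scales.
* The Promax noise-model failure boundary is intrinsically between
  σ = 3 and σ = 4 at the default parameters: the floor-consistency rule
  can trip at σ = 3 (median noise SD ≈ 0.67 > 0.61) where a different
  failure mechanism might first trip at σ = 4. The recorded behaviour —
  results at low σ, `no_result` beyond σ = 3 — is the stable contract.
* Circular-shift nulls default to 500 rounds (reducible for desk-scale
  work); CORE's k-means rounds default to 1000 per k.
* All detectors are deterministic given (input, seed); every test and
  the acceptance script pin their seeds.

## Known limitations

* The DC-SBM search is a heuristic (spectral sweep + greedy merges),
  not an exhaustive MCMC; on graphs with very unbalanced communities it
  can misjudge B by one.
* The Promax transient model is a contract-level reconstruction (95 %
  confidence, Gaussian noise, decay-aware run tests), not a line-by-line
  port of the original interactive toolbox; the zMax cut-off replaces
  that toolbox's manual fallback with a percentile rule.
* Fast non-negative deconvolution is the first-order AR(1) inversion —
  exact on clean traces, conservative under heavy noise.
* The chance level assumes uniformly random subsets of fixed size
  distributions; detectors with strong size biases are compared against
  that same reference, which is the point of a common chance floor.
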