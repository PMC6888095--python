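# Methods

## The estimator

Transfer entropy from a source series `x` to a target series `y` is the
deviation from the generalized Markov condition
`p(y_t | y_{t-1}^{d_y}, x_{t-u}^{d_x}) = p(y_t | y_{t-1}^{d_y})`, written as
a four-term combination of entropies of the present target sample, the
delay-embedded target past, and the delay-embedded source past. The package
evaluates that combination with a matrix functional instead of estimated
densities. Each block of samples is turned into a Gaussian RBF Gram matrix
`K` (bandwidth σ = median pairwise distance of that block's own samples),
divided by `n` so `tr = 1`, and

    H_α(A) = log₂(Σ λ_i^α) / (1 − α)

is computed from the eigenvalues λ of `A`. Joint entropies use the Hadamard
product of the participating Gram matrices, renormalized to unit trace. The
functional satisfies the properties expected of an entropy: invariance under
orthonormal conjugation, additivity over Kronecker products, the range
`0 ≤ H_α ≤ log₂ n` (maximized by `(1/n) I`), monotone non-increase in α, and
convergence to the von Neumann form `−Σ λ log₂ λ` as α → 1. The test suite
asserts all of these.

Comparators:

* **KSG TE** — conditional-mutual-information form of the
  Kraskov–Stögbauer–Grassberger estimator: K-th-neighbor distances in the
  joint space under the Chebyshev norm, projected to the marginal spaces
  where strictly closer points are counted, with `+1` on all three marginal
  counts (`ψ(K) + ⟨ψ(n_{y⁻}+1) − ψ(n_{y y⁻}+1) − ψ(n_{y⁻ x⁻}+1)⟩`). A
  Theiler window (default: the embedding delay) excludes temporally adjacent
  samples from searches and counts, so serial correlation does not
  masquerade as neighborhood density. Measured bias under independence is
  ≈ 0.003 nats at `l = 1000` (a formula without the third `+1` would be
  biased by `⟨1/n_{y⁻x⁻}⟩ ≈ 0.15` nats).
* **Symbolic TE** — ordinal patterns: each embedded vector is replaced by
  the permutation of delay indices that sorts its amplitudes ascending
  (ties → smaller delay first), and a plug-in Shannon TE is computed from
  symbol counts. Invariant under strictly monotone transforms of either
  series.
* **Granger causality** — OLS fits of the restricted (own-lags) and full
  (own + source lags) autoregressions over the same sample range;
  `GC = ln(var e / var e′)`.

Units: kernel and symbolic TE are in bits (base-2 logs, forced by
`H_α((1/n)I) = log₂ n`); KSG TE and GC are in nats (the digamma identity and
the variance-ratio log are natural). Directionality indices and permutation
tests always compare a measure with itself, so units never mix.

## Embedding and parameter defaults

| parameter | default | meaning |
|---|---|---|
| `d` | 3 | embedding dimension (all TE variants) |
| `τ` | 1 ACT | embedding delay; ACT = first lag with ACF ≤ 1/e (signed value, capped at `l/4`) |
| `u` | 1 (VAR) / 4 (Kus) | interaction delay between driver and driven |
| `K` | 4 | KSG neighbor count |
| Theiler | 1 ACT | KSG serial-correlation exclusion window |
| α | {1.01, 2} | Rényi order; 1.01 ≈ Shannon limit, 2 neutral weighting |
| GC order | 3 | matches the VAR(3) generator |
| σ | median distance | RBF bandwidth, per Gram matrix, from that matrix's own embedded samples (raw, un-normalized values) |
| permutations | 1000, level 5% | per-edge, no multiple-testing correction |

When an experiment config leaves `τ` unset, it is resolved per trial as the
maximum of the two series' ACTs.

## Synthetic benchmarks

**VAR(3) pair.** `z_t = c + Σ_{i=1..3} Q_i z_{t-i} + ε_t` with coefficients
and constants drawn uniform on [−1, 1], the cross-coefficients of the
non-causal direction set exactly to 0, and draws rejected until the
companion-matrix spectral radius is < 0.95 (margin below 1 for
well-behaved finite simulations). Innovations are unit-variance Gaussian;
200 burn-in samples are discarded. Model coefficients are redrawn per trial;
the coupling direction is fixed per realization and chosen at random.

**Noise mixer.** `Z_η = (1−γ)·Z/‖Z‖_F + γ·ΘΞ/‖ΘΞ‖_F` with Θ a random 2×3
instantaneous mixing matrix (uniform [−1, 1]) and Ξ three independent
stable AR(3) noise series — a stand-in for volume conduction, where several
unknown sources superpose at both sensors. A scalar γ gives symmetric noise;
a 2-vector applies row-wise (asymmetric noise). At γ = 1 the coupled signal
is gone entirely, so direction detection must fall to chance — the headline
check of `scripts/acceptance.py`.

**Modified Kus network.** Five channels: an EEG-like input drives channel 1;
channel 2 is `0.4 × ch1` delayed 4 samples; channel 3 is `0.4 × ch2` delayed
4; channel 4 is `0.4 × ch2` delayed 8; channel 5 is pure noise. Each
equation adds internal noise scaled by `v` = a quarter of the variance of
that equation's driving series (channels 1 and 5, and the external noise,
use the input series' variance — the generative equations do not pin this
down further), then external white Gaussian noise of variance `v` is added
to every channel, and the first 8 samples (the longest delay) are trimmed so
all channels align. Ground truth: direct edges 1→2, 2→3, 2→4; indirect
1→3, 1→4 (chain) and 3→4 (common driver, channel 3 leading by 4 samples);
everything touching channel 5 is a true negative.

**Surrogate EEG input.** The real scalp-channel input of the original Kus
benchmark is replaced by a synthetic stand-in: 1/f-weighted Gaussian noise
with a narrowband 8–12 Hz (alpha) component at a nominal 250 Hz rate,
standardized to zero mean and unit variance. It reproduces the broadband
spectral shape and the dominant rhythm of resting EEG but none of its
nonstationarity, artifacts, or cross-subject variability — so Kus-recovery
results here validate the pipeline's mechanics, not its behavior on real
recordings, and detection rates are not comparable to real-EEG-driven runs.
A file-input hook (`simulate_kus(input_series, ...)`) accepts a real channel
where available.

## Significance testing

The null hypothesis of no coupling between a source and a target channel is
sampled by **trial-randomized surrogates**: re-pairing source trials with
mismatched target trials destroys cross-trial coupling while preserving each
trial's own dynamics. The observed statistic is the mean over trials of the
per-trial directed measure. Two interchangeable null schemes:

* `trial_shuffle`: every permutation draws a fixed-point-free re-pairing and
  recomputes the mean statistic (estimator values cached per trial pair).
  This is the textbook scheme; its cost is bounded by `n_trials²` estimator
  calls, affordable for the cheap estimators (symbolic, GC).
* `paired`: one fixed-point-free re-pairing produces a surrogate value per
  trial, and null samples are means of random per-trial label swaps between
  observed and surrogate values. Cost is `2 n_trials` estimator calls
  regardless of the permutation count, which is what makes
  eigendecomposition-heavy kernel TE affordable at network scale (20 ordered
  edges × 100 trials × 10 realizations); this is also how the established
  TRENTOOL workflow structures its trial-shuffling test.

Both are exact level-α tests under the null (measured false-positive rate at
a nominal 5%: ≈ 5–8%). The p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_perm)`, so it is never zero. Network
scans test every ordered channel pair and, by default, control the false
discovery rate across the `C(C−1)` edges with Benjamini–Hochberg at the
nominal level — the convention of established multichannel TE tooling, and
necessary for a 20-edge scan not to produce one expected false edge per
realization at a raw 5% level (`correction="none"` restores the raw
per-edge test); the
per-pair random streams are derived from the pair's data content, making the
scan exactly invariant under channel relabeling. Ties in the directionality
index count as detection failures (conservative).

## Numerical choices and degenerate inputs

* Eigenvalues of Gram matrices can undershoot 0 by ~1e−15; they are clipped
  at 0 and the spectrum renormalized to sum 1 before non-integer powering.
* Matrices are symmetrized (`(A + Aᵀ)/2`) before `eigvalsh`.
* `0 log 0 := 0` in the von Neumann limit; α = 1 raises a parameter error
  (callers use 1.01).
* Constant series raise degenerate-data errors in every estimator rather
  than silently returning zeros; an all-identical sample block likewise
  (its median distance is 0, leaving the RBF bandwidth undefined). One
  exception: a non-constant target whose ordinal alphabet collapses to a
  single symbol (e.g. a strictly monotone ramp) is valid for symbolic TE
  and yields exactly 0 — there is no uncertainty in the target to resolve.
* Negative TE estimates (finite-sample bias) are reported as-is.
* KSG neighbor counts use strict inequality against the K-th-neighbor
  distance, the standard convention; equal-distance ties are therefore
  excluded from counts.
* The derangement sampler rejects permutations with fixed points
  (re-pairing a trial with itself would leak coupling into the null).

## Problem sizes used by the shipped studies

The full-scale protocol of the benchmark studies (10 realizations × 100
trials per cell; 11-point γ grids; 1000 permutations) is available through
`ExperimentConfig`. The shipped test suite runs the same code at sizes
chosen to keep a single-CPU run affordable: the chance-floor check uses
10 × 50 trials (the acceptance script uses the full 10 × 100), the
noise/data-size trend checks use 100 trials per cell, the Kus recovery check
uses 10 realizations × 100 trials with 500 label-swap permutations and
256-sample inputs, and the calibration check uses 200 repetitions of a
15-trial test. These sizes are the package's own reproduction defaults;
accuracy values at these scales carry binomial noise of a few percentage
points, which the test tolerances account for.

## Known limitations

* The kernel estimator's cost is dominated by `O(n³)` eigendecompositions
  per TE evaluation, so series of more than a few thousand samples are
  expensive; windowing (as in the EEG workflow) is the intended use.
* Bivariate only: no conditional/multivariate TE, so common-driver and
  different-delay-driving confounds are not disambiguated (the indirect
  Kus edges are genuinely detected as couplings; distinguishing direct from
  indirect requires conditioning, which is out of scope).
* The Gaussian-equivalence between GC and 2·TE holds only for jointly
  Gaussian data and is used solely as a sanity cross-check for the KSG
  estimator.
* Deterministically synchronized systems and strongly nonstationary data
  violate TE's assumptions; nothing in the package detects that for you.
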