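# Methods

This note documents the model, the defaults, the numerical choices, and
what the synthetic fixtures do and do not establish about real data.

## Model and inference

The observation sequence `y_1..y_T` (envelope principal components,
`M` dimensions) is modeled by a K-state hidden Markov chain with
multivariate-normal emissions `y_t | s_t = k ~ N(μ_k, Σ_k)`. Priors are
conjugate: symmetric Dirichlet on each transition row and on the
initial-state distribution, Gaussian–Wishart on each `(μ_k, Λ_k)` with
`Λ_k = Σ_k^{-1}`. Inference is coordinate-ascent variational Bayes on
the factorization `q(s) q(π_0) q(π) Πk q(μ_k, Λ_k)`:

* **E-step.** Forward–backward recursions over the expected log
  parameters: `E[ln π_ij] = ψ(α_ij) − ψ(Σ_j α_ij)` for the Dirichlet
  factors, and for the emissions

      E[ln N(y_t | μ_k, Λ_k^{-1})] = ½ ( E[ln|Λ_k|] − M ln 2π − M/β_k
                                         − ν_k (y_t − m_k)ᵀ W_k (y_t − m_k) )

  with `E[ln|Λ_k|] = Σ_i ψ((ν_k+1−i)/2) + M ln 2 + ln|W_k|`. The
  recursions are linear-space with per-sample rescaling (stable to at
  least `T = 10^6`) and restart from the initial-state distribution at
  every subject boundary, so no transitions are counted across subjects.
* **M-step.** Conjugate updates: Dirichlet posteriors are priors plus
  expected transition (or segment-initial) counts; Gaussian–Wishart
  posteriors come from responsibility-weighted means and scatters.
* **Free energy.** `F = −ln Z̃ + KL(q(Θ)‖p(Θ))`, where `ln Z̃` is the
  chain's log normalizer from the scaled forward pass and the KL sums
  the Dirichlet and Gaussian–Wishart divergences of posteriors from
  priors. Evaluated after each E-step, `F` is mathematically guaranteed
  to be non-increasing; for `K = 1` the bound is tight and `−F` equals
  the closed-form Normal–Wishart log marginal likelihood, which the test
  suite verifies to machine precision.
* **Decoding.** Viterbi over the same expected log parameters, per
  segment, with ties broken toward the lowest state index.

### Prior defaults

| hyperparameter | default | rationale |
| --- | --- | --- |
| transition Dirichlet concentration | 1 per entry | flat over each row |
| initial-state Dirichlet concentration | 1 | flat |
| Gaussian mean `m_0` | 0 | whitened data are zero-mean |
| mean-precision scale `β_0` | 1e-3 | broad (the mean is essentially free) |
| Wishart degrees of freedom `ν_0` | `M` | minimum proper value |
| Wishart inverse scale `W_0^{-1}` | `M·I` | `E[Λ] = ν_0 W_0 = I`, matched to unit-variance whitened data |

All are configurable through `HMMPriors`. With `T ≫ M` the data terms
dominate every posterior and the exact prior scale is immaterial.

### Initialization and restarts

Each restart must break the label symmetry of the model. Drawing
per-sample responsibilities from a symmetric Dirichlet and taking an
M-step does *not* accomplish this for long sequences: every state then
receives nearly the global moments (deviations are O(T^{-1/2})), the
model starts at the symmetric saddle point where all states are
identical, and the free energy is immediately flat. `envhmm` instead
breaks symmetry in parameter space: each restart sets the K posterior
means to K randomly drawn observations and every state's expected
precision to the global precision. Restarts (default 10) differ only in
their sub-seed; the fit with the lowest converged free energy is kept.
Convergence is declared when the relative free-energy change drops
below `1e-5` (default), with a 500-iteration cap.

## Whitening

The group-concatenated envelopes are reduced to `M` principal components
(default 40) scaled to zero mean and exactly unit variance. The
decomposition is a plain SVD with a deterministic sign convention (the
largest-magnitude spatial loading of each component is made positive),
so repeated runs are bit-identical. Spatial interpretation is recovered
afterwards from the *full-rank* envelope data, never from the scores.

## Spatial maps and identifiability

State maps are computed per voxel by multiple regression of the
z-scored envelope on all z-scored state indicator columns jointly. For a
full-column-rank design this returns exact partial correlation
coefficients (verified against a residualization oracle at 1e-10). Two
structural caveats are documented rather than hidden:

1. **Collinearity.** Mutually exclusive, exhaustive indicators are
   exactly rank K−1 after z-scoring (the occupancy-weighted sum of the
   z-scored columns is identically zero), so the partial correlation of
   one state given the others is undefined. In that case the GLM
   returns the minimum-norm standardized coefficients on the effective
   (K−1)-dimensional space, computed by truncated SVD, and logs a note.
2. **Identifiability of topographies.** Any linear map estimator can
   only recover a state's amplitude topography up to a common
   occupancy-weighted average of all topographies (the per-voxel mean
   absorbs it). Recovery of generating topographies is therefore best
   when each state is active a minority of the time — which is also the
   empirically relevant regime (transient states with occupancies well
   below one half). The synthetic recovery fixtures include a quiescent
   background state occupying roughly half the time for exactly this
   reason; with three equally occupied states and no background, the
   spatial correlation between the identifiable map and the generating
   topography is bounded near 0.82 regardless of noise level or data
   length.

Thresholding of maps (keep voxels above a fraction of each state's
maximum absolute value) is presentation-only and never feeds back into
statistics.

## Beamformer

The LCMV scalar beamformer uses the sample sensor covariance with an
optional diagonal ridge (`C + ridge·mean(diag C)·I`; default ridge 0).
The dipole orientation maximizes the projected signal-to-noise ratio
`(vᵀHᵀC⁻¹Hv)/(vᵀHᵀC⁻²Hv)` via the generalized eigenproblem; when the
top eigenvalue is degenerate (for white sensor noise the ratio is
constant) the tie is broken deterministically toward maximal projected
signal power, which reduces to the leading right-singular vector of the
lead field. Weights are `wᵀ = [hᵀC⁻¹h]⁻¹ hᵀC⁻¹` (unit gain, `wᵀh = 1`)
and projected time courses are scaled by the projected sensor noise,
`z(t) = wᵀm(t) / √(wᵀw)`, which makes the output variance for white
noise independent of lead-field norm (depth-bias correction).

## Envelope preparation

Fixed order: zero-phase Butterworth band-pass (default 4–30 Hz, order
4, applied forward–backward) → Hilbert-transform magnitude → averaging
in sliding windows (default 100 ms, 75% overlap: 200 Hz → 40 Hz;
trailing partial windows dropped to avoid edge bias) → Gaussian spatial
smoothing over voxel coordinates (default FWHM 9.4 mm, weights
normalized per target voxel) → per-subject voxel demeaning and division
by the subject's pooled-over-voxels standard deviation → temporal
concatenation with recorded segment boundaries. All windowed operations
in the package (downsampling, FO time courses, sliding correlations,
the width sweep) share one windowing utility, so their window grids are
identical by construction.

## Summary statistics

Computed from the hard Viterbi path: fractional occupancy, number of
occurrences (entries into a state; the virtual sample before each
segment counts as "no state", so segment-initial runs count), mean life
time (dwell samples / occurrences), and mean interval length
`(T − dwell)/occurrences`. The interval formula intentionally divides
total out-of-state time by the number of visits; the literal mean gap
between consecutive visits is the separately named `mean_gap_length`.
Empirical transition matrices count within-segment transitions only,
and diagonal masking sets the diagonal to NaN without renormalizing.

## Synthetic fixtures: what they emulate and what they don't

The generators produce Markov-switching state sequences with geometric
dwell times (self-transition `p = 1 − 1/mean_lifetime`), per-state
Gaussian emissions, and non-negative envelope-like data: baseline plus
a state-specific additive topography plus Gaussian noise, rectified at
zero, at a 40 Hz effective rate with independent per-subject chain
restarts. Default conditions used throughout the tests:

* **Gaussian-HMM recovery fixture:** K = 4, M = 10, T = 48 000
  (20 minutes at 40 Hz), transition diagonal 0.9 (mean dwell 10 samples
  = 250 ms), state means at pairwise Euclidean distance exactly 1, and
  per-state diagonal covariances with two state-specific variances
  elevated to 5.0 over a baseline of 1.0. The covariance contrast is
  part of the design: states in envelope data are distinguished largely
  by their covariance structure, and a Viterbi-path accuracy target of
  0.90 is only information-theoretically reachable when per-sample
  discriminability is high enough — with near-identity covariances the
  Bayes-optimal decoder itself stays below 0.85 at this mean
  separation, as run boundaries are intrinsically ambiguous.
* **Envelope fixture:** 48 voxels, three localized topographies
  (12 voxels each, gains ≈ 1 over baseline 2.0), mean lifetime
  8 samples (200 ms), three subjects × 8 000 samples, noise SD 0.4, and
  a quiescent background state with ~2× the occupancy of each active
  state (see the identifiability discussion above).

What passing on these fixtures does **not** show about real data: the
generators have white (or simply low-passed) noise rather than 1/f
spectra, no volume-conduction-induced spatial leakage beyond explicit
smoothing, no artifacts, and topographies that are exactly constant
within a state. Life-time and occupancy values for real resting-state
recordings depend on data that are not distributed with the package;
the tests establish correctness
of the machinery and qualitative behavior (e.g. the window-width sweep
peaking below 0.5 s for fast-switching envelopes and above 0.8 s after
a 0.5 Hz low-pass), not empirical claims about any particular dataset.

## Numerical choices and degenerate inputs

* Forward–backward and Viterbi are numba-compiled; scaling is per
  sample, and marginals are renormalized against drift during the
  backward pass.
* Ties in Viterbi and in all argmax selections break toward the lowest
  index; PCA signs and orientation signs are fixed deterministically.
* Zero-variance data are rejected before fitting; states that receive
  zero responsibility mass keep their priors; states absent from a
  decoded path get NaN map coefficients with a logged warning; unvisited
  states report NaN life times and intervals.
* Covariance validation accepts positive *semi*-definite matrices in
  the simulator (a zero covariance is a legitimate degenerate emission)
  but the Wishart posterior scale must remain positive definite, which
  holds whenever the prior inverse scale is.
* All randomness flows from user-supplied seeds through
  `numpy.random.SeedSequence` spawning; repeated runs are bit-identical.

## Problem sizes in the shipped tests

The default suite runs in well under a minute except for the recovery
battery (~15 s: one 48 000-sample fit with 10 restarts). The
acceptance script re-simulates everything and completes in a few
minutes on one CPU. Exhaustive-enumeration oracles cover all
`(K, T) ∈ {2,3} × {2..8}`; larger grids add nothing since the
recursions are length-independent.

## Known limitations

* Observation model is Gaussian per state; no autoregressive or
  time-frequency observation models.
* One group-level HMM over concatenated subjects; no per-subject models
  or hierarchical pooling.
* The spatial-map GLM inherits the identifiability limits described
  above; maps are interpretable as deviations from the
  occupancy-weighted mean activity, not absolute topographies.
* No forward-model computation: lead fields must be supplied.
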