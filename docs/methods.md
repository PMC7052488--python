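# Methods

This note documents the models and procedures implemented in `milatoms`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Problem setting

Bi-class motor-imagery (MI) decoding from EEG: a subject imagines a left- or
right-hand movement, which attenuates the sensorimotor mu (8–13 Hz) and beta
(13–25 Hz) rhythms over the contralateral motor cortex (event-related
desynchronization, ERD). The decoding difficulty is that the informative
frequency band, spatial pattern, and — especially — time interval vary
between subjects and between trials, so a feature extractor committed to a
single analysis window degrades on most of the population.

## Pipeline

### Filter bank and windowing

Trials are band-pass filtered through `N_f` overlapped Butterworth filters
(default 4–40 Hz, 4 Hz bandwidth, 2 Hz step → 17 bands, order 5,
zero-phase by default; a causal flag exists for online-compatible
experiments). Each band signal is cut into windows of length `tau` with 90%
sample overlap. The hop is `ceil((1 - overlap) · tau · fs)` samples: the
ceiling is the one rounding rule that reproduces the canonical per-length
window counts for a 500-sample segment at 250 Hz (91 windows at 0.2 s down
to 1 at 2.0 s, 337 in total). A consequence of the ceiling rule is that a
trailing remainder shorter than one hop can stay uncovered (one sample at
tau = 0.3 s); we accept this rather than break the count contract.
Indexing is 0-based and half-open everywhere.

### CSP atoms

For each (band, window) cell, Common Spatial Patterns solves the
generalized eigenproblem `Σ⁺ w = λ Σ⁻ w` on the class-conditional spatial
covariances; the eigenvalues are the Rayleigh quotients
`J(w) = (wᵀΣ⁺w)/(wᵀΣ⁻w)` and the top one measures class separability of
that cell. Rows are unit-normalized (J is scale invariant) with the
largest-magnitude entry made positive for backend-independent determinism.
The `M` first and `M` last eigenvectors (default `M = 3`, i.e. 6 filters)
are retained. The atom of one trial–window is the concatenation over bands
of `ln(v_m / Σ_m' v_m')`, where `v_m` is the temporal variance of retained
projection `m`; each band block is therefore the log of a normalized
variance distribution (`Σ_m exp(d_m) = 1`), making atoms invariant to
global amplitude scaling. Variances are computed as quadratic forms
`wᵀ C w` of the per-trial window covariance, so the projected time series
is never materialized.

Numerical choices: per-trial covariances are trace-normalized before class
averaging (configurable off) to suppress inter-trial amplitude
differences; both class covariances are shrunk toward a scaled identity
before the eigenproblem, with a Ledoit–Wolf-style intensity estimated from
the spread of the per-trial covariances (a 50-sample, 22-channel window
covariance is otherwise ill-conditioned). A singular denominator without
shrinkage raises an error pointing at the shrinkage option instead of
returning garbage.

The Rayleigh map reports the top `J` per (band, window) and a per-band
marginal (mean over windows by default; max and sum are options) whose
peak identifies the rhythm carrying the class contrast.

### Multiple-instance refinement

A trial's windows form a bag; only the bag label is known. The
instance-level model is logistic, and the bag probability is the noisy-OR
`P(+|B) = 1 - Π_t (1 - h(β₀ + d_tᵀβ))` — a bag is positive as soon as any
window expresses the positive pattern. The L1-penalized bag likelihood is
minimized by EM: the E-step computes the conditional expectation of the
latent instance labels of positive bags,
`γ_t = h_t / (1 - Π_s (1 - h_s))` (negative-bag instances are negative
with weight 1); the M-step performs coordinate-wise soft-threshold updates
on the weighted logistic surrogate using the 1/4 curvature bound, so every
sweep is a true majorization step and the penalized objective is
non-increasing (asserted on every fit; a violation is surfaced as a
convergence diagnostic, never silently). Probabilities are clipped to
`[1e-12, 1 - 1e-12]` inside logarithms. Initialization is `β = 0`,
`β₀ = log(n⁺/n⁻)`. With singleton bags the model reduces exactly to L1
logistic regression, which is the correctness anchor: coefficients agree
with an independent solver to ~1e-9.

Refinement drops the atom coordinates outside the L1 support (threshold 0
by default; re-weighting by |β| is a conceivable alternative we did not
adopt, as dropping matches the goal of discarding irrelevant coordinates
with no extra knob). The penalty is specified per instance in the pipeline
configuration (`alpha_raw = alpha · n_instances`) so its strength is
commensurate with the summed log-likelihood as bag counts change across
window lengths; `"auto"` selects it by bag-level cross-validated held-out
log-likelihood over a small per-instance grid (3e-4 … 1e-2 by default —
the range in which the solver moves from dense to empty supports on
realistic atoms). If the selected fit has an empty support the pipeline
falls back through the CV-ranked candidates, since refinement requires at
least one surviving coordinate. MILR is fitted per window length, inside
each training fold.

### Similarity embedding and expansion

Every (refined) training instance is a target concept; a bag's feature for
concept `d^k` is the most-likely-cause similarity
`s(d^k, B) = max_t exp(-||d_t - d^k||² / σ²)` in [0, 1]. Stacking bags
gives the similarity block `S_τ` for one window length; concatenating the
blocks of a contiguous range of lengths `τ = q·Δτ … p·Δτ` (Δτ = 0.1 s)
yields the expanded embedding `Δ_pq`. With 19 lengths there are
19·20/2 = 190 admissible (q, p) ranges. Every column is book-kept to
(τ, concept, source trial, source window) — a bijection asserted by test —
so sparse weights can be mapped back onto time.

σ uses the median heuristic (median pairwise squared distance over a
seeded subsample). It is shared across window lengths by pooling each
length's pairwise distances (refinement masks differ per length, so
pooling raw instances would mix spaces of different dimension); per-length
σ is available by configuration. Dictionaries are built from training
folds only: a held-out bag is never embedded against its own instances.

### Selection and classification

A LASSO regression of the expanded features on the ±1 labels,
`u* = argmin ||Δu - l||² + λ||u||₁` (intercept by centering; the ±1
regression surrogate is used deliberately rather than logistic LASSO),
screens the columns; an RBF-SVM (C = 1) on the surviving columns
classifies bags. Model selection of (λ, SVM bandwidth) is nested inside
each outer fold (inner stratified CV; ties prefer the sparser λ, then the
smaller bandwidth; penalties selecting identical column sets share one SVM
evaluation). The default grids are the standard protocol — bandwidths
1e-3…1e3 in decades, λ log-spaced 1e-10…1e-1 — with an optional
glmnet-style relative mode that interprets the λ grid as fractions of the
training set's analytic death point `2·||Δᵀ(l - l̄)||_∞`, which keeps the
grid meaningful across feature scales and avoids wasting iterations in the
effectively unpenalized regime. A fold whose every λ yields an empty
active set falls back to majority-class prediction and is flagged.

The expansion search evaluates every (q ≤ p) cell with this procedure and
returns the upper-triangular accuracy matrix; the best cell maximizes mean
CV accuracy with ties broken toward the smallest total column count, then
the smallest p (cheaper models win deterministically). The search
criterion is accuracy (equivalently, minimal disagreement with the true
labels).

Temporal profiles aggregate each fold's |u| mass onto the center time of
each active column's source window, on the time grid of the finest window
length in the best range, normalized per fold to maximum 1 (an all-zero
fit is flagged, not hidden); the aggregate curve is the fold mean,
re-normalized. Sum-normalization is a documented alternative.

### Orchestration

`run_pipeline` executes the stages with full fold hygiene — CSP filters,
MILR models, σ, concept dictionaries, λ and the SVM bandwidth are all
fitted on outer-fold training data only — and stamps provenance (derived
stage seeds, fold assignments, resolved configuration, a hash of the
fitted selection vectors). One global seed fans out to the stages through
`numpy.random.SeedSequence`, so a rerun with the same configuration and
seed reproduces fold scores exactly.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes: one
discriminative source (white noise band-passed to the ERD band, unit
variance per trial) whose amplitude is multiplied by `sqrt(erd_depth)`
inside the ERD interval for class −1 only, plus class-independent 1/f
background sources, mixed to the montage through a seeded column-normalized
Gaussian matrix, with white sensor noise added to a target SNR. The ERD
envelope uses 100 ms raised-cosine ramps placed *outside* the interval, so
the in-interval class variance ratio equals `erd_depth` exactly while
avoiding gating artifacts.

Default conditions: 22 channels, 250 Hz, 2 s trials, 72 trials per class,
ERD band 10–13 Hz, depth 0.3, 8 background sources, 15 dB SNR. The default
ERD interval is 0.25–1.75 s — a sustained desynchronization with a typical
onset latency. This default matters: the discriminative information of the
planted contrast is a variance ratio carried by roughly `2·B·T` degrees of
freedom (B the band width, T the ERD duration). For a transient 0.6 s ERD
at 3 Hz bandwidth, even an oracle reading the true source variance cannot
exceed ≈0.88 accuracy at depth 0.3 — that configuration emulates a
low-SNR subject, and the generator accepts it via `erd_interval` for
localization experiments; the sustained default (oracle ≈0.997) emulates
the strong-effect subject that recovery benchmarks presume.

What passing the benchmark shows: the pipeline recovers a planted
band/space/time-localized variance modulation under linear mixing,
broadband background and sensor noise, with honest cross-validation. What
it does not show: robustness to artifacts (EOG/EMG), nonstationary noise,
electrode drift, or real inter-subject variability — no claim about real
recordings follows from the synthetic results alone. Real epoched
recordings can be supplied through `EEGTrialSet` directly.

### Measuring the planted depth

Recovery tests estimate the class variance ratio by unmixing the
discriminative source with the stored mixing matrix, band-passing with a
band *enclosing* the ERD band (8–15 Hz), and measuring variance inside the
interval with 0.1 s edge guards: a filter as narrow as the ERD band itself
has an impulse response long enough to smear the louder surrounding signal
into the interval and bias the ratio upward by ~20%.

## Problem sizes used in the shipped benchmarks

The reduced ("smoke") configuration used by the test suite and the
acceptance script keeps the full 144-trial dataset, 22 channels, M = 3 and
10-fold outer CV, and reduces the multipliers that only scale runtime: a
4-band bank (4–20 Hz, step 4) straddling the mu band, window lengths
{0.4, 1.0, 2.0} s (6 expansion cells), a 5-point relative λ grid, 3 inner
folds, and a 2-candidate MILR grid. The full-scale defaults (17 bands, 19
lengths, 190 cells) are the package defaults for real experiments.

## Known limitations

- The LASSO active set is not guaranteed monotone in λ; nesting is
  asserted on generic fixtures only.
- The noisy-OR EM solver is first-order; for very small penalties on
  near-separable data it needs many sweeps (the singleton-bag oracle test
  runs it to tolerance 1e-10 deliberately).
- The expansion search refits the entire selection path per cell; the
  full 190-cell search at 17 bands is an offline computation by design.
- Bags assume equal trial lengths and a common sampling rate; no
  resampling is provided.
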