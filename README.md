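# milatoms

Bag-of-patterns decoding of bi-class motor-imagery EEG.

`milatoms` implements an enhanced multiple-instance representation for
left-vs-right motor-imagery classification. Trials are decomposed by an
overlapped filter bank and short-time windows; each (band, window) cell
yields a Common Spatial Patterns log-variance feature, and the
concatenation over bands is a *time-frequency atom*. A trial's atoms form
a *bag*: the trial label is known, the individual windows are not. The
package then

1. refines the atoms with an L1-penalized multiple-instance logistic
   regression whose bag likelihood is the noisy-OR of instance
   probabilities, `P(+|B_r) = 1 − Π_t (1 − h(β₀ + d_rtᵀβ))`, keeping only
   coordinates with nonzero weight;
2. embeds every bag against a dictionary of training instances (concepts)
   through the most-likely-cause similarity
   `s(d^k, B_r) = max_t exp(−‖d_rt − d^k‖²/σ²)`;
3. expands the embedding over a contiguous range of window lengths
   `Δ_pq = [S_{qΔτ} ‖ … ‖ S_{pΔτ}]` and searches all 190 admissible
   (q, p) ranges;
4. selects columns with a LASSO regression
   `u* = argmin ‖Δ_pq u − l‖² + λ‖u‖₁` and classifies bags with an
   RBF-SVM on the selected columns, under nested 10-fold cross-validation.

The absolute LASSO weights, mapped back to their source windows, trace
which time intervals of the imagery period drive the decision; the
Rayleigh-quotient map traces the informative frequency bands.

A synthetic generator produces labeled multichannel trials with a planted
event-related desynchronization (band-limited source, linear mixing,
class-dependent variance drop in a known band/interval), so the whole
pipeline is testable without any recording. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

```python
import milatoms as m

trials, truth = m.generate_dataset(m.SyntheticConfig(seed=11))
result = m.run_pipeline(trials, m.smoke_config(seed=11))

s = result.search
print(f"best range: q={s.best_q}, p={s.best_p}")
print(f"accuracy:   {s.mean_accuracy:.3f} +/- {s.std_accuracy:.3f}")
import numpy as np
band = result.spectral.band_centers[np.argmax(result.spectral.spectral_relevance)]
print(f"spectral relevance peak at {band:.0f} Hz")
```

Output:

```
best range: q=10, p=20
accuracy:   0.959 +/- 0.034
spectral relevance peak at 14 Hz
```

The search preferred expanding the 1.0 s and 2.0 s window lengths
(indices 10–20 in 0.1 s units) and classifies the planted 10–13 Hz ERD at
95.9% cross-validated accuracy; the spectral relevance peak falls in the
12–16 Hz band, overlapping the planted rhythm. `m.report(result, "out/")`
renders the accuracy matrix, the spectral relevance bars and the per-fold
temporal profiles.

The same pipeline runs from the shell:

```
milatoms simulate --seed 11 --out trials.npz
milatoms run --in trials.npz --smoke --seed 11 --out results/
milatoms report --results results/ --out report/
```

`EEGTrialSet` accepts any (trials × channels × samples) array with ±1
labels, so epochs exported from EDF/GDF recordings plug in directly.

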