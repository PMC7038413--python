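# Methods

## Problem and pipeline

`afdetect` labels every heartbeat of an RR-interval series as AF or non-AF
and consolidates the labels into episodes. The pipeline has four stages —
windowed feature extraction, a Lagrangian SVM, label aggregation, and the
evaluation protocol (balanced draws, Monte Carlo cross-validation, six
performance measures) — each usable on its own through the library API.

## Feature extraction

All sixteen features are computed in a symmetric moving window of N = 21
beats (half-width k = 10) around the classified beat; the first and last k
beats of every record have no complete window and are excluded (25 records
therefore lose exactly 500 beats). Defaults: quantile order 0.7 for QNT,
inclusive HR band [120, 160] bpm for PRP, 50 ms successive-difference cutoff
for pNN50 — established operating values for this window length.

Numerical conventions, declared once and used everywhere:

* **Quantiles** (QNT, the de Haan IQR) use linear interpolation between
  order statistics ("type 7", the numpy default).
* **STD_HR** and the Yeh index use the sample SD (denominator N−1 over N
  values, N−2 over the N−1 successive-difference ratios — the Yeh index's
  printed 1/(N−2) normalization *is* the sample SD of its N−1 terms).
* **SD1/SD2** come from the variance identities SD1² = Var(ΔRR)/2,
  SD2² = 2·Var(RR) − SD1² with population variances over the window — the
  closed form of Poincaré ellipse fitting.
* **Turning points** require a strict sign change of consecutive
  differences; plateaus do not count. TPR divides the observed count by the
  random-sequence expectation (2N−4)/3.
* **Huey's index** sums |ΔHR| only where the successive HR difference
  strictly changes sign (product < 0).
* **de Haan angles** are φᵢ = arctan(RRᵢ/RRᵢ₋₁) in degrees over the 20
  successive pairs of the window; constant RR puts every point on the 45°
  diagonal and the index at 0.
* Units are kept as conventionally printed (the Yeh and Zugaib indices are
  built from dimensionless ratios although often labeled [ms]; this is a
  labeling convention with no numeric effect).

Extraction is vectorized over all windows (`sliding_window_view`); the test
suite checks it against loop-based recomputation to 1e−9 relative.

## Lagrangian SVM

The LSVM objective replaces the hinge penalty with squared slacks and
penalizes the offset, making the dual's only constraint λ ≥ 0 and enabling
the fixed-point iteration λ⁽ᵏ⁺¹⁾ = Q⁻¹(1 + (Qλ⁽ᵏ⁾ − 1 − αλ⁽ᵏ⁾)₊).
Choices that the formulation leaves open:

* **Initialization** λ⁽⁰⁾ = 0 — the iteration converges from any start, and
  zero is deterministic.
* **Q⁻¹** is applied through a single Cholesky factorization computed before
  iterating; Q = I/γ + HHᵀ (or I/γ + DKD) is symmetric positive definite.
  At the training sizes this package targets (≲ 20 000 vectors) a direct
  factorization is simpler to verify than low-rank update formulas and is
  not the bottleneck.
* **Stopping**: Euclidean norm of the dual change ≤ 1e−5, or 100 iterations
  — the classical operating recipe for this trainer. Oracle-equivalence
  tests tighten the tolerance instead of relying on defaults.
* **Step size** α defaults to 1.9/γ, always inside the (0, 2/γ) convergence
  band; the config validates the band for explicit α.
* **Kernel**: Gaussian exp(−χ‖x−y‖²) applied to inputs augmented with a
  constant −1 coordinate, which folds the offset into the kernel surface
  K(x_e, X₀ₑᵀ)Dλ. Hyperparameters default to γ = 10, χ = 4; the 1–4–7
  decade ladder {1e−5, 4e−5, 7e−5, …, 7e4, 1e5} is exposed for searches.
* **Scaling**: training features map affinely to [−1, +1]; test data reuse
  the same transform unclipped; a constant feature maps to 0.
* **Ties**: a decision score of exactly 0 predicts non-AF — conservative
  toward the negative class.

## Aggregation

Every beat is relabeled simultaneously (single pass, no cascading) by the
AF percentage of its symmetric window against threshold p (strict >). The
rule is deliberately bidirectional — non-AF beats surrounded by AF flip to
AF as well — because one-directional revalidation can only lower
sensitivity, while closing single-beat gaps inside episodes is exactly what
raises it; the one-directional variant would be a strict subset of this
behavior.

Window geometry: width w counts beats *including* the centre — ⌊w/2⌋
before, w−1−⌊w/2⌋ after — so odd widths are exactly centred and even widths
are off-centre by one beat. Windows truncate at record edges and the
percentage uses the beats actually available. A consequence worth knowing:
on an even-width window, perfect predictions flip exactly one beat at each
episode boundary regardless of p; the grid search trades this against the
noise it removes. Smoothing is applied within each record; a window never
spans two signals.

The grid is w = 10…190 step 10 × p = 5…95 step 5 (361 cells); ties in
F-Score resolve to the smallest w, then smallest p. Reported optima are the
search's own argmax on the data at hand — they are data-dependent and are
not hard-coded.

## Dataset construction

* Training draws are without replacement throughout.
* Odd minority counts floor at 50 % (⌊N_minority/2⌋ per class).
* Mixed-signal designs draw size/2 beats per class uniformly from the
  pooled class populations of the named signal group; per-signal
  stratification is available by drawing per signal instead.
* Single-class records cannot seed a balanced draw and raise a dedicated
  error; they still contribute testing beats and pool members.
* Randomness: one master seed; Monte Carlo repeats use child seeds spawned
  via `numpy.random.SeedSequence`, so repeats are independent and the whole
  protocol is reproducible bit-for-bit.
* The rdann-style annotation reader labels each RR interval with the rhythm
  state at its *starting* beat; rhythm intervals are half-open
  [change, next change), records without rhythm annotations are non-AF.

## Synthetic generator

The generator emulates the two regimes a beat classifier must separate:

* **Sinus**: stationary AR(1) around 800 ms with marginal SD 20 ms and
  lag-1 correlation 0.8 — smooth, respiratory-like variability.
* **AF**: independent draws around 600 ms with successive-difference SD
  120 ms — fast and erratic. This is a deliberate caricature of
  fibrillatory conduction, not a physiological model.
* **Rhythm**: a two-state Markov chain, default p_enter = 0.002 and
  p_exit = 0.003 per beat, giving a stationary AF fraction of 0.40 (close
  to the 42.56 % of the reference beat database) and mean episode lengths
  of hundreds of beats, i.e. minutes — matching the clinical picture of AF
  episodes. Per-signal prevalence overrides (including exact 0 and 1)
  mimic the extreme imbalance spread of real records.
* RR intervals are floored at 250 ms (HR ≤ 240 bpm) so all features stay
  finite.

What passing tests on this generator do **not** show: robustness to ectopic
beats, detector artifacts, sinus arrhythmia that mimics irregularity, or AF
with atypical ventricular response — the synthetic separation is wide, so
end-to-end accuracy here is an upper bound, a check of plumbing and of the
method's ability to exploit genuine separation, not a clinical claim.

## Problem sizes

Default study conditions for end-to-end runs: 25 synthetic records of 2000
beats (50 000 beats, ~49 500 valid), balanced training draws of 2000
vectors, the full 361-cell aggregation grid; Monte Carlo summaries use
repeated redraws at these sizes. These sizes exercise every code path at
full fidelity while keeping a complete run in seconds.

## Known limitations

* Beats are taken as given; there is no QRS detection, waveform processing
  or signal-quality assessment, and no frequency-domain HRV.
* No minimum-episode-duration filter (e.g. 30-s clinical-significance
  rules); episodes are maximal runs of AF beats, whatever their length.
* The LSVM stores and factorizes the full N×N dual matrix; training sets
  beyond a few tens of thousands of vectors need a different solver.
* No probability calibration or score thresholding; decisions are hard.
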