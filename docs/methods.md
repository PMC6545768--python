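# Methods

`fdbci` studies how robust fractal-dimension (FD) features are for
two-class motor-imagery EEG classification when the training and testing
recordings come from different days, and how much a per-subject choice of
bandpass cutoff frequencies improves accuracy over the conventional fixed
1–100 Hz filter.  This note describes the models, the estimators, the
synthetic study the package evaluates itself on, and the numerical and
design choices a maintainer should know about.

## Pipeline

1. **Preprocessing.** Each 3 s trial (250 Hz, 22 channels in the emulated
   recordings) is bandpass filtered and an analysis window is cut out.
   The candidate filters form a grid: passband width `W ∈ {10, 20, …, 100}`
   Hz crossed with integer low cutoff `f_low ∈ {1, …, 125 − W}` Hz, so every
   band `[f_low, f_low + W]` stays at or below the 125 Hz Nyquist limit —
   700 configurations, plus the off-grid *classical* 1–100 Hz baseline.
2. **Feature extraction.** Per channel and trial, one of: Higuchi FD,
   Katz FD (both `M`-dimensional feature vectors for `M` channels), or the
   coefficients of an AR(2) model (`2M`-dimensional).
3. **Classification.** Fisher's linear discriminant
   (`w ∝ S_pooled⁻¹ (μ₁ − μ₀)`, threshold at the projected midpoint).
4. **Evaluation protocol.** Condition A trains on the day-1 session and
   tests on day 2; Condition B swaps the roles.  Each evaluation repeats
   30 times; each repetition draws a class-stratified 70% subset
   (`⌊0.7 n_class⌋` per class, without replacement) independently from the
   training and the testing session.  The mean ± sd of the 30 accuracies is
   reported.
5. **Statistics.** Kruskal–Wallis across the three techniques' accuracy
   groups at α = 0.05, followed (when significant) by Tukey–Kramer
   comparisons on mean ranks against the best technique; a two-sided
   Wilcoxon rank-sum test at α = 0.01 compares optimal-band and
   classical-band accuracies; the *increase rate* is
   `100 · (acc_opt − acc_cls) / acc_cls` percent.

## Feature estimators

**Higuchi.** For lag `k = 1..k_max` and offset `m = 1..k` the curve length
is `L_m(k) = (1/k) Σ_i |x(m+ik) − x(m+(i−1)k)| · (N−1)/(n_k k)` with
`n_k = ⌊(N−m)/k⌋`; `L(k)` averages the offsets and FD is the least-squares
slope of `ln L(k)` against `ln(1/k)`.  `k_max = 8` by default for
500-sample windows (the estimate is stable between `k_max` 4 and 16; all
three are exercised in the tests).  Implementation detail: for each lag the
per-offset sums are folded into one precomputed weight vector, so a batch
of windows reduces to one absolute-difference array and one matrix–vector
product per lag.  A straight line gives FD = 1 exactly (the log–log fit
has zero residual); white noise estimates ≈ 2; an H = 0.5 random walk
≈ 1.5.  Narrowband-filtered noise can estimate slightly above 2; the
estimator logs (but does not reject) values outside [1, 2].

**Katz.** With `n = N − 1` steps, path length `L = Σ|Δx|` and diameter
`d = max_i |x(i) − x(1)|`: `FD = log₁₀(n) / (log₁₀(n) + log₁₀(d/L))`.
This is the waveform (unit abscissa) reading of Katz's estimator; the
Euclidean-with-time-axis variant is out of scope.  Monotone signals give
exactly 1.  Note Katz's value depends on the sampling rate and routinely
exceeds 2 on noisy, heavily oversampled signals; only between-class
contrast matters here.

**AR(2).** Burg's lattice recursion (vectorized across windows, matching
per-window reference implementations to machine precision) in the
prediction-form convention `x(t) ≈ a₁x(t−1) + a₂x(t−2) + e(t)`; reflection
coefficients bounded by 1 guarantee a stable model on short windows.
Yule–Walker estimation is available as a cross-check option.  Signals are
demeaned before fitting.

Both FD estimators are exactly invariant to amplitude offset and positive
rescaling, so no feature standardization is applied before the (itself
affine-equivariant) discriminant.

## Filtering and windowing

The bandpass is zero phase: the trial's DFT is multiplied by the squared
magnitude response of a 4th-order Butterworth bandpass — the frequency
response forward–backward IIR filtering applies — and inverted.  This
realization was chosen over running an IIR filter twice because (i) its
phase is exactly zero, (ii) it has no numerical start-up transient, and
(iii) the trial spectrum is computed once per session, making a
700-configuration sweep two orders of magnitude cheaper.  Circular edge
effects are confined to the trial boundaries; the analysis window is
therefore **centered** in the trial by default (offset 0.5 s for the
default 2 s window in a 3 s trial), which also keeps any filter transient
of whatever realization outside the analysed samples.  Window lengths of
1, 1.5 and 2 s are supported; 2 s is the default.

Grid bands whose upper edge reaches 125 Hz exactly (e.g. 115–125) are
realized as a Butterworth highpass at `f_low`, since a bandpass cannot
place its upper −3 dB point on the Nyquist frequency itself; bands strictly
above Nyquist are rejected before any data is touched.

The evaluation engine computes filtering and features in float32 (the
public single-signal functions and the discriminant use float64); FD
values agree with the float64 path to ~2·10⁻⁷, far below any decision
threshold in the pipeline.

## Synthetic study

`SyntheticConfig` emulates the structure the analysis assumes, not any
particular subject:

| parameter | default | meaning |
|---|---|---|
| `n_channels`, `fs`, `trial_seconds` | 22, 250 Hz, 3 s | recording geometry |
| `trials_per_class_per_session` | 72 | 6 runs × 12 trials per class |
| `erd_band` | (8, 12) Hz | mu-band rhythm carrying the class effect |
| `erd_channels` | (7, 9, 11) | sensorimotor subset with the ERD |
| `erd_depth` | 0.6 | fractional rhythm attenuation in class 1 |
| `osc_amplitude` | 0.5 | rhythm amplitude vs unit-variance background |
| `background_exponent` | 1.0 | 1/f^β spectral slope of the background |
| `session_gain` | 0.85 | day-2 amplitude factor |
| `session_noise_sd` | 0.3 | day-2 added white-noise sd |
| `session_freq_shift` | 0.5 Hz | day-2 rhythm peak shift |

Each channel is independent 1/f^β noise (spectrally shaped white noise,
normalized to unit variance) plus a Hann-enveloped sinusoid at the band
center with a random per-trial/channel phase; class-1 trials attenuate the
sinusoid by `erd_depth` on `erd_channels`.  Day 2 applies the three drift
parameters.  One master seed expands to per-(session, trial) substreams
keyed by counters, so identical configurations reproduce bit-identically
and subsets are reproducible.  `osc_amplitude = 0.5` with the default
drift was fixed once so that the classical-band accuracy (~0.5–0.65) and
narrowband accuracy (~0.8) of the simulated subject fall in the range
published cross-session motor-imagery studies report; with the first
value tried (2.0) every configuration classified at ceiling and band
selection was vacuous.

What the generator does **not** emulate: volume conduction (channels are
independent), EOG/EMG artifacts, line noise, heavy-tailed amplitude
distributions, or within-session drift.  Consequences observed in the
package's own tests: Higuchi FD and AR(2) separate the classes well,
while **Katz FD has almost no leverage on this waveform family** (its
diameter-to-path ratio barely moves when the rhythm amplitude changes
inside a band).  A passing pipeline therefore demonstrates correct
mechanics and a recoverable planted effect, not that any particular
technique would win on real recordings.

Session drift is likewise band-dependent for FD features: the day-2 noise
floor raises broadband complexity, so the cross-session penalty shows
clearly under the classical 1–100 Hz filter (FD is amplitude-invariant, so
the gain factor alone is invisible to it); the drift test in the suite
uses that configuration with matched training-set sizes.

## Statistical protocol: known optimism

The 30 repetition accuracies of one evaluation are **not** independent:
consecutive 70% subsets share most of their trials, so the 30 values
cluster tightly around a study-realization-specific accuracy.  Rank tests
that assume independent observations (Kruskal–Wallis across techniques,
rank-sum between bands) read the spread of those cluster centers as
evidence and reject far above their nominal level under a true null — a
property of the resampling protocol itself, reproduced faithfully here and
demonstrated by two deliberately strict tests in the acceptance suite
(which fail, documenting the measured null rejection rates of ~0.7–0.8
against nominal 0.05/0.01).  Band selection adds a second optimism: the
optimal band is chosen and scored on the same resamples (mirrored from the
original protocol, and noted in the outputs), and even "fresh" resamples
reuse the trials the band was overfitted to.  Conclusions drawn from these
p-values on real data should be treated as exploratory; only fresh
*sessions* decorrelate the selection.

## Numerical and design details

- Grid-search ties (equal mean accuracy) break to the smaller width, then
  the smaller low cutoff.
- Decision-plane ties in the discriminant go to the negative-side class.
- The pooled covariance gets a ridge `λ = 10⁻⁶ tr(S)/d` only if its
  Cholesky factorization fails (e.g. duplicated feature columns).
- Subsets too small for the feature dimension (`n ≤ d`) raise a dedicated
  error; the grid search records such configurations as missing rather
  than skipping them silently.
- Degenerate inputs: constant signals are rejected by all three feature
  estimators with the offending trial and channel identified; identical
  constant accuracy groups give Kruskal–Wallis "degenerate, no
  difference" and rank-sum p = 1.
- Desk-scale defaults used by the package's own test suite: 6–8 channels,
  16–36 trials per class, 2 s trials with a 1 s window for protocol-level
  simulations; the planted-band recovery check runs at the full default
  geometry (22 channels, 72 trials/class/session, 20 independent studies,
  reduced grid of widths {10, 20, 40} Hz at low-cutoff stride 2).
- GDF ingestion (for the public competition recordings) is an optional
  extra behind `mne`; everything else runs without external data.

## Limitations

- The synthetic generator's simplifications above; in particular, absolute
  accuracies and increase rates are properties of the simulated subject,
  not predictions for any real one.
- Only two classes and a single linear classifier are in scope; no
  spatial filtering (e.g. CSP), artifact handling, or alternative
  classifiers.
- The per-subject window-length choice is supported but not automated:
  all three lengths can be run and compared, the default is 2 s.
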