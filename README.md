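# fdbci

Fractal-dimension EEG features and per-subject frequency-band selection for
cross-session motor-imagery classification.

## The problem

A brain–computer interface (BCI) must classify short EEG trials reliably
even though the signals are nonstationary — most severely when the
classifier is trained on one day's recording session and used on another.
This package implements and evaluates a pipeline built around two ideas:

1. **Fractal dimension (FD) as a feature.** The FD of a waveform is a
   dimensionless complexity index (1 for a smooth line, 2 for
   plane-filling noise).  When a motor task desynchronizes a narrowband
   sensorimotor rhythm (an *event-related desynchronization*, ERD), the
   rhythm-to-noise ratio on the affected channels changes and so does the
   waveform's FD.  Two time-domain estimators are provided — Higuchi's
   (slope of the mean curve length `L(k) ∝ k^{-FD}` in log–log
   coordinates) and Katz's (`FD = log₁₀ n / (log₁₀ n + log₁₀ (d/L))` from
   the path length `L`, diameter `d` and step count `n`) — plus the
   coefficients of an AR(2) model as the classical linear baseline.
2. **Per-subject bandpass selection.**  Instead of the conventional fixed
   1–100 Hz filter, the pipeline sweeps a grid of 700 passbands
   (widths `W ∈ {10, …, 100}` Hz × low cutoffs `f_low ∈ {1, …, 125 − W}` Hz)
   and selects the band that maximizes classification accuracy, reporting
   the relative gain over the classical band (the *increase rate*, in %).

Classification uses Fisher's linear discriminant,
`w ∝ S_pooled⁻¹(μ₁ − μ₀)`.  Robustness is measured cross-session:
Condition A trains on day 1 and tests on day 2, Condition B the reverse;
every evaluation repeats 30 times on stratified random 70% subsets of both
sessions, and techniques/bands are compared with rank-based tests
(Kruskal–Wallis with a Tukey–Kramer mean-rank post hoc; a Wilcoxon
rank-sum improvement test at α = 0.01).

Because public competition recordings are an optional download, the
package ships a synthetic study generator that emulates the relevant
structure — 1/f background, a class-attenuated mu-band rhythm on a few
channels, and controlled between-day drift — so the whole pipeline is
testable offline.  See `docs/methods.md` for the model details and known
limitations, including an honest analysis of the resampling protocol's
statistical optimism.

Audience: BCI and neural-signal-processing researchers who want a tested,
reproducible reference implementation of FD-based classification with
filter-bank band selection, or a harness to study cross-session
robustness protocols.

## Worked example

```python
import fdbci

cfg = fdbci.SyntheticConfig(seed=42)           # 22 ch, 250 Hz, 2 x 144 trials
day1, day2 = fdbci.generate_study(cfg)
report = fdbci.run_condition(
    day1, day2, condition="A", techniques=("higuchi", "katz", "ar"),
    seed=42, widths=(10, 20, 40), f_low_stride=2,   # reduced desk-scale grid
)
for name, o in report.outcomes.items():
    print(f"{name:8s} classical {o.classical.mean:.3f}+/-{o.classical.std:.3f}  "
          f"optimal {o.optimal.mean:.3f}+/-{o.optimal.std:.3f}  "
          f"band {o.grid.selected}  increase {o.increase_rate:5.1f}%  "
          f"improvement p {o.improvement_p:.1e}")
```

prints

```
higuchi  classical 0.666+/-0.083  optimal 0.832+/-0.037  band 9-19  increase  25.0%  improvement p 7.4e-11
katz     classical 0.476+/-0.041  optimal 0.595+/-0.035  band 3-13  increase  25.1%  improvement p 2.5e-10
ar       classical 0.531+/-0.043  optimal 0.829+/-0.038  band 9-49  increase  56.3%  improvement p 2.9e-11
```

Reading: with the fixed 1–100 Hz filter this simulated subject classifies
near chance-to-moderate levels (0.48–0.67); selecting the band per
technique recovers the planted 8–12 Hz rhythm (bands 9–19, 3–13, 9–49 all
cover it) and lifts accuracy by 25–56%, significant at α = 0.01 for every
technique.  The means and standard deviations summarize 30 resampled
train/test repetitions each.

The same run from the shell, with CSV tables written to `out/`:

```bash
fdbci run --condition A --grid reduced --seed 42 --out out/
```

(`accuracy_classical.csv`, `accuracy_optimal.csv`, `selected_bands.csv`,
`increase_rate.csv`, `stats.csv`, `band_curves.csv`; runs repeated with
the same seed are byte-identical.)  `fdbci simulate` writes synthetic
sessions to HDF5; `fdbci evaluate` scores a single band.

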