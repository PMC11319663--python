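# startlelab

Startle-blink EMG analysis for threat-of-shock neurostimulation
experiments: session scheduling, synthetic surface-EMG simulation, blink
scoring, potentiated-startle difference scores, and within-subject
statistics.

## What it is for

In the NPU threat paradigm, participants experience alternating Neutral
(no shock), Predictable (shock only during a cue) and Unpredictable
(shock at any time) blocks while brief white-noise probes elicit the
startle eyeblink, measured as orbicularis-oculi EMG.  Two difference
scores summarize threat reactivity:

* **FPS** (fear-potentiated startle) = mean(P cue) − mean(P ITI)
* **APS_ITI** (anxiety-potentiated startle) = mean(U ITI) − mean(N ITI)

In crossover neurostimulation designs (e.g. active vs sham theta-burst
stimulation of the dorsolateral prefrontal cortex), these scores per
subject and session feed a 2 (coil: active vs sham) × 2 (response type:
FPS vs APS) repeated-measures ANOVA with partial eta-squared
(η²ₚ = F·df₁/(F·df₁ + df₂)) and post-hoc paired t-tests.

`startlelab` provides that full chain for researchers who score startle
EMG or prototype such designs:

* **schedules** — validated, seeded builders for NPU runs (block orders
  `NPNUNUNP` / `NUNPNPNU`, 16 trials/condition across two runs, 3
  shocks/run), habituation series (9 probes ~17 s apart), three Sternberg
  working-memory variants, theta-burst pulse trains (600-pulse default
  session) and the 100-ms / 200-Hz shock pulse train.
* **synth** — continuous 2000-Hz EMG with calibrated noise-burst blinks,
  condition-dependent potentiation, per-trial habituation, transient
  baseline artifacts, no-blink trials, 0–10 anxiety ratings, and a fast
  score-level study generator with exact standardized-effect control.
* **scoring** — 30–300 Hz zero-phase bandpass → rectify → 20-ms smooth;
  raw amplitude = peak (20–120 ms post-probe) − baseline (50 ms
  pre-probe); noisy-trial exclusion (baseline SD > 2× run SD), no-blink
  zero-coding, t-score normalization (t = z·10 + 50).
* **outcomes** — condition means, FPS/APS_ITI, outlier truncation at
  mean ± 2 SD (single pass, original moments), Sternberg behaviour cells.
* **stats** — 2×2 within-subject ANOVA (each F equals the squared paired
  t of its contrast), partial eta-squared, paired t with Cohen's d, and
  noncentral-t power / sample-size for the paired test.

## Worked example

Simulate a small crossover study end to end (synthetic EMG → scoring →
difference scores → ANOVA):

```python
from startlelab.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo", seed=7, n_subjects=4, log_level="WARNING")
bundle = run_pipeline(cfg)
print(bundle["anova_table"].round(3).to_string(index=False))
```

prints

```
  measure                    term       F  df1  df2     p  partial_eta_sq
startle_t                 session  35.956    1    3 0.009           0.923
startle_t           response_type  81.534    1    3 0.003           0.965
startle_t session x response_type   1.728    1    3 0.280           0.365
   rating                 session   3.121    1    3 0.175           0.510
   rating           response_type 108.876    1    3 0.002           0.973
   rating session x response_type   0.172    1    3 0.706           0.054
```

Reading the startle rows: the simulated active session potentiates both
FPS and APS (a `session` main effect), FPS exceeds APS (`response_type`),
and there is no session-by-response-type interaction — the effect
structure the generator injects.  Ratings show the response-type effect
but no reliable session effect, mirroring a double-blind manipulation
check.  (At n = 4 the F values are unstable; the design-scale behaviour
is exercised by the test suite at n = 28.)  The per-subject difference
scores behind the ANOVA:

```
subject_id session   measure   FPS  APS_ITI
    sub-00  active startle_t  9.18     5.54
    sub-00    sham startle_t  8.73     3.87
    sub-01  active startle_t 10.13     4.48
    sub-01    sham startle_t  7.60     3.50
```

The same stages are available from the shell:

```sh
startlelab schedule npu --seed 3 --out npu_events.csv
startlelab power --d 0.6 --alpha 0.025 --power 0.8
# -> required n = 29 (d=0.6, two-tailed alpha=0.025, power=0.8)
startlelab run-all --seed 7 --n-subjects 4 --out demo/
```

## Layout

```
src/startlelab/
  schedules.py   session timing: NPU, habituation, Sternberg, pulse trains
  synth.py       synthetic EMG + ratings with ground truth
  scoring.py     envelope, windowed peak scoring, exclusion, t-scores
  outcomes.py    condition means, FPS/APS_ITI, truncation, behaviour
  stats.py       2x2 RM-ANOVA, eta-squared, paired t, power
  io.py          CSV dialects, seed derivation
  pipeline.py    simulate -> score -> aggregate -> anova runner
  cli.py         command-line interface
docs/methods.md  model assumptions, parameter defaults, limitations
```
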