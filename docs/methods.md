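# Methods

## Scope and model of the experiment

`startlelab` implements the desk-scale analysis chain of a threat-of-shock
psychophysiology study with noninvasive brain stimulation: the timed
structure of the experimental sessions, a synthetic surface-EMG generator
with known ground truth, startle-blink scoring from continuous EMG, the
fear- and anxiety-potentiated startle difference scores, and the
within-subject statistics run on them.  Raw laboratory recordings from
such studies are rarely shareable, so the package treats the simulator as
a first-class component: every downstream stage is exercised against data
whose true blink amplitudes, artifact positions and population effects
are known exactly.

### Session schedules

The NPU threat task alternates Neutral (never shocked), Predictable
(shock possible only during an 8-s visual cue) and Unpredictable (shock
possible at any time) blocks.  A testing session has two runs with the
counterbalanced 8-block orders `NPNUNUNP` and `NUNPNPNU`; threat blocks
are always separated by a neutral block.  Each N block contributes 2
startle-probe trials per phase (cue / ITI) and each P and U block 4 per
phase, giving 16 trials per condition across the two runs.  Three shocks
per run are attached uniformly at random, without replacement, to
eligible intervals (P-cue or any U interval).

Probe timing inside blocks is not dictated by the design, only the cue
duration (8 s) is.  We place one probe per interval with uniform jitter,
ITI durations uniform on 12–18 s, a ≥2-s margin after interval onset, a
≥1-s margin before interval end, and a minimum of 8 s between successive
probes (standard practice to avoid blink refractoriness).  With these
margins a feasible probe position always exists, so placement is a single
sequential pass, no rejection sampling.

The habituation series is 9 unsignaled probes ~17 s apart (jitter ±2 s by
default).  The Sternberg working-memory variants reproduce the printed
trial arithmetic (12 per condition for the targeting session, 3 per
condition per block × 2 blocks × 2 runs for the testing-threat variant, 4
per condition for the TMS-session runs), the printed duration ranges
(letters 1.5–2.5 s, retention 6.5–8.5 s, ITI 5–8 s, instruction exactly
1 s, response prompt exactly 3 s), match/mismatch balance within each
trial type, and 2 extra shock trials per testing-threat run confined to
threat blocks and excluded from behavioural aggregation.

Theta-burst pulse trains are fully parametrized (trains × bursts ×
pulses, intra-burst rate, burst rate, inter-train gap).  The default
intermittent-TBS session is 10 trains × 20 triplet bursts at 50 Hz
repeated at 5 Hz, i.e. the canonical 600-pulse dose.  The published train
description is internally inconsistent (60-pulse trains vs "2 s of
stimulation", which at 3-pulse 5-Hz bursts is 30 pulses); the only
unambiguous anchor is the 600-pulse session total, which is what the
default configuration asserts.  The shock stimulus is a 100-ms train of
2-ms pulses at 200 Hz (20 pulses, 5-ms onset spacing).

### Synthetic EMG

A blink is synthesized as a Gaussian-windowed band-limited noise burst
added to baseline Gaussian noise at 2000 Hz.  Surface EMG is a stochastic
interference signal, which is exactly why the rectify-then-smooth
envelope is the appropriate amplitude estimator; the simulator mirrors
that physics rather than using a deterministic template.  Two choices
matter:

* **Constant-envelope carrier.**  The carrier is band-limited (70–250 Hz)
  Gaussian noise divided by its instantaneous Hilbert magnitude, i.e. a
  random-phase, constant-magnitude oscillation.  With a plain Gaussian
  carrier the realized envelope peak of a single burst varies by ~9%
  (few independent samples under a 20-ms smoothing window); the
  constant-envelope carrier reduces this to ~4% so that single-trial
  recovered amplitudes track ground truth tightly.
* **Gaussian window with σ = width/4** (default width 60 ms, onset
  latency 45 ms), so the burst's ±2σ support spans the nominal width and
  the tail at the probe onset is negligible — blink energy must not leak
  into the 50-ms pre-probe baseline window.

The mapping from requested amplitude to scoring-chain envelope peak is a
single empirical gain (`ENVELOPE_GAIN = 1.7267`), estimated as the
reciprocal mean envelope peak of 1000 noise-free unit bursts and frozen
in code; `calibrate_envelope_gain()` regenerates it and a test asserts
the frozen value is current within 2%.

Per trial, the true amplitude is `base × condition multiplier ×
habituation_decay^rank` (rank = chronological probe index in the
session; defaults: base 100 µV, decay 0.985).  No-blink trials
(probability `no_blink_prob`) have amplitude 0.  Artifact trials
(probability `artifact_prob`) have a 20-ms stretch of the pre-probe
baseline noise amplified by `artifact_gain` (default 10) — a transient,
as real spontaneous-blink or motion artifacts are.  A uniform
amplification of the entire baseline window would be nearly undetectable
under the run-SD exclusion rule below, because it shifts the envelope
mean (inflating the pooled run SD) more than the within-window SD; the
transient's sharp edges are what the rule can see.  When several
artifacts land in the same run they can still partially mask each other
by inflating the pooled run SD — that is a property of the exclusion
rule itself and is reported, not hidden.

Study-level generation has two tiers.  `simulate_study_scores` draws
subject-level FPS/APS difference scores directly from the
repeated-measures effect model: subject random intercepts, a response-type
shift, a coil (active−sham) shift applied equally to FPS and APS (no
interaction), and cell noise.  The coil shift is `d × σ_w` where σ_w is
the cell SD, which makes the population Cohen's d of the per-subject coil
contrast exactly `d` — this exactness is what the calibration tests rely
on.  Ratings get a response-type effect and a zero coil effect,
mirroring the double-blind manipulation check.  `simulate_study` renders
full EMG per subject and session; there the coil effect is expressed as
extra fractional potentiation of the threat conditions (t-normalization
within session removes any overall gain difference, so an amplitude-scale
"coil effect" would vanish by construction).  Defaults: n = 28 subjects,
coil d = 0.43, response-type d = 0.61 — the standardized effects implied
by the published F values at n = 28 via d = √(F/n).

What the simulator does **not** model: biophysical motor-unit dynamics,
shock-evoked EMG contamination, non-stationary baseline drift, electrode
artifacts other than the transient above, and any coupling between
ratings and EMG noise.  Passing tests therefore demonstrate that the
pipeline recovers what the model of the data contains — calibrated
amplitudes, condition structure, known contaminants — not that it is
robust to every failure mode of laboratory EMG.

### Startle scoring

The chain follows standard psychophysiological practice: 30–300 Hz
4th-order Butterworth bandpass applied forward and backward (zero phase,
preserves blink latency), full-wave rectification, and a centred 20-ms
boxcar (reflection padding).  Raw amplitude = max of the envelope in the
20–120 ms post-probe window minus the mean of the 50-ms pre-probe
window.  Window endpoints are converted to samples by rounding half up;
the baseline window is half-open `[onset−50 ms, onset)`, the peak window
closed `[onset+20 ms, onset+120 ms]`.

Trials whose baseline SD exceeds 2× the run SD are excluded as missing.
"Run SD" is the sample SD of the envelope over the concatenation of all
the run's baseline windows (robust to blink energy; a whole-run variant
is selectable).  Trials whose peak fails to clear the baseline excursion
(peak < baseline mean + baseline max−min; a literal peak < range variant
is selectable) are coded 0 but retained.  Raw amplitudes are then
t-scored within subject-session (per-run selectable): z over non-missing
trials (zero-coded included, sample SD), t = 10z + 50.  Zero-coded trials
stay in the pool because they are data — a genuine absence of response —
whereas noisy trials are measurement failures.

The no-blink rule deserves a caveat: on stationary noise it is a
statistical detector, catching ~70–80% of genuinely blink-free trials at
our default noise level while never zero-coding a calibrated blink.
That operating characteristic belongs to the rule, not to this
implementation.

### Outcomes and statistics

Condition means are computed per subject-session over non-missing trials;
FPS = mean(P_cue) − mean(P_iti) and APS_ITI = mean(U_iti) − mean(N_iti),
identically for startle t-scores and 0–10 ratings.  Difference scores
(the analyzed values) are truncated at mean ± 2 sample SD per analysis
cell (coil session × measure, across subjects), using the moments of the
original vector in a single pass; a flag truncates condition means
instead.  With the sample-SD convention a vector of ≤5 values can never
be truncated (max standardized deviation (n−1)/√n < 2).

The 2 (coil) × 2 (response type) fully within-subject ANOVA is computed
by the contrast decomposition: each term's F is the squared paired t of
its per-subject contrast, df = (1, n−1), which is algebraically identical
to the sums-of-squares decomposition with per-effect error terms (tests
verify this against an independent SS oracle and against pingouin).
Sphericity is moot with two-level factors, so no correction exists.
Subjects with missing cells are dropped listwise with a log line.  The
published effect sizes follow the partial eta-squared identity
pes = F·df1/(F·df1 + df2); all eight printed (F, η²) pairs at df2 = 27
reproduce to 2 decimals under this convention, which is why partial
eta-squared is the implemented one.

Power for the paired t-test uses the noncentral t distribution
(ncp = d√n, critical value from the central t at the two-tailed alpha),
exact at small n; `required_n` returns the smallest n reaching the target
power.  At d = 0.6, α = 0.025 two-tailed, power 0.8 it returns 29.
Post-hoc paired t-tests report uncorrected p with Cohen's d for dependent
means (mean difference / SD of differences); the α = 0.025 convention is
carried in the output metadata rather than adjusting p.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the study's
own scale where that is cheap (schedules, ANOVA, truncation, power) and
at deliberately chosen simulation sizes elsewhere: scoring fidelity uses
full two-run NPU sessions (96 trials, ~19 min of 2000-Hz signal);
statistical calibration uses 500 replicate studies of 28 subjects drawn
from the score-level generator; the F = t² oracle suite uses 100 random
datasets with n between 4 and 28.  Envelope calibration uses 1000
noise-free bursts.  Seeds: a single global seed derives every substream
via `SeedSequence` over CRC-32-hashed keys (stage, subject), keeping all
derived seeds below 2³¹; identical configuration + seed reproduces every
table bit-for-bit.

Degenerate inputs are errors, not warnings: zero-variance normalization
groups, constant ANOVA contrasts, fewer than 3 complete subjects,
out-of-range scoring windows, infeasible shock counts, and pulse widths
at or above the pulse period all raise with the offending group, trial or
parameter named.

## Known limitations

* The published real-data startle result (coil main effect F(1,27) = 5.1
  on recorded EMG) is not reproducible here: the raw recordings are not
  deposited.  The package reproduces the design arithmetic, the formula
  anchors and the statistical machinery, and demonstrates calibration on
  synthetic data at the published design size.
* Ratings are generated, not modelled from EMG; any EMG–rating coupling
  is absent.
* The EMG-level coil effect is qualitative (sign and monotonicity), not
  an exact standardized effect; exact effect-size control lives at the
  score level.
* fMRI acquisition and analysis, electric-field modelling, motor
  thresholding and hardware control are out of scope.
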