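"""Synthetic EMG and ratings with known ground truth.

The study's raw orbicularis-oculi recordings are not deposited, so this
module generates continuous 2000-Hz surface-EMG traces that exercise every
downstream stage with known truth: noise-burst blink responses time-locked
to the acoustic probes, condition-dependent potentiation, per-trial
habituation, occasional baseline artifacts and no-blink trials, plus 0-10
subjective anxiety ratings.

A blink is modelled as a Gaussian-windowed band-limited noise burst: a
surface-EMG interference pattern is stochastic, which is exactly why the
rectify-then-smooth envelope is the right amplitude estimator downstream.
Burst synthesis normalizes the carrier's realized energy under the window
and applies a fixed empirical gain so that the scoring chain's envelope
peak reproduces the requested amplitude (see
:func:`calibrate_envelope_gain`).

Two study-level generators exist:

* :func:`simulate_study_scores` draws subject-level FPS/APS difference
  scores directly from the study's repeated-measures effect model (exact
  standardized-effect parametrization; cheap enough for large calibration
  simulations);
* :func:`simulate_study` renders full EMG recordings per subject and
  session for end-to-end pipeline runs at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .schedules import (
    HabituationSchedule,
    NpuRun,
    NpuSchedule,
    build_npu_schedule,
    place_shocks,
)
from .scoring import ScoringConfig, preprocess

__all__ = [
    "BlinkSimParams",
    "EmgEvent",
    "EmgRecording",
    "StudyEffectSpec",
    "blink_burst",
    "calibrate_envelope_gain",
    "simulate_session",
    "simulate_ratings",
    "simulate_study_scores",
    "simulate_study",
    "ENVELOPE_GAIN",
]

#: Empirical gain mapping requested blink amplitude to the scoring chain's
#: envelope peak, estimated from 1000 noise-free unit bursts at the default
#: parameters (reproduce with ``calibrate_envelope_gain()``).
ENVELOPE_GAIN = 1.7267


@dataclass(frozen=True)
class BlinkSimParams:
    """Ground-truth blink and noise model for one simulated session."""

    base_amplitude_uv: float = 100.0
    onset_latency_ms: float = 45.0
    burst_width_ms: float = 60.0
    carrier_band_hz: tuple[float, float] = (70.0, 250.0)
    baseline_noise_sd_uv: float = 2.0
    habituation_decay: float = 0.985
    condition_multipliers: dict = field(default_factory=dict)
    artifact_prob: float = 0.0
    artifact_gain: float = 10.0
    no_blink_prob: float = 0.0
    fs_hz: float = 2000.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_amplitude_uv < 0 or self.baseline_noise_sd_uv < 0:
            raise ValueError("amplitudes and noise SD must be >= 0")
        if not 0 < self.habituation_decay <= 1:
            raise ValueError("habituation_decay must lie in (0, 1]")
        for p in (self.artifact_prob, self.no_blink_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.artifact_gain <= 1:
            raise ValueError("artifact_gain must exceed 1")
        if any(m <= 0 for m in self.condition_multipliers.values()):
            raise ValueError("condition multipliers must be strictly positive")
        lo, hi = self.carrier_band_hz
        if not 0 < lo < hi < self.fs_hz / 2:
            raise ValueError("carrier band must lie inside (0, fs/2)")


@dataclass
class EmgEvent:
    event_type: str  # probe / shock
    onset_s: float
    condition_label: str
    trial_index: int


@dataclass
class EmgRecording:
    """One continuous EMG channel with its event markers and (simulation
    only) the per-trial ground truth."""

    sampling_rate_hz: float
    samples: np.ndarray
    events: list[EmgEvent]
    subject_id: str
    session_label: str
    run: int = 0
    ground_truth: pd.DataFrame | None = None


def _carrier(n: int, band: tuple[float, float], fs: float, rng: np.random.Generator) -> np.ndarray:
    """Constant-envelope band-limited stochastic carrier: band-limited
    Gaussian noise divided by its instantaneous (Hilbert) magnitude, so the
    realized burst envelope is set by the window rather than by the carrier
    draw.  Extra samples pad the Hilbert transform's edges."""
    pad = 200
    sos = butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))
    mag = np.abs(hilbert(x))
    mag[mag == 0] = 1.0
    return (x / mag)[pad : pad + n]


def blink_burst(
    amplitude_uv: float,
    latency_ms: float = 45.0,
    width_ms: float = 60.0,
    carrier_band: tuple[float, float] = (70.0, 250.0),
    fs: float = 2000.0,
    rng: np.random.Generator | None = None,
    gain: float = ENVELOPE_GAIN,
) -> np.ndarray:
    """One zero-mean blink burst, to be added at the probe onset sample.

    The rectified-smoothed envelope (scoring-chain defaults) peaks near
    ``latency_ms`` after segment start with height ~= ``amplitude_uv``.
    The carrier is constant-envelope random-phase band-limited noise, so
    the realized envelope peak tracks the requested amplitude tightly.
    """
    if amplitude_uv < 0:
        raise ValueError("amplitude must be >= 0")
    if width_ms <= 0:
        raise ValueError("width must be positive")
    lo, hi = carrier_band
    if not 0 < lo < hi < fs / 2:
        raise ValueError("carrier band must lie inside (0, fs/2)")
    rng = rng or np.random.default_rng()
    seg_s = (latency_ms + 3.0 * width_ms) / 1000.0
    n = int(round(seg_s * fs))
    if amplitude_uv == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    # sigma = width/4: the burst's effective support (+/- 2 sigma) spans
    # ``width_ms`` and the tail at segment start is negligible, keeping
    # blink energy out of the pre-probe baseline window
    sigma_s = width_ms / 4.0 / 1000.0
    window = np.exp(-0.5 * ((t - latency_ms / 1000.0) / sigma_s) ** 2)
    carrier = _carrier(n, carrier_band, fs, rng)
    return amplitude_uv * gain * window * carrier


def calibrate_envelope_gain(
    n_bursts: int = 1000,
    fs: float = 2000.0,
    latency_ms: float = 45.0,
    width_ms: float = 60.0,
    carrier_band: tuple[float, float] = (70.0, 250.0),
    seed: int = 20_240_101,
) -> float:
    """Re-estimate :data:`ENVELOPE_GAIN`: the reciprocal of the mean
    scoring-chain envelope peak of noise-free unit-amplitude bursts."""
    rng = np.random.default_rng(seed)
    cfg = ScoringConfig()
    pad = int(0.5 * fs)
    peaks = np.empty(n_bursts)
    for i in range(n_bursts):
        burst = blink_burst(1.0, latency_ms, width_ms, carrier_band, fs, rng, gain=1.0)
        sig = np.zeros(2 * pad + burst.size)
        sig[pad : pad + burst.size] = burst
        env = preprocess(sig, fs, cfg)
        peaks[i] = env.max()
    return float(1.0 / peaks.mean())


DEFAULT_RATING_MEANS = {
    "N_iti": 1.0, "N_cue": 1.0,
    "P_iti": 2.0, "P_cue": 4.0,
    "U_iti": 4.5, "U_cue": 5.0,
    "habituation": 1.0,
}


def _probe_events(schedule: NpuSchedule | HabituationSchedule | NpuRun) -> list[list[EmgEvent]]:
    """Per-run probe/shock event lists."""
    if isinstance(schedule, NpuSchedule):
        runs = schedule.runs
    elif isinstance(schedule, NpuRun):
        runs = [schedule]
    elif isinstance(schedule, HabituationSchedule):
        evs = [
            EmgEvent("probe", t, "habituation", i)
            for i, t in enumerate(schedule.probe_times_s)
        ]
        return [evs]
    else:
        raise TypeError(f"unsupported schedule type {type(schedule).__name__}")
    out = []
    for run in runs:
        evs = []
        for t in run.trials:
            evs.append(EmgEvent("probe", t.probe_time_s, t.condition_label, t.trial_index))
            if t.shock_time_s is not None:
                evs.append(EmgEvent("shock", t.shock_time_s, t.condition_label, t.trial_index))
        evs.sort(key=lambda e: e.onset_s)
        out.append(evs)
    return out


def simulate_session(
    schedule: NpuSchedule | HabituationSchedule | NpuRun,
    params: BlinkSimParams,
    subject_id: str = "sub-00",
    session_label: str = "pretest",
    rng: np.random.Generator | None = None,
) -> list[EmgRecording]:
    """Render continuous EMG for every run of a schedule.

    The trace is baseline Gaussian noise plus one blink burst per probe with
    true amplitude ``base x condition multiplier x decay^rank`` (rank =
    chronological probe index across the session).  No-blink trials get
    amplitude 0; artifact trials have their pre-probe baseline noise
    scaled by ``artifact_gain``.  Ground truth is attached per recording.
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    fs = params.fs_hz
    cfg = ScoringConfig()
    bwin = int(round(cfg.baseline_window_ms / 1000.0 * fs))
    recordings = []
    rank = 0
    for run_index, events in enumerate(_probe_events(schedule)):
        probes = [e for e in events if e.event_type == "probe"]
        dur_s = max(e.onset_s for e in events) + 2.0
        n = int(round(dur_s * fs))
        sig = rng.standard_normal(n) * params.baseline_noise_sd_uv
        truth_rows = []
        for ev in probes:
            onset = int(round(ev.onset_s * fs))
            is_no_blink = bool(rng.random() < params.no_blink_prob)
            is_artifact = bool(rng.random() < params.artifact_prob)
            mult = params.condition_multipliers.get(ev.condition_label, 1.0)
            amp = 0.0 if is_no_blink else (
                params.base_amplitude_uv * mult * params.habituation_decay**rank
            )
            if is_artifact:
                # transient baseline artifact: a ~20-ms stretch of the
                # pre-probe noise amplified by artifact_gain, mimicking a
                # spontaneous blink / motion transient; the abrupt
                # excursion inflates the within-window baseline SD far
                # more than the pooled run SD
                a_len = int(round(0.020 * fs))
                a0 = onset - bwin + int(rng.integers(0, max(1, bwin - a_len)))
                sig[a0 : a0 + a_len] *= params.artifact_gain
            if amp > 0:
                burst = blink_burst(
                    amp,
                    params.onset_latency_ms,
                    params.burst_width_ms,
                    params.carrier_band_hz,
                    fs,
                    rng,
                )
                end = min(n, onset + burst.size)
                sig[onset:end] += burst[: end - onset]
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "session": session_label,
                    "run": run_index,
                    "trial_index": ev.trial_index,
                    "condition_label": ev.condition_label,
                    "true_amplitude_uv": amp,
                    "is_artifact": is_artifact,
                    "is_no_blink": is_no_blink,
                }
            )
            rank += 1
        recordings.append(
            EmgRecording(
                sampling_rate_hz=fs,
                samples=sig,
                events=events,
                subject_id=subject_id,
                session_label=session_label,
                run=run_index,
                ground_truth=pd.DataFrame(truth_rows),
            )
        )
    return recordings


def simulate_ratings(
    schedule: NpuSchedule,
    rng: np.random.Generator,
    condition_means: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    subject_id: str = "sub-00",
    session_label: str = "pretest",
) -> pd.DataFrame:
    """Per-trial 0-10 anxiety ratings: condition mean plus truncated-normal
    noise, clipped to the scale."""
    means = dict(DEFAULT_RATING_MEANS)
    if condition_means:
        means.update(condition_means)
    rows = []
    for run in schedule.runs:
        for t in run.trials:
            val = means.get(t.condition_label, 1.0) + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "subject_id": subject_id,
                    "session": session_label,
                    "run": run.run_index,
                    "trial_index": t.trial_index,
                    "condition_label": t.condition_label,
                    "rating": float(np.clip(val, 0.0, 10.0)),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StudyEffectSpec:
    """Population effect structure of the crossover study.

    Standardized effects are on the scale of the paired contrast analyzed
    downstream: ``coil_effect_d`` is the population Cohen's d of the
    active-sham difference of the startle difference scores (applied
    equally to FPS and APS, i.e. no coil-by-response-type interaction);
    ``response_type_effect_d`` the d of the FPS-APS contrast.  Ratings get
    a response-type effect but no coil effect, matching the double-blind
    manipulation check.
    """

    n_subjects: int = 28
    coil_effect_d: float = 0.43
    response_type_effect_d: float = 0.61
    between_subject_sd: float = 4.0
    within_subject_sd: float = 8.0
    startle_grand_mean: float = 6.0
    ratings_response_type_effect_d: float = 1.29
    ratings_between_subject_sd: float = 0.8
    ratings_within_subject_sd: float = 1.5
    ratings_grand_mean: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for sd in (
            self.between_subject_sd,
            self.within_subject_sd,
            self.ratings_between_subject_sd,
            self.ratings_within_subject_sd,
        ):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")


def _draw_measure(
    rng: np.random.Generator,
    n: int,
    grand_mean: float,
    coil_d: float,
    rt_d: float,
    sd_b: float,
    sd_w: float,
) -> np.ndarray:
    """Cells (subject, coil x response-type) for one measure.

    The coil shift is ``coil_d x sd_w`` because the per-subject coil
    contrast (mean over the two response types, active - sham) has SD
    ``sd_w``; likewise for the response-type shift.  Returns an array of
    shape (n, 2, 2) indexed [subject, coil(sham=0/active=1), type(FPS=0/APS=1)].
    """
    b = rng.normal(0.0, sd_b, size=(n, 1, 1))
    eps = rng.normal(0.0, sd_w, size=(n, 2, 2))
    coil = np.array([0.0, coil_d * sd_w]).reshape(1, 2, 1)
    rtype = np.array([rt_d * sd_w / 2.0, -rt_d * sd_w / 2.0]).reshape(1, 1, 2)
    return grand_mean + b + coil + rtype + eps


def simulate_study_scores(spec: StudyEffectSpec,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subject-level FPS / APS difference scores for both measures and
    both coil sessions, drawn directly from the study effect model.

    Returns a tidy frame with columns subject_id, session, measure, FPS,
    APS_ITI — the exact shape the ANOVA stage consumes.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    n = spec.n_subjects
    startle = _draw_measure(
        rng, n, spec.startle_grand_mean, spec.coil_effect_d,
        spec.response_type_effect_d, spec.between_subject_sd,
        spec.within_subject_sd,
    )
    ratings = _draw_measure(
        rng, n, spec.ratings_grand_mean, 0.0,
        spec.ratings_response_type_effect_d, spec.ratings_between_subject_sd,
        spec.ratings_within_subject_sd,
    )
    rows = []
    for i in range(n):
        sid = f"sub-{i:02d}"
        for ci, coil in enumerate(("sham", "active")):
            rows.append({"subject_id": sid, "session": coil, "measure": "startle_t",
                         "FPS": startle[i, ci, 0], "APS_ITI": startle[i, ci, 1]})
            rows.append({"subject_id": sid, "session": coil, "measure": "rating",
                         "FPS": ratings[i, ci, 0], "APS_ITI": ratings[i, ci, 1]})
    return pd.DataFrame(rows)


#: Baseline fractional potentiation of the EMG-level generator: the P-cue
#: blink is 45% larger than P-ITI, the U-ITI blink 30% larger than N-ITI.
FPS_POTENTIATION = 0.45
APS_POTENTIATION = 0.30
#: Converts a standardized coil effect into extra fractional potentiation
#: in the active session (qualitative mapping; exact effect calibration is
#: the score-level generator's job).
COIL_POTENTIATION_SCALE = 0.25


def simulate_study(
    spec: StudyEffectSpec,
    blink: BlinkSimParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[EmgRecording], pd.DataFrame]:
    """Full-EMG rendering of the crossover study: for every subject and
    coil session, an NPU schedule with shocks, two EMG run recordings, and
    per-trial ratings.  Intended for end-to-end pipeline runs at small n;
    the active session potentiates both FPS and APS contrasts, ratings
    carry no coil effect.
    """
    blink = blink or BlinkSimParams()
    rng = rng or np.random.default_rng(spec.rng_seed)
    recs: list[EmgRecording] = []
    ratings = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i:02d}"
        subj_gain = float(rng.normal(1.0, 0.1))
        for coil in ("sham", "active"):
            extra = spec.coil_effect_d * COIL_POTENTIATION_SCALE if coil == "active" else 0.0
            mult = {
                "N_iti": 1.0,
                "N_cue": 1.0,
                "P_iti": 1.1,
                "P_cue": 1.1 * (1.0 + FPS_POTENTIATION + extra),
                "U_cue": 1.35,
                "U_iti": 1.0 + APS_POTENTIATION + extra,
            }
            seed = int(rng.integers(0, 2**31 - 1))
            sched = place_shocks(
                build_npu_schedule(rng_seed=seed), n_per_run=3, rng_seed=seed + 1
            )
            params = BlinkSimParams(
                base_amplitude_uv=blink.base_amplitude_uv * max(subj_gain, 0.2),
                onset_latency_ms=blink.onset_latency_ms,
                burst_width_ms=blink.burst_width_ms,
                carrier_band_hz=blink.carrier_band_hz,
                baseline_noise_sd_uv=blink.baseline_noise_sd_uv,
                habituation_decay=blink.habituation_decay,
                condition_multipliers=mult,
                artifact_prob=blink.artifact_prob,
                artifact_gain=blink.artifact_gain,
                no_blink_prob=blink.no_blink_prob,
                fs_hz=blink.fs_hz,
                rng_seed=seed,
            )
            recs.extend(simulate_session(sched, params, sid, coil, rng=rng))
            ratings.append(
                simulate_ratings(sched, rng, subject_id=sid, session_label=coil)
            )
    return recs, pd.concat(ratings, ignore_index=True)
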