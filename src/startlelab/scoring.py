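"""Startle-blink EMG scoring.

The processing chain for orbicularis-oculi surface EMG recorded around
acoustic startle probes:

1. zero-phase bandpass filter (30-300 Hz, 4th-order Butterworth applied
   forward and backward),
2. full-wave rectification,
3. smoothing with a centred 20-ms boxcar (reflection padding at the edges),
4. per-trial peak scoring: raw amplitude = max of the envelope in the
   20-120 ms post-probe window minus the mean of the 50-ms pre-probe
   baseline window,
5. noisy-trial exclusion (baseline SD > 2x the run's baseline SD ->
   missing), no-blink coding (peak below the baseline excursion -> scored
   0 but retained), and
6. t-score normalization within subject-session: t = z * 10 + 50.

Window endpoints are converted to sample indices by rounding half up; the
baseline window is half-open ``[onset-50ms, onset)`` and the peak window is
closed ``[onset+20ms, onset+120ms]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "ScoringConfig",
    "TrialScore",
    "preprocess",
    "score_trial",
    "flag_noisy",
    "code_no_blink",
    "t_normalize",
    "score_recording",
    "scores_to_frame",
]

VALID = "valid"
MISSING_NOISY = "missing_noisy"
ZERO_NO_BLINK = "zero_no_blink"


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the scoring chain.  Defaults follow standard startle
    methodology: 30-300 Hz band, 20-ms smoothing, peak in 20-120 ms
    post-probe, 50-ms baseline, exclusion at 2x the run baseline SD."""

    band_low_hz: float = 30.0
    band_high_hz: float = 300.0
    smooth_window_ms: float = 20.0
    peak_window_ms: tuple[float, float] = (20.0, 120.0)
    baseline_window_ms: float = 50.0
    noise_multiplier: float = 2.0
    filter_order: int = 4
    #: "session" or "run": grouping for t-score normalization.
    group_by: str = "session"
    #: if True, code no-blink when peak < (baseline max - min) alone;
    #: default compares against baseline mean + range.
    literal_baseline_range: bool = False
    #: if True, the run SD used for noisy-trial exclusion is the SD of the
    #: whole-run envelope instead of the concatenated baseline windows.
    run_sd_whole_run: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        lo, hi = self.peak_window_ms
        if not lo < hi:
            raise ValueError("peak window start must precede its end")
        if min(self.smooth_window_ms, self.baseline_window_ms) <= 0:
            raise ValueError("window lengths must be positive")
        if self.noise_multiplier <= 0:
            raise ValueError("noise_multiplier must be positive")
        if self.group_by not in ("session", "run"):
            raise ValueError("group_by must be 'session' or 'run'")


@dataclass
class TrialScore:
    """One trial's scored startle response."""

    subject_id: str
    session: str
    run: int
    trial_index: int
    condition_label: str
    probe_onset_s: float
    raw_amplitude_uv: float
    baseline_mean_uv: float
    baseline_sd_uv: float
    peak_uv: float
    status: str = VALID
    z_value: float | None = None
    t_value: float | None = None
    extras: dict = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def preprocess(samples: np.ndarray, fs_hz: float, cfg: ScoringConfig | None = None) -> np.ndarray:
    """Bandpass-filter, rectify and smooth a raw EMG trace; returns the
    nonnegative envelope at the input length and rate."""
    cfg = cfg or ScoringConfig()
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D signal")
    if fs_hz / 2.0 <= cfg.band_high_hz:
        raise ValueError(
            f"sampling rate {fs_hz} Hz too low for a {cfg.band_high_hz} Hz band edge"
        )
    sos = butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=fs_hz,
        output="sos",
    )
    if x.size <= 3 * cfg.filter_order * 2:
        raise ValueError("signal shorter than the filter warm-up")
    filtered = sosfiltfilt(sos, x)
    rectified = np.abs(filtered)
    win = max(1, _round_half_up(fs_hz * cfg.smooth_window_ms / 1000.0))
    return uniform_filter1d(rectified, size=win, mode="reflect")


def _trial_windows(
    probe_onset_s: float, fs_hz: float, n: int, cfg: ScoringConfig
) -> tuple[slice, slice]:
    onset = _round_half_up(probe_onset_s * fs_hz)
    b0 = onset - _round_half_up(cfg.baseline_window_ms / 1000.0 * fs_hz)
    p0 = onset + _round_half_up(cfg.peak_window_ms[0] / 1000.0 * fs_hz)
    p1 = onset + _round_half_up(cfg.peak_window_ms[1] / 1000.0 * fs_hz)
    if b0 < 0 or p1 + 1 > n:
        raise ValueError(
            f"scoring windows for probe at {probe_onset_s:.3f} s fall outside the recording"
        )
    return slice(b0, onset), slice(p0, p1 + 1)  # peak window inclusive at the end


def score_trial(
    envelope: np.ndarray,
    probe_onset_s: float,
    fs_hz: float,
    cfg: ScoringConfig | None = None,
) -> tuple[float, float, float, float]:
    """Score one trial on a preprocessed envelope.

    Returns ``(raw_amplitude, baseline_mean, baseline_sd, peak)`` where
    raw amplitude = peak - baseline mean.
    """
    cfg = cfg or ScoringConfig()
    env = np.asarray(envelope, dtype=float)
    bsl, pk = _trial_windows(probe_onset_s, fs_hz, env.size, cfg)
    baseline = env[bsl]
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std(ddof=1))
    peak = float(env[pk].max())
    return peak - baseline_mean, baseline_mean, baseline_sd, peak


def flag_noisy(
    trial_scores: list[TrialScore],
    envelope: np.ndarray,
    fs_hz: float,
    cfg: ScoringConfig | None = None,
) -> list[TrialScore]:
    """Mark trials whose baseline SD exceeds ``noise_multiplier`` times the
    run SD as missing.  The run SD is the sample SD of the envelope over the
    concatenation of all the run's baseline windows (optionally the whole
    run).  Returns new TrialScore objects; input untouched."""
    cfg = cfg or ScoringConfig()
    if not trial_scores:
        raise ValueError("flag_noisy requires at least one scored trial")
    env = np.asarray(envelope, dtype=float)
    if cfg.run_sd_whole_run:
        run_sd = float(env.std(ddof=1))
    else:
        segs = [
            env[_trial_windows(t.probe_onset_s, fs_hz, env.size, cfg)[0]]
            for t in trial_scores
        ]
        run_sd = float(np.concatenate(segs).std(ddof=1))
    out = []
    for t in trial_scores:
        if t.baseline_sd_uv > cfg.noise_multiplier * run_sd:
            out.append(replace(t, status=MISSING_NOISY, z_value=None, t_value=None))
        else:
            out.append(replace(t))
    return out


def code_no_blink(
    trial_scores: list[TrialScore],
    envelope: np.ndarray,
    fs_hz: float,
    cfg: ScoringConfig | None = None,
) -> list[TrialScore]:
    """Code trials without a detectable blink as 0.

    A trial has no blink when its peak fails to clear the baseline
    excursion: default reading peak < baseline mean + (baseline max - min);
    ``literal_baseline_range`` compares the peak to the range alone.
    Zero-coded trials stay in the normalization pool and condition means.
    """
    cfg = cfg or ScoringConfig()
    env = np.asarray(envelope, dtype=float)
    out = []
    for t in trial_scores:
        if t.status == MISSING_NOISY:
            out.append(replace(t))
            continue
        bsl, _ = _trial_windows(t.probe_onset_s, fs_hz, env.size, cfg)
        brange = float(env[bsl].max() - env[bsl].min())
        threshold = brange if cfg.literal_baseline_range else t.baseline_mean_uv + brange
        if t.peak_uv < threshold:
            out.append(replace(t, status=ZERO_NO_BLINK, raw_amplitude_uv=0.0))
        else:
            out.append(replace(t))
    return out


def t_normalize(
    trial_scores: list[TrialScore],
    group_by: str = "session",
) -> list[TrialScore]:
    """Convert raw amplitudes to t-scores within each normalization group.

    Grouping is per subject-session by default (``group_by="run"`` adds the
    run).  Within a group, z = (raw - mean) / sample SD over all non-missing
    trials (zero-coded trials included), then t = z * 10 + 50.  Missing
    trials receive no t-value.
    """
    if group_by not in ("session", "run"):
        raise ValueError("group_by must be 'session' or 'run'")

    def key(t: TrialScore):
        k = (t.subject_id, t.session)
        return k + (t.run,) if group_by == "run" else k

    groups: dict[tuple, list[TrialScore]] = {}
    for t in trial_scores:
        groups.setdefault(key(t), []).append(t)

    out: list[TrialScore] = []
    for gkey, members in groups.items():
        usable = [t for t in members if t.status != MISSING_NOISY]
        raws = np.array([t.raw_amplitude_uv for t in usable])
        if raws.size < 2:
            raise ValueError(f"group {gkey}: fewer than 2 usable trials")
        sd = raws.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {gkey}: zero variance among usable trials")
        mean = raws.mean()
        for t in members:
            if t.status == MISSING_NOISY:
                out.append(replace(t, z_value=None, t_value=None))
            else:
                z = (t.raw_amplitude_uv - mean) / sd
                out.append(replace(t, z_value=float(z), t_value=float(z * 10 + 50)))
    out.sort(key=lambda t: (t.subject_id, t.session, t.run, t.trial_index))
    return out


def score_recording(recording, cfg: ScoringConfig | None = None,
                    normalize: bool = True) -> list[TrialScore]:
    """Run the full chain on one continuous recording.

    ``recording`` is an :class:`~startlelab.synth.EmgRecording`-like object
    with ``samples``, ``sampling_rate_hz``, ``subject_id``, ``session_label``,
    ``run`` and probe ``events`` (``event_type == "probe"``).  Noise flags are
    computed per run; normalization honours ``cfg.group_by``.
    """
    cfg = cfg or ScoringConfig()
    env = preprocess(recording.samples, recording.sampling_rate_hz, cfg)
    scores: list[TrialScore] = []
    for ev in recording.events:
        if ev.event_type != "probe":
            continue
        raw, bmean, bsd, peak = score_trial(env, ev.onset_s, recording.sampling_rate_hz, cfg)
        scores.append(
            TrialScore(
                subject_id=recording.subject_id,
                session=recording.session_label,
                run=recording.run,
                trial_index=ev.trial_index,
                condition_label=ev.condition_label,
                probe_onset_s=ev.onset_s,
                raw_amplitude_uv=raw,
                baseline_mean_uv=bmean,
                baseline_sd_uv=bsd,
                peak_uv=peak,
            )
        )
    scores = flag_noisy(scores, env, recording.sampling_rate_hz, cfg)
    scores = code_no_blink(scores, env, recording.sampling_rate_hz, cfg)
    if normalize:
        scores = t_normalize(scores, group_by=cfg.group_by)
    return scores


def scores_to_frame(scores: list[TrialScore]) -> pd.DataFrame:
    """Trial scores as a tidy table (one row per trial)."""
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in scores],
            "session": [t.session for t in scores],
            "run": [t.run for t in scores],
            "trial_index": [t.trial_index for t in scores],
            "condition_label": [t.condition_label for t in scores],
            "raw_uv": [t.raw_amplitude_uv for t in scores],
            "z": [t.z_value for t in scores],
            "t": [t.t_value for t in scores],
            "status": [t.status for t in scores],
        }
    )
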