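"""Timed structure of the experimental sessions.

Builds validated, seeded schedules for every session type in the protocol:

* the NPU threat task (alternating Neutral / Predictable / Unpredictable
  blocks with acoustic startle probes and electric shocks),
* the startle habituation series,
* the three Sternberg working-memory variants (fMRI targeting,
  testing-session threat variant, short TMS-session runs),
* theta-burst stimulation pulse trains and the shock stimulus pulse train.

All times are seconds from run start.  Schedules are plain dataclasses and
serialize to a long-format event table (one row per probe / shock / pulse)
via :func:`schedule_to_table`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NpuTrial",
    "NpuBlock",
    "NpuRun",
    "NpuSchedule",
    "HabituationSchedule",
    "SternbergTrial",
    "SternbergSchedule",
    "PulseTrainSchedule",
    "NPU_BLOCK_ORDERS",
    "build_npu_schedule",
    "place_shocks",
    "build_habituation_schedule",
    "build_sternberg_schedule",
    "build_itbs_schedule",
    "build_shock_pulse_train",
    "schedule_to_table",
]

#: The two counterbalanced 8-block orders used on testing sessions.
NPU_BLOCK_ORDERS: tuple[str, str] = ("NPNUNUNP", "NUNPNPNU")

#: Cue geometry/colour labels per block type (display is out of scope; the
#: labels ride along so event tables are self-describing).
CUE_LABELS = {"N": "orange_triangle", "P": "teal_square", "U": "purple_pentagon"}

#: Probe trials per phase (cue / iti) contributed by one block of each type.
DEFAULT_TRIALS_PER_BLOCK = {"N": 2, "P": 4, "U": 4}

CUE_DURATION_S = 8.0
DEFAULT_ITI_RANGE_S = (12.0, 18.0)
MIN_PROBE_GAP_S = 8.0
PROBE_DURATION_S = 0.040
#: Probe placement margins inside an interval: keeps the baseline window
#: clear of the interval transition and the blink window inside the interval.
PROBE_MARGIN_START_S = 2.0
PROBE_MARGIN_END_S = 1.0
RUN_START_OFFSET_S = 10.0


@dataclass
class NpuTrial:
    """One startle-probe trial inside an NPU block."""

    trial_index: int
    block_index: int
    block_type: str  # N / P / U
    phase: str  # cue / iti
    interval_start_s: float
    interval_end_s: float
    probe_time_s: float
    cue_label: str | None
    shock_time_s: float | None = None

    @property
    def condition_label(self) -> str:
        return f"{self.block_type}_{self.phase}"


@dataclass
class NpuBlock:
    block_index: int
    block_type: str
    trials: list[NpuTrial]


@dataclass
class NpuRun:
    run_index: int
    block_order: str
    blocks: list[NpuBlock]

    @property
    def trials(self) -> list[NpuTrial]:
        return [t for b in self.blocks for t in b.trials]

    @property
    def shock_times_s(self) -> list[float]:
        return sorted(
            t.shock_time_s for t in self.trials if t.shock_time_s is not None
        )

    @property
    def duration_s(self) -> float:
        return max(t.interval_end_s for t in self.trials)


@dataclass
class NpuSchedule:
    runs: list[NpuRun]

    def condition_counts(self) -> dict[str, int]:
        """Trials per condition label, pooled across runs."""
        counts: dict[str, int] = {}
        for run in self.runs:
            for t in run.trials:
                counts[t.condition_label] = counts.get(t.condition_label, 0) + 1
        return counts


@dataclass
class HabituationSchedule:
    probe_times_s: list[float]


@dataclass
class SternbergTrial:
    trial_index: int
    run_index: int
    block_index: int
    trial_type: str  # sort / maintain
    block_condition: str  # safe / threat / none
    instruction_s: float
    letters_s: float
    retention_s: float
    probe_s: float
    iti_s: float
    is_match: bool
    is_shock_trial: bool

    @property
    def duration_s(self) -> float:
        return (
            self.instruction_s
            + self.letters_s
            + self.retention_s
            + self.probe_s
            + self.iti_s
        )


@dataclass
class SternbergSchedule:
    session_kind: str  # targeting / testing_threat / tms
    trials: list[SternbergTrial]

    def cell_counts(self, include_shock: bool = False) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for t in self.trials:
            if t.is_shock_trial and not include_shock:
                continue
            key = (t.trial_type, t.block_condition)
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class PulseTrainSchedule:
    pulse_times_s: np.ndarray
    train_bounds: list[tuple[float, float]]
    params: dict = field(default_factory=dict)

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times_s.size)


def _validate_block_order(order: str) -> None:
    if len(order) != 8:
        raise ValueError(f"block order must have 8 blocks, got {len(order)!r}: {order}")
    if set(order) - set("NPU"):
        raise ValueError(f"block order may only contain N, P, U: {order}")
    for a, b in zip(order, order[1:]):
        if {a, b} <= {"P", "U"} and "N" not in (a, b):
            raise ValueError(
                f"threat blocks must be separated by a neutral block: {order}"
            )


def _place_probe(
    rng: np.random.Generator,
    interval: tuple[float, float],
    prev_probe: float,
) -> float:
    """Uniform probe placement honouring interval margins and the minimum
    inter-probe gap.  Feasibility is guaranteed for cue >= 8 s and iti >= 12 s
    intervals with the default margins."""
    start, end = interval
    lo = max(start + PROBE_MARGIN_START_S, prev_probe + MIN_PROBE_GAP_S)
    hi = end - PROBE_MARGIN_END_S
    if lo > hi:
        raise ValueError(
            f"no feasible probe position in interval ({start:.2f}, {end:.2f})"
        )
    return float(rng.uniform(lo, hi))


def _build_npu_run(
    run_index: int,
    order: str,
    trials_per_block: dict[str, int],
    iti_range_s: tuple[float, float],
    rng: np.random.Generator,
) -> NpuRun:
    blocks: list[NpuBlock] = []
    clock = RUN_START_OFFSET_S
    prev_probe = -np.inf
    trial_index = 0
    for block_index, block_type in enumerate(order):
        n = trials_per_block[block_type]
        trials: list[NpuTrial] = []
        # Each trial pair is an ITI interval followed by the 8-s cue; one
        # probe falls in each interval.
        for _ in range(n):
            iti_len = float(rng.uniform(*iti_range_s))
            iti = (clock, clock + iti_len)
            clock = iti[1]
            cue = (clock, clock + CUE_DURATION_S)
            clock = cue[1]

            p_iti = _place_probe(rng, iti, prev_probe)
            prev_probe = p_iti
            trials.append(
                NpuTrial(
                    trial_index=trial_index,
                    block_index=block_index,
                    block_type=block_type,
                    phase="iti",
                    interval_start_s=iti[0],
                    interval_end_s=iti[1],
                    probe_time_s=p_iti,
                    cue_label=None,
                )
            )
            trial_index += 1

            p_cue = _place_probe(rng, cue, prev_probe)
            prev_probe = p_cue
            trials.append(
                NpuTrial(
                    trial_index=trial_index,
                    block_index=block_index,
                    block_type=block_type,
                    phase="cue",
                    interval_start_s=cue[0],
                    interval_end_s=cue[1],
                    probe_time_s=p_cue,
                    cue_label=CUE_LABELS[block_type],
                )
            )
            trial_index += 1
        blocks.append(NpuBlock(block_index=block_index, block_type=block_type, trials=trials))
    return NpuRun(run_index=run_index, block_order=order, blocks=blocks)


def build_npu_schedule(
    order_pair: tuple[str, str] = NPU_BLOCK_ORDERS,
    trial_params: dict[str, int] | None = None,
    rng_seed: int = 0,
    iti_range_s: tuple[float, float] = DEFAULT_ITI_RANGE_S,
) -> NpuSchedule:
    """Build the two-run NPU schedule.

    Parameters
    ----------
    order_pair
        The block order of each run; defaults to the two counterbalanced
        printed orders.
    trial_params
        Probe trials per phase contributed by one block of each type
        (default N=2, P=4, U=4, which yields 16 trials per condition
        across the two runs).
    rng_seed
        Seed controlling ITI durations and probe jitter.
    """
    trials_per_block = dict(DEFAULT_TRIALS_PER_BLOCK)
    if trial_params:
        trials_per_block.update(trial_params)
    if len(order_pair) != 2:
        raise ValueError("order_pair must contain exactly two run orders")
    for order in order_pair:
        _validate_block_order(order)
    if iti_range_s[0] < MIN_PROBE_GAP_S + PROBE_MARGIN_END_S:
        raise ValueError("minimum ITI too short for probe spacing constraints")
    rng = np.random.default_rng(rng_seed)
    runs = [
        _build_npu_run(i, order, trials_per_block, iti_range_s, rng)
        for i, order in enumerate(order_pair)
    ]
    return NpuSchedule(runs=runs)


def eligible_shock_trials(run: NpuRun) -> list[NpuTrial]:
    """Trials that may carry a shock: predictable-cue intervals and any
    unpredictable interval (cue or ITI).  Neutral blocks never shock."""
    out = []
    for t in run.trials:
        if t.block_type == "P" and t.phase == "cue":
            out.append(t)
        elif t.block_type == "U":
            out.append(t)
    return out


def place_shocks(
    schedule: NpuSchedule, n_per_run: int = 3, rng_seed: int = 0
) -> NpuSchedule:
    """Attach ``n_per_run`` shocks per run, uniformly without replacement
    over eligible trials, with the shock time uniform inside the trial's
    interval.  Returns a new schedule; the input is not mutated."""
    if n_per_run < 0:
        raise ValueError("n_per_run must be >= 0")
    out = copy.deepcopy(schedule)
    rng = np.random.default_rng(rng_seed)
    for run in out.runs:
        for t in run.trials:
            t.shock_time_s = None
        eligible = eligible_shock_trials(run)
        if n_per_run > len(eligible):
            raise ValueError(
                f"run {run.run_index}: {n_per_run} shocks requested but only "
                f"{len(eligible)} eligible trials"
            )
        chosen = rng.choice(len(eligible), size=n_per_run, replace=False)
        for idx in chosen:
            trial = eligible[int(idx)]
            trial.shock_time_s = float(
                rng.uniform(trial.interval_start_s, trial.interval_end_s)
            )
    return out


def build_habituation_schedule(
    n_probes: int = 9,
    mean_isi_s: float = 17.0,
    jitter_s: float = 2.0,
    rng_seed: int = 0,
    start_s: float = 10.0,
) -> HabituationSchedule:
    """Unsignaled probe series preceding the NPU task: ``n_probes`` probes
    with successive gaps uniform in ``mean_isi_s +/- jitter_s``."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if mean_isi_s <= 0:
        raise ValueError("mean_isi_s must be positive")
    if jitter_s < 0:
        raise ValueError("jitter_s must be >= 0")
    if mean_isi_s - jitter_s <= PROBE_DURATION_S:
        raise ValueError("mean_isi_s - jitter_s must exceed the probe duration")
    rng = np.random.default_rng(rng_seed)
    times = [float(start_s)]
    for _ in range(n_probes - 1):
        gap = float(rng.uniform(mean_isi_s - jitter_s, mean_isi_s + jitter_s))
        times.append(times[-1] + gap)
    return HabituationSchedule(probe_times_s=times)


_STERNBERG_DEFAULTS = {"targeting": 12, "testing_threat": 3, "tms": 4}

INSTRUCTION_S = 1.0
RESPONSE_PROBE_S = 3.0
LETTERS_RANGE_S = (1.5, 2.5)
RETENTION_RANGE_S = (6.5, 8.5)
STERNBERG_ITI_RANGE_S = (5.0, 8.0)
SHOCK_TRIALS_PER_RUN = 2


def _match_flags(n: int, rng: np.random.Generator) -> list[bool]:
    if n % 2:
        raise ValueError(
            f"cannot balance matches and mismatches over {n} trials (odd count)"
        )
    flags = [True] * (n // 2) + [False] * (n // 2)
    rng.shuffle(flags)
    return flags


def _draw_durations(rng: np.random.Generator) -> dict[str, float]:
    return {
        "instruction_s": INSTRUCTION_S,
        "letters_s": float(rng.uniform(*LETTERS_RANGE_S)),
        "retention_s": float(rng.uniform(*RETENTION_RANGE_S)),
        "probe_s": RESPONSE_PROBE_S,
        "iti_s": float(rng.uniform(*STERNBERG_ITI_RANGE_S)),
    }


def build_sternberg_schedule(
    session_kind: str,
    trials_per_condition: int | None = None,
    rng_seed: int = 0,
) -> SternbergSchedule:
    """Build a Sternberg working-memory schedule.

    ``trials_per_condition`` means trials per trial type for ``targeting``
    and ``tms`` sessions, and trials per trial type *per block* for
    ``testing_threat`` sessions (2 safe + 2 threat blocks per run, 2 runs,
    so the default 3/block yields 12 per trial-type-by-condition cell).
    Testing-threat runs additionally carry 2 shock trials placed in random
    threat-block positions; these are marked ``is_shock_trial`` and are
    excluded from the match/mismatch balance (they are discarded before
    behavioural analysis).
    """
    if session_kind not in _STERNBERG_DEFAULTS:
        raise ValueError(f"unknown session_kind {session_kind!r}")
    tpc = _STERNBERG_DEFAULTS[session_kind] if trials_per_condition is None else int(trials_per_condition)
    if tpc < 1:
        raise ValueError("trials_per_condition must be >= 1")
    rng = np.random.default_rng(rng_seed)
    trials: list[SternbergTrial] = []
    idx = 0

    def add_trial(run_i: int, block_i: int, ttype: str, cond: str,
                  is_match: bool, shock: bool = False) -> None:
        nonlocal idx
        trials.append(
            SternbergTrial(
                trial_index=idx,
                run_index=run_i,
                block_index=block_i,
                trial_type=ttype,
                block_condition=cond,
                is_match=is_match,
                is_shock_trial=shock,
                **_draw_durations(rng),
            )
        )
        idx += 1

    if session_kind in ("targeting", "tms"):
        flags = {t: _match_flags(tpc, rng) for t in ("sort", "maintain")}
        order = ["sort"] * tpc + ["maintain"] * tpc
        rng.shuffle(order)
        taken = {"sort": 0, "maintain": 0}
        for ttype in order:
            add_trial(0, 0, ttype, "none", flags[ttype][taken[ttype]])
            taken[ttype] += 1
    else:  # testing_threat
        n_runs, blocks_per_cond = 2, 2
        total_per_cell = tpc * blocks_per_cond * n_runs
        flags = {
            (t, c): _match_flags(total_per_cell, rng)
            for t in ("sort", "maintain")
            for c in ("safe", "threat")
        }
        taken = {k: 0 for k in flags}
        for run_i in range(n_runs):
            # block order counterbalanced across runs
            conds = ["safe", "threat"] * blocks_per_cond if run_i % 2 == 0 else ["threat", "safe"] * blocks_per_cond
            threat_blocks = [i for i, c in enumerate(conds) if c == "threat"]
            # choose (block, position) slots for the run's shock trials
            shock_slots = sorted(
                (int(b), int(p))
                for b, p in zip(
                    rng.choice(threat_blocks, size=SHOCK_TRIALS_PER_RUN, replace=True),
                    rng.integers(0, 2 * tpc + 1, size=SHOCK_TRIALS_PER_RUN),
                )
            )
            for block_i, cond in enumerate(conds):
                order = ["sort"] * tpc + ["maintain"] * tpc
                rng.shuffle(order)
                pending = [(p, "shock") for b, p in shock_slots if b == block_i]
                pos = 0
                for ttype in order:
                    while pending and pending[0][0] <= pos:
                        pending.pop(0)
                        add_trial(run_i, block_i, str(rng.choice(["sort", "maintain"])),
                                  cond, bool(rng.integers(0, 2)), shock=True)
                    key = (ttype, cond)
                    add_trial(run_i, block_i, ttype, cond, flags[key][taken[key]])
                    taken[key] += 1
                    pos += 1
                for _ in pending:
                    add_trial(run_i, block_i, str(rng.choice(["sort", "maintain"])),
                              cond, bool(rng.integers(0, 2)), shock=True)
    return SternbergSchedule(session_kind=session_kind, trials=trials)


def build_itbs_schedule(
    n_trains: int = 10,
    bursts_per_train: int = 20,
    pulses_per_burst: int = 3,
    intra_burst_rate_hz: float = 50.0,
    burst_rate_hz: float = 5.0,
    inter_train_gap_s: float = 8.0,
) -> PulseTrainSchedule:
    """Intermittent theta-burst pulse train: triplet 50-Hz bursts repeated at
    5 Hz within trains, trains separated by a stimulation-free gap.  The
    default configuration delivers the 600-pulse session dose
    (10 trains x 20 bursts x 3 pulses)."""
    if min(n_trains, bursts_per_train, pulses_per_burst) < 1:
        raise ValueError("counts must be >= 1")
    if intra_burst_rate_hz <= 0 or burst_rate_hz <= 0 or inter_train_gap_s < 0:
        raise ValueError("rates must be positive and gap non-negative")
    if intra_burst_rate_hz <= burst_rate_hz:
        raise ValueError("intra-burst rate must exceed the burst repetition rate")
    burst_dur = (pulses_per_burst - 1) / intra_burst_rate_hz
    burst_period = 1.0 / burst_rate_hz
    if bursts_per_train > 1 and burst_dur >= burst_period:
        raise ValueError("burst duration exceeds the burst period")
    times = []
    bounds = []
    t0 = 0.0
    for _ in range(n_trains):
        for b in range(bursts_per_train):
            onset = t0 + b * burst_period
            for p in range(pulses_per_burst):
                times.append(onset + p / intra_burst_rate_hz)
        span = (bursts_per_train - 1) * burst_period + burst_dur
        bounds.append((t0, t0 + span))
        t0 = t0 + span + inter_train_gap_s
    return PulseTrainSchedule(
        pulse_times_s=np.asarray(times),
        train_bounds=bounds,
        params={
            "n_trains": n_trains,
            "bursts_per_train": bursts_per_train,
            "pulses_per_burst": pulses_per_burst,
            "intra_burst_rate_hz": intra_burst_rate_hz,
            "burst_rate_hz": burst_rate_hz,
            "inter_train_gap_s": inter_train_gap_s,
        },
    )


def build_shock_pulse_train(
    duration_ms: float = 100.0,
    rate_hz: float = 200.0,
    pulse_width_ms: float = 2.0,
) -> PulseTrainSchedule:
    """Shock stimulus: square pulses at ``rate_hz`` filling ``duration_ms``
    (default: a 100-ms train of 2-ms pulses at 200 Hz, i.e. 20 pulses)."""
    if duration_ms <= 0 or rate_hz <= 0 or pulse_width_ms <= 0:
        raise ValueError("duration, rate and width must be positive")
    period_ms = 1000.0 / rate_hz
    if pulse_width_ms >= period_ms:
        raise ValueError("pulse width must be shorter than the pulse period")
    times = []
    k = 0
    while True:
        t = k * period_ms
        if t >= duration_ms or t + pulse_width_ms > duration_ms:
            break
        times.append(t / 1000.0)
        k += 1
    return PulseTrainSchedule(
        pulse_times_s=np.asarray(times),
        train_bounds=[(0.0, duration_ms / 1000.0)],
        params={
            "duration_ms": duration_ms,
            "rate_hz": rate_hz,
            "pulse_width_ms": pulse_width_ms,
        },
    )


_TABLE_COLUMNS = [
    "subject_id", "session", "run", "block_index", "block_type", "trial_index",
    "phase", "event_type", "onset_s", "duration_s", "condition_label",
]


def schedule_to_table(
    schedule: NpuSchedule | HabituationSchedule | SternbergSchedule | PulseTrainSchedule,
    subject_id: str = "sub-00",
    session: str = "unspecified",
) -> pd.DataFrame:
    """Serialize any schedule to the long-format event table (one row per
    probe, shock or pulse) used by the signal pipeline."""
    rows: list[dict] = []

    def row(**kw) -> None:
        base = dict.fromkeys(_TABLE_COLUMNS)
        base.update(subject_id=subject_id, session=session)
        base.update(kw)
        rows.append(base)

    if isinstance(schedule, NpuSchedule):
        for run in schedule.runs:
            for t in run.trials:
                row(run=run.run_index, block_index=t.block_index,
                    block_type=t.block_type, trial_index=t.trial_index,
                    phase=t.phase, event_type="probe", onset_s=t.probe_time_s,
                    duration_s=PROBE_DURATION_S, condition_label=t.condition_label)
                if t.shock_time_s is not None:
                    row(run=run.run_index, block_index=t.block_index,
                        block_type=t.block_type, trial_index=t.trial_index,
                        phase=t.phase, event_type="shock", onset_s=t.shock_time_s,
                        duration_s=0.1, condition_label=t.condition_label)
    elif isinstance(schedule, HabituationSchedule):
        for i, t in enumerate(schedule.probe_times_s):
            row(run=0, block_index=0, block_type="H", trial_index=i, phase="iti",
                event_type="probe", onset_s=t, duration_s=PROBE_DURATION_S,
                condition_label="habituation")
    elif isinstance(schedule, SternbergSchedule):
        clock = RUN_START_OFFSET_S
        prev_run = 0
        for t in schedule.trials:
            if t.run_index != prev_run:
                clock = RUN_START_OFFSET_S
                prev_run = t.run_index
            row(run=t.run_index, block_index=t.block_index, block_type=t.block_condition,
                trial_index=t.trial_index, phase=t.trial_type, event_type="probe",
                onset_s=clock, duration_s=t.duration_s,
                condition_label=("shock_trial" if t.is_shock_trial
                                 else f"{t.trial_type}_{t.block_condition}"))
            clock += t.duration_s
    elif isinstance(schedule, PulseTrainSchedule):
        for i, t in enumerate(schedule.pulse_times_s):
            row(run=0, block_index=0, block_type="pulse", trial_index=i, phase="pulse",
                event_type="pulse", onset_s=float(t),
                duration_s=schedule.params.get("pulse_width_ms", 0.0) / 1000.0,
                condition_label="pulse")
    else:
        raise TypeError(f"unsupported schedule type {type(schedule).__name__}")
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return df.sort_values(["run", "onset_s"], kind="stable").reset_index(drop=True)
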