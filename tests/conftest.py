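import numpy as np
import pandas as pd
import pytest

from startlelab.schedules import build_npu_schedule, place_shocks
from startlelab.scoring import score_recording, scores_to_frame
from startlelab.synth import BlinkSimParams, simulate_session

#: condition multipliers with distinct potentiation per condition, used by
#: the recovery fixtures
POTENTIATION_MULTIPLIERS = {
    "N_iti": 1.0,
    "N_cue": 1.0,
    "P_iti": 1.1,
    "P_cue": 1.6,
    "U_cue": 1.35,
    "U_iti": 1.3,
}


def scored_session(seed: int, **param_overrides):
    """Simulate one two-run NPU session and score it (no normalization).

    Returns (per-trial score frame merged with ground truth, recordings).
    """
    defaults = dict(
        baseline_noise_sd_uv=0.01,
        condition_multipliers=dict(POTENTIATION_MULTIPLIERS),
        rng_seed=seed,
    )
    defaults.update(param_overrides)
    params = BlinkSimParams(**defaults)
    schedule = place_shocks(build_npu_schedule(rng_seed=seed), rng_seed=seed + 1)
    recordings = simulate_session(schedule, params, "sub-00", "pretest")
    scores = []
    for rec in recordings:
        scores.extend(score_recording(rec, normalize=False))
    truth = pd.concat([r.ground_truth for r in recordings], ignore_index=True)
    merged = scores_to_frame(scores).merge(
        truth, on=["subject_id", "session", "run", "trial_index", "condition_label"]
    )
    assert len(merged) == len(scores)
    return merged, recordings


@pytest.fixture(scope="session")
def noise_free_scored_session():
    """One noise-controlled session: near-zero baseline noise, no
    artifacts, no missing blinks."""
    return scored_session(seed=101)


@pytest.fixture(scope="session")
def noisy_scored_session():
    """A session with realistic baseline noise plus injected artifacts and
    no-blink trials."""
    return scored_session(
        seed=202,
        baseline_noise_sd_uv=2.0,
        artifact_prob=0.02,
        no_blink_prob=0.08,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
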