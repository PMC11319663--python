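"""End-to-end pipeline: simulate -> score -> aggregate -> ANOVA.

Stages run in a fixed order, every intermediate table is written to the
output directory, and a manifest records the configuration hash, the seed
and per-stage row counts, so that identical configuration + seed yields an
identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as slio
from .outcomes import condition_means, difference_scores, truncate_groups
from .scoring import MISSING_NOISY, ZERO_NO_BLINK, ScoringConfig, scores_to_frame, t_normalize, score_recording
from .stats import rm_anova_2x2
from .synth import BlinkSimParams, StudyEffectSpec, simulate_study

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "anova_on_outcomes"]


@dataclass
class PipelineConfig:
    """Validated configuration of a full synthetic-study run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_subjects: int = 4
    coil_effect_d: float = 0.43
    truncate_k: float = 2.0
    group_by: str = "session"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    blink: BlinkSimParams = field(default_factory=BlinkSimParams)
    log_level: str = "INFO"
    #: also write the raw per-run signal CSVs (large; off by default --
    #: the scored tables carry the analysis)
    write_signals: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.truncate_k <= 0:
            raise ValueError("truncate_k must be positive")
        if self.group_by not in ("session", "run"):
            raise ValueError("group_by must be 'session' or 'run'")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        logging excluded, so relocated reruns stay comparable)."""
        d = asdict(self)
        d.pop("out_dir")
        d.pop("log_level")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def anova_on_outcomes(outcome_table: pd.DataFrame, measure: str):
    """Run the 2 (coil: active vs sham) x 2 (response type: FPS vs APS_ITI)
    within-subject ANOVA on a difference-score table."""
    sub = outcome_table[outcome_table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    long = sub.melt(
        id_vars=["subject_id", "session"],
        value_vars=["FPS", "APS_ITI"],
        var_name="response_type",
        value_name="score",
    )
    return rm_anova_2x2(long, dv="score", subject="subject_id",
                        within=("session", "response_type"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic-study pipeline and write all artifacts.

    Returns a bundle with the trial-score table, the outcome table, the
    per-measure ANOVA results and the manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = slio.ensure_dir(config.out_dir)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # -- stage 1: simulate -------------------------------------------------
    spec = StudyEffectSpec(
        n_subjects=config.n_subjects,
        coil_effect_d=config.coil_effect_d,
        rng_seed=slio.derive_seed(config.seed, "simulate"),
    )
    try:
        recordings, ratings = simulate_study(
            spec, config.blink, rng=slio.derive_rng(config.seed, "simulate")
        )
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    truth_frames = []
    for rec in recordings:
        if config.write_signals:
            sig_dir = slio.ensure_dir(out / "signals")
            stem = f"{rec.subject_id}_{rec.session_label}_run{rec.run}"
            t = np.arange(rec.samples.size) / rec.sampling_rate_hz
            slio.write_signal(sig_dir / f"{stem}_signal.csv", t, rec.samples)
        truth_frames.append(rec.ground_truth)
    truth = pd.concat(truth_frames, ignore_index=True)
    slio.write_table(truth, out / "ground_truth.csv")
    slio.write_table(ratings, out / "ratings.csv")
    manifest["stages"]["simulate"] = {
        "recordings": len(recordings),
        "rating_rows": len(ratings),
    }

    # -- stage 2: score ----------------------------------------------------
    scores = []
    by_session: dict[tuple[str, str], list] = {}
    for rec in recordings:
        try:
            run_scores = score_recording(rec, config.scoring, normalize=False)
        except Exception as e:
            raise RuntimeError(
                f"stage 'score' failed on {rec.subject_id}/{rec.session_label}"
                f"/run {rec.run}: {e}"
            ) from e
        by_session.setdefault((rec.subject_id, rec.session_label), []).extend(run_scores)
    for (sid, sess), trial_scores in sorted(by_session.items()):
        normed = t_normalize(trial_scores, group_by=config.group_by)
        n_missing = sum(t.status == MISSING_NOISY for t in normed)
        n_zero = sum(t.status == ZERO_NO_BLINK for t in normed)
        log.info("scored %s/%s: %d trials, %d missing, %d zero-coded",
                 sid, sess, len(normed), n_missing, n_zero)
        scores.extend(normed)
    score_frame = scores_to_frame(scores)
    slio.write_table(score_frame, out / "trial_scores.csv")
    manifest["stages"]["score"] = {
        "trials": len(score_frame),
        "missing": int((score_frame["status"] == MISSING_NOISY).sum()),
        "zero_coded": int((score_frame["status"] == ZERO_NO_BLINK).sum()),
    }

    # -- stage 3: aggregate ------------------------------------------------
    startle = condition_means(
        score_frame.rename(columns={"t": "value"}), "value", "startle_t"
    )
    rate_means = condition_means(
        ratings.rename(columns={"rating": "value"}), "value", "rating"
    )
    outcome = pd.concat(
        [difference_scores(startle), difference_scores(rate_means)],
        ignore_index=True,
    )
    outcome = truncate_groups(outcome, ["FPS", "APS_ITI"], k=config.truncate_k)
    slio.write_table(outcome, out / "outcomes.csv")
    manifest["stages"]["aggregate"] = {"rows": len(outcome)}

    # -- stage 4: ANOVA ----------------------------------------------------
    anovas = {}
    frames = []
    for measure in ("startle_t", "rating"):
        try:
            res = anova_on_outcomes(outcome, measure)
        except Exception as e:
            raise RuntimeError(f"stage 'anova' failed for measure {measure!r}: {e}") from e
        anovas[measure] = res
        f = res.to_frame()
        f.insert(0, "measure", measure)
        frames.append(f)
    anova_frame = pd.concat(frames, ignore_index=True)
    slio.write_table(anova_frame, out / "anova.csv")
    manifest["stages"]["anova"] = {"terms": len(anova_frame)}

    manifest_path = Path(out) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "trial_scores": score_frame,
        "outcomes": outcome,
        "anova": anovas,
        "anova_table": anova_frame,
        "manifest": manifest,
    }
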