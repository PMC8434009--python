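"""End-to-end simulated experiment: train, decode, QC, analyze.

Mirrors the study protocol: a training session of several selections at 30
blinks per button builds the LDA, then 15 online selections per environment
at 20 blinks per button are decoded by summed discriminant score. The two
"environments" differ only in their independent noise seeds — the simulator
has no rendering — which is exactly the null hypothesis the statistics
should not reject. All seeds derive from one master seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .classify import decide_selection, evaluate_accuracy, score_epochs, train_lda
from .erp_stats import average_target_erp, find_p300_peak
from .io import RunConfig
from .paradigm import generate_flash_schedule, inject_artifacts, synthesize_recording
from .preprocess import EpochSet, run_pipeline, single_trial_epochs
from .qc import qc_report

__all__ = ["simulate_selection", "train_from_simulation", "run_experiment"]

logger = logging.getLogger(__name__)

ENVIRONMENTS = ("VR", "AR")


def _seed_from(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1, dtype=np.uint32)[0])


def simulate_selection(
    config: RunConfig,
    *,
    target: int,
    n_blinks: int,
    seed: int,
    selection_id: int = 0,
    environment: str = "NA",
):
    """One selection's schedule + recording (artifacts included if enabled)."""
    schedule = generate_flash_schedule(
        config.paradigm,
        n_blinks,
        target,
        seed,
        selection_id=selection_id,
        environment=environment,
    )
    noise = dataclasses.replace(config.noise, seed=seed + 1)
    recording = synthesize_recording(schedule, config.template, noise, config.paradigm)
    if noise.artifact_rate_per_min > 0:
        recording = inject_artifacts(recording, noise)
    return recording


def train_from_simulation(config: RunConfig, seed_seq: np.random.SeedSequence):
    """Simulate the training session and fit the classifier.

    Each training selection uses 30 blinks per button; the pipeline's
    configured averaging mode (sliding by default) sets how many averaged
    exemplars each selection yields.
    """
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    parts: list[EpochSet] = []
    for sel in range(config.n_training_selections):
        target = int(rng.integers(config.paradigm.n_buttons))
        rec = simulate_selection(
            config,
            target=target,
            n_blinks=config.paradigm.blinks_training,
            seed=_seed_from(seed_seq.spawn(1)[0]),
            selection_id=sel,
        )
        parts.append(run_pipeline(rec, config.pipeline))
    features = EpochSet.concatenate(parts)
    return train_lda(features)


def measure_simulated_peak(config: RunConfig, seed: int):
    """Simulate one subject's online session in one environment (15
    selections x 20 blinks -> 300 target epochs) and measure the P300 peak
    from the grand-average waveform with zero-phase analysis filtering.

    Returns the PeakMeasure; used for parameter-recovery studies.
    """
    erp_cfg = dataclasses.replace(config.pipeline, causal_filtering=False)
    seq = np.random.SeedSequence(seed)
    target_rng = np.random.default_rng(seq.spawn(1)[0])
    parts: list[EpochSet] = []
    for sel in range(config.paradigm.selections_per_env):
        target = int(target_rng.integers(config.paradigm.n_buttons))
        rec = simulate_selection(
            config,
            target=target,
            n_blinks=config.paradigm.blinks_online,
            seed=_seed_from(seq.spawn(1)[0]),
            selection_id=sel,
        )
        parts.append(single_trial_epochs(rec, erp_cfg))
    erp = average_target_erp(EpochSet.concatenate(parts))
    return find_p300_peak(erp, config.erp.peak_window_ms, config.erp.channel_policy)


def run_experiment(config: RunConfig, out_dir=None) -> dict:
    """Full protocol for one simulated subject; returns the summary dict.

    Online decoding averages each button's full block of 20 blinks into one
    feature epoch (block mode); training uses the configured mode. QC runs
    on the un-averaged, un-decimated epochs; the ERP peak analysis on the
    grand average of single-blink target epochs at 100 Hz.
    """
    master = np.random.SeedSequence(config.seed)
    model = train_from_simulation(config, master.spawn(1)[0])

    online_cfg = dataclasses.replace(
        config.pipeline, avg_mode="block", avg_window=config.paradigm.blinks_online
    )
    # Waveform analysis is an offline study: zero-phase filtering avoids the
    # causal filter's group delay, which would bias peak latency.
    erp_cfg = dataclasses.replace(config.pipeline, causal_filtering=False)
    target_rng = np.random.default_rng(master.spawn(1)[0])
    summary: dict = {"config_hash": config.config_hash(), "environments": {}}
    qc_inputs: list[EpochSet] = []
    erp_inputs: dict[str, list[EpochSet]] = {env: [] for env in ENVIRONMENTS}

    for env in ENVIRONMENTS:
        env_seq = master.spawn(1)[0]
        results = []
        for sel in range(config.paradigm.selections_per_env):
            target = int(target_rng.integers(config.paradigm.n_buttons))
            rec = simulate_selection(
                config,
                target=target,
                n_blinks=config.paradigm.blinks_online,
                seed=_seed_from(env_seq.spawn(1)[0]),
                selection_id=sel,
                environment=env,
            )
            feats = run_pipeline(rec, online_cfg)
            scores = score_epochs(model, feats)
            results.append(
                decide_selection(
                    scores,
                    feats.button,
                    n_buttons=config.paradigm.n_buttons,
                    true_button=target,
                    selection_id=sel,
                    environment=env,
                )
            )
            qc_inputs.append(single_trial_epochs(rec, config.pipeline, resample=False))
            erp_inputs[env].append(single_trial_epochs(rec, erp_cfg))
        accuracy = evaluate_accuracy(results)
        summary["environments"][env] = {
            "accuracy_pct": accuracy,
            "n_selections": len(results),
            "selections": [
                {
                    "selection_id": r.selection_id,
                    "true": r.true_button,
                    "predicted": r.predicted_button,
                    "correct": bool(r.correct),
                }
                for r in results
            ],
        }
        logger.info("%s: decoded %s%% of selections", env, accuracy)

    # ERP peak analysis per environment on single-blink target epochs.
    for env in ENVIRONMENTS:
        erp = average_target_erp(
            EpochSet.concatenate(erp_inputs[env]), environment=env
        )
        peak = find_p300_peak(
            erp, config.erp.peak_window_ms, config.erp.channel_policy
        )
        summary["environments"][env]["p300_peak"] = {
            "latency_ms": peak.latency_ms,
            "amplitude_uv": peak.amplitude_uv,
            "n_epochs_averaged": erp.n_epochs_averaged,
        }

    report = qc_report(EpochSet.concatenate(qc_inputs), config.qc)
    summary["qc"] = report.to_dict()
    summary["mean_accuracy_pct"] = round(
        float(
            np.mean(
                [summary["environments"][e]["accuracy_pct"] for e in ENVIRONMENTS]
            )
        ),
        2,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        config.to_yaml(out_dir / "resolved_config.yaml")
    return summary
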