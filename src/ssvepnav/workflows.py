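"""End-to-end experiment workflows: train a decoder on simulated training
blocks, play the closed-loop game with it, and aggregate subject reports.

These are the library functions behind the CLI verbs; every report carries a
provenance block (config hash, seed, package version) and identical
(config, seed) pairs produce byte-identical reports.
"""

from __future__ import annotations

import json
from functools import partial
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .decoder import SsvepDecoder, crossval_accuracy, train_decoder
from .epochs import EpochSet
from .evaluation import itr_bits_per_min, online_accuracy_lower_bound
from .game import EEGAgent, RoundLog, SessionTiming, logs_to_frame, run_closed_loop
from .preprocess import preprocess_online, preprocess_training
from .simulate import Simulator

__all__ = ["train_subject", "play_session", "aggregate_reports", "run_experiment"]


def _provenance(cfg: ExperimentConfig, seed: int) -> dict:
    return {"config_hash": cfg.hash(), "seed": int(seed), "version": __version__}


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def generate_training_data(
    cfg: ExperimentConfig, seed: int, simulator: Simulator | None = None
) -> EpochSet:
    """The training session: ``n_blocks`` blocks of ``n_sequences`` sequences,
    concatenated (each sequence presents all four targets once)."""
    sim = simulator or Simulator(cfg.sim)
    children = np.random.SeedSequence(seed).spawn(cfg.training.n_blocks)
    blocks = [
        sim.generate_session(cfg.training.n_sequences, child) for child in children
    ]
    out = blocks[0]
    for b in blocks[1:]:
        out = out.concat(b)
    return out


def train_subject(
    cfg: ExperimentConfig,
    seed: int,
    out_dir: str | Path | None = None,
    simulator: Simulator | None = None,
) -> tuple[SsvepDecoder, dict]:
    """Simulate the training session, preprocess, cross-validate, train the
    final decoder on all clean trials, and write model + offline report."""
    sim = simulator or Simulator(cfg.sim)
    raw = generate_training_data(cfg, seed, sim)
    clean, rejected = preprocess_training(raw, cfg.preprocess)
    cv = crossval_accuracy(
        clean,
        k_folds=cfg.training.k_folds,
        seed=seed,
        feature_mode=cfg.decoder.feature_mode,
        gamma=cfg.decoder.gamma,
    )
    dec = train_decoder(
        clean,
        f_stim=cfg.sim.f_stim,
        n_harmonics=cfg.sim.n_harmonics,
        feature_mode=cfg.decoder.feature_mode,
        gamma=cfg.decoder.gamma,
    )
    report = {
        "n_trials": int(raw.n_trials),
        "n_rejected": int(len(rejected)),
        "n_clean_trials": int(clean.n_trials),
        "effective_trial_dur_s": clean.duration,
        "cv_accuracy": float(cv),
        "offline_itr_bits_per_min": itr_bits_per_min(cv, 4, clean.duration),
        "provenance": _provenance(cfg, seed),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["model_path"] = str(dec.save(out / "model"))
        _json_dump(report, out / "train_report.json")
    return dec, report


def play_session(
    cfg: ExperimentConfig,
    decoder: SsvepDecoder,
    seed: int,
    out_dir: str | Path | None = None,
    simulator: Simulator | None = None,
) -> tuple[list[RoundLog], dict]:
    """Run the closed-loop online session and compute the online report.

    The simulator must be the same simulated subject the decoder was trained
    on (same ``sim.seed``); its online-session topographies include the
    configured drift.
    """
    sim = simulator or Simulator(cfg.sim)
    agent = EEGAgent(
        simulator=sim,
        decoder=decoder,
        preprocess=partial(preprocess_online, params=cfg.preprocess),
    )
    logs = run_closed_loop(
        agent, n_rounds=cfg.game.n_rounds, seed=seed, step_limit=cfg.game.step_limit
    )
    p_hat = online_accuracy_lower_bound(logs)
    won = [lg for lg in logs if lg.won]
    total_steps = sum(lg.steps_used for lg in logs)
    timing = SessionTiming(stimulation=cfg.sim.epoch_dur)
    effective_dur = cfg.sim.epoch_dur - cfg.preprocess.discard
    report = {
        "n_rounds": len(logs),
        "wins": len(won),
        "mean_steps_to_win": float(np.mean([lg.steps_used for lg in won]))
        if won
        else None,
        "total_steps": int(total_steps),
        "online_accuracy_lower_bound": float(p_hat),
        "online_itr_bits_per_min": itr_bits_per_min(p_hat, 4, effective_dur),
        "session_minutes": timing.session_minutes(total_steps, len(logs)),
        "per_round": [
            {
                "round_index": lg.round_index,
                "won": bool(lg.won),
                "steps": lg.steps_used,
                "p_hat": lg.fraction_distance_reducing,
            }
            for lg in logs
        ],
        "provenance": _provenance(cfg, seed),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        logs_to_frame(logs).to_csv(out / "trajectory.csv", index=False)
        _json_dump(report, out / "play_report.json")
    return logs, report


def run_experiment(
    cfg: ExperimentConfig, seed: int, out_dir: str | Path | None = None
) -> dict:
    """One simulated subject end to end: train, then play. The training and
    online sessions use distinct noise streams but the same subject."""
    train_seed, play_seed = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(2)
    ]
    sim = Simulator(cfg.sim)
    dec, train_report = train_subject(cfg, train_seed, out_dir, sim)
    logs, play_report = play_session(cfg, dec, play_seed, out_dir, sim)
    report = {"train": train_report, "play": play_report}
    if out_dir is not None:
        _json_dump(report, Path(out_dir) / "subject_report.json")
    return report


def aggregate_reports(reports: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-subject reports into accuracy/ITR and game-outcome tables
    (one row per subject plus mean and standard-deviation rows)."""
    if not reports:
        raise ValueError("no subject reports to aggregate")
    t1_rows, t2_rows = [], []
    for i, rep in enumerate(reports, start=1):
        tr, pl = rep["train"], rep["play"]
        t1_rows.append(
            {
                "subject": str(i),
                "offline_accuracy_pct": 100 * tr["cv_accuracy"],
                "offline_itr_bits_per_min": tr["offline_itr_bits_per_min"],
                "online_accuracy_pct": 100 * pl["online_accuracy_lower_bound"],
                "online_itr_bits_per_min": pl["online_itr_bits_per_min"],
            }
        )
        t2_rows.append(
            {
                "subject": str(i),
                "games_won": pl["wins"],
                "mean_steps_to_win": pl["mean_steps_to_win"],
                "session_minutes": pl["session_minutes"],
            }
        )

    def with_summary(rows: list[dict]) -> pd.DataFrame:
        df = pd.DataFrame(rows)
        num = df.drop(columns="subject")
        mean = {"subject": "mean", **num.mean().to_dict()}
        std = {"subject": "standard deviation", **num.std(ddof=1).to_dict()}
        return pd.concat([df, pd.DataFrame([mean, std])], ignore_index=True)

    return with_summary(t1_rows), with_summary(t2_rows)
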