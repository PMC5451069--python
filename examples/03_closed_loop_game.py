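"""Play the closed-loop 2-D navigation game with a trained decoder.

Each round the goal starts 6 steps away in x and 6 in y (12 steps minimum).
Per step the greedy policy picks the intended gaze direction, the simulator
produces a fresh online-session EEG epoch for it, the decoder predicts, and
the *predicted* command shifts the landscape — wrong decodes move the goal
the wrong way. A round not won within 25 steps is lost. The fraction of
steps that reduced the Euclidean distance to the goal estimates the online
classification accuracy.
"""

from ssvepnav import (
    ExperimentConfig,
    SimConfig,
    play_session,
    train_subject,
)
from ssvepnav.config import GameParams, PreprocessParams, TrainingParams
from ssvepnav.simulate import Simulator

cfg = ExperimentConfig(
    sim=SimConfig(fs=512.0, epoch_dur=2.0, snr_db=10.0, seed=1),
    preprocess=PreprocessParams(fs_out=256.0, online_downsample=True),
    training=TrainingParams(n_blocks=2, n_sequences=10, k_folds=5),
    game=GameParams(n_rounds=16),
)

sim = Simulator(cfg.sim)  # one simulated subject for both sessions
decoder, train_report = train_subject(cfg, seed=7, simulator=sim)
logs, report = play_session(cfg, decoder, seed=8, simulator=sim)

print(f"offline cross-validated accuracy: {train_report['cv_accuracy']:.3f}")
print(f"rounds won:                 {report['wins']} / {report['n_rounds']}")
print(f"mean steps to win:          {report['mean_steps_to_win']:.1f} (minimum 12)")
print(f"online accuracy (lower bd): {report['online_accuracy_lower_bound']:.3f}")
print(f"online ITR:                 {report['online_itr_bits_per_min']:.1f} bits/min")
print(f"session time:               {report['session_minutes']:.1f} min "
      "(epochs + 2 s shift animations + blanks)")
print()
print("per round: W=won L=lost, steps used")
print("  " + "  ".join(
    f"{'W' if r['won'] else 'L'}{r['steps']}" for r in report["per_round"]))
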