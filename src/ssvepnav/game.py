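"""The 2-D landscape-shifting navigation game and closed-loop harness.

A goal icon starts in one of the four corners of the game map, always 6
steps away from the screen centre in x and 6 in y (12 steps minimum). Each
decoded command (N/E/W/S) shifts the whole landscape one step in that
direction, carrying the goal one step toward the centre when the command
points the right way. Reaching the centre wins the round; a round not won
within 25 steps is lost.

Coordinates: ``goal_offset = goal - screen centre`` in screen coordinates
(x positive toward E, y positive toward S). The command named after a
direction moves the landscape that way: N decrements dy, S increments dy,
E decrements dx, W increments dx. Overshooting past the centre is allowed
(the grid is symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .epochs import CLASSES

__all__ = [
    "DIRECTIONS",
    "GameState",
    "StepRecord",
    "RoundLog",
    "new_round",
    "apply_command",
    "greedy_policy",
    "run_closed_loop",
    "oracle_agent",
    "ConfusionAgent",
    "EEGAgent",
    "SessionTiming",
]

DIRECTIONS = CLASSES  # ("N", "E", "W", "S")
_MOVES = {"N": (0, -1), "S": (0, 1), "E": (-1, 0), "W": (1, 0)}

#: Durations (seconds) used only for session-time accounting, never waited on:
#: stimulation epoch per step, landscape shift animation, inter-step blank.
@dataclass(frozen=True)
class SessionTiming:
    stimulation: float = 4.0
    animation: float = 2.0
    blank: float = 1.5

    def session_minutes(self, total_steps: int, n_rounds: int) -> float:
        per_step = self.stimulation + self.animation
        return (total_steps * per_step + n_rounds * self.blank) / 60.0


class GameError(RuntimeError):
    pass


@dataclass(frozen=True)
class GameState:
    goal_offset: tuple[int, int]
    steps_taken: int = 0
    step_limit: int = 25
    status: str = "running"  # running | won | lost

    @property
    def euclidean_distance(self) -> float:
        return float(np.hypot(*self.goal_offset))

    @property
    def manhattan_distance(self) -> int:
        return abs(self.goal_offset[0]) + abs(self.goal_offset[1])


def new_round(seed_or_rng: int | np.random.Generator, step_limit: int = 25) -> GameState:
    """Fresh round with the goal in a uniformly random corner (+/-6, +/-6)."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    corner = (int(rng.choice([-6, 6])), int(rng.choice([-6, 6])))
    return GameState(goal_offset=corner, step_limit=step_limit)


def apply_command(g: GameState, direction: str) -> GameState:
    """Shift the landscape one step; updates step count and win/lose status."""
    if g.status != "running":
        raise GameError(f"round already finished ({g.status})")
    if direction not in _MOVES:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    dx, dy = _MOVES[direction]
    offset = (g.goal_offset[0] + dx, g.goal_offset[1] + dy)
    steps = g.steps_taken + 1
    if offset == (0, 0):
        status = "won"
    elif steps >= g.step_limit:
        status = "lost"
    else:
        status = "running"
    return replace(g, goal_offset=offset, steps_taken=steps, status=status)


def greedy_policy(g: GameState) -> str:
    """A direction that strictly reduces Euclidean distance whenever one
    exists; when |dx| = |dy| > 0, reduce x first (deterministic tie rule)."""
    dx, dy = g.goal_offset
    if dx == 0 and dy == 0:
        raise GameError("goal already at centre")
    if dx != 0 and (abs(dx) >= abs(dy)):
        return "E" if dx > 0 else "W"
    return "N" if dy > 0 else "S"


@dataclass(frozen=True)
class StepRecord:
    intended: str
    decoded: str
    offset_before: tuple[int, int]
    offset_after: tuple[int, int]
    dist_before: float
    dist_after: float


@dataclass
class RoundLog:
    round_index: int
    steps: list[StepRecord] = field(default_factory=list)
    won: bool = False

    @property
    def steps_used(self) -> int:
        return len(self.steps)

    @property
    def fraction_distance_reducing(self) -> float:
        if not self.steps:
            raise ValueError("empty round log")
        return float(
            np.mean([s.dist_after < s.dist_before for s in self.steps])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round_index": self.round_index,
                "step": np.arange(self.steps_used),
                "intended": [s.intended for s in self.steps],
                "decoded": [s.decoded for s in self.steps],
                "dx_before": [s.offset_before[0] for s in self.steps],
                "dy_before": [s.offset_before[1] for s in self.steps],
                "dx_after": [s.offset_after[0] for s in self.steps],
                "dy_after": [s.offset_after[1] for s in self.steps],
                "dist_before": [s.dist_before for s in self.steps],
                "dist_after": [s.dist_after for s in self.steps],
            }
        )


def logs_to_frame(logs: Sequence[RoundLog]) -> pd.DataFrame:
    """One row per step across rounds (the trajectory CSV layout)."""
    return pd.concat([lg.to_frame() for lg in logs], ignore_index=True)


# Agents: callable(intended_direction, rng) -> decoded direction -------------

def oracle_agent(intended: str, rng: np.random.Generator) -> str:
    """Perfect decoder: always returns the intended direction."""
    return intended


@dataclass(frozen=True)
class ConfusionAgent:
    """Symmetric-confusion decoder: correct with probability p, otherwise a
    uniformly random other direction. Bypasses EEG simulation for fast
    Monte Carlo runs."""

    p: float

    def __call__(self, intended: str, rng: np.random.Generator) -> str:
        if rng.random() < self.p:
            return intended
        others = [d for d in DIRECTIONS if d != intended]
        return str(others[rng.integers(len(others))])


@dataclass
class EEGAgent:
    """Full closed loop: intended gaze -> simulated online-session epoch ->
    online preprocessing -> decoder prediction."""

    simulator: "object"  # ssvepnav.simulate.Simulator
    decoder: "object"  # ssvepnav.decoder.SsvepDecoder
    preprocess: Callable  # EpochSet -> EpochSet (online path)

    def __call__(self, intended: str, rng: np.random.Generator) -> str:
        from .epochs import EpochSet

        epoch = self.simulator.generate_epoch(intended, rng, session="online")
        e = EpochSet(
            data=epoch[None, :, :],
            fs=self.simulator.cfg.fs,
            labels=np.array([intended], dtype=object),
            montage=self.simulator.montage,
        )
        return self.decoder.predict(self.preprocess(e).data[0])


def run_closed_loop(
    agent: Callable[[str, np.random.Generator], str],
    n_rounds: int = 16,
    seed: int = 0,
    step_limit: int = 25,
    policy: Callable[[GameState], str] = greedy_policy,
) -> list[RoundLog]:
    """Play ``n_rounds`` rounds: the policy chooses the intended direction,
    the agent decodes it (possibly wrongly), and the *decoded* command moves
    the landscape. Seeds are spawned per round, so adding rounds never
    perturbs earlier ones."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    logs = []
    for ri, child in enumerate(np.random.SeedSequence(seed).spawn(n_rounds)):
        rng = np.random.default_rng(child)
        g = new_round(rng, step_limit=step_limit)
        log = RoundLog(round_index=ri)
        while g.status == "running":
            intended = policy(g)
            decoded = agent(intended, rng)
            g2 = apply_command(g, decoded)
            log.steps.append(
                StepRecord(
                    intended=intended,
                    decoded=decoded,
                    offset_before=g.goal_offset,
                    offset_after=g2.goal_offset,
                    dist_before=g.euclidean_distance,
                    dist_after=g2.euclidean_distance,
                )
            )
            g = g2
        log.won = g.status == "won"
        logs.append(log)
    return logs
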