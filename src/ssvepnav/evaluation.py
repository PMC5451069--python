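"""Performance metrics: ITR, the online accuracy lower bound, topographies.

The information transfer rate of a C-way selection system with accuracy P
and selection time T seconds follows Wolpaw's formula,

    ITR = 60/T * ( log2 C + P log2 P + (1-P) log2( (1-P)/(C-1) ) )  [bits/min]

with the 0*log0 = 0 limits at P = 0 and P = 1. During online play the true
intention is unknown; assuming the player always intends the optimal move,
the fraction of steps that reduced the Euclidean distance to the goal is a
lower bound on the step classification accuracy, counted identically for won
and lost rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochSet
from .game import RoundLog
from .montage import Montage

__all__ = [
    "itr_bits_per_min",
    "online_accuracy_lower_bound",
    "TopographyMap",
    "power_topography",
    "phase_amplitude",
    "topography_similarity",
    "performance_over_time",
]


def itr_bits_per_min(p: float, n_classes: int = 4, trial_dur: float = 3.5) -> float:
    """Wolpaw ITR in bits/min for accuracy ``p``, ``n_classes`` options and
    ``trial_dur`` seconds per selection."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if trial_dur <= 0:
        raise ValueError("trial duration must be positive")

    def xlog2x(x: float) -> float:
        return 0.0 if x == 0.0 else x * np.log2(x)

    bits = np.log2(n_classes) + xlog2x(p) + xlog2x(1.0 - p) - (1.0 - p) * np.log2(
        n_classes - 1
    )
    return float(60.0 / trial_dur * bits)


def online_accuracy_lower_bound(
    logs: Sequence[RoundLog], weighted: bool = False
) -> float:
    """Fraction of steps that reduced the Euclidean distance to the goal.

    Per round the fraction is (distance-reducing steps) / (steps made); the
    default aggregate is the unweighted mean over rounds, ``weighted=True``
    pools all steps instead. Won and lost rounds count identically.
    """
    if len(logs) == 0:
        raise ValueError("no round logs")
    if weighted:
        good = sum(
            sum(s.dist_after < s.dist_before for s in lg.steps) for lg in logs
        )
        total = sum(lg.steps_used for lg in logs)
        return good / total
    return float(np.mean([lg.fraction_distance_reducing for lg in logs]))


@dataclass
class TopographyMap:
    """Per-channel scalar (e.g. 15 Hz power in uV^2) over a montage."""

    values: np.ndarray = field(repr=False)
    montage: Montage
    freq: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.montage.n_channels,):
            raise ValueError("values must have one entry per montage channel")
        self.values = v

    @property
    def peak_channel(self) -> str:
        return self.montage.channel_names[int(np.argmax(self.values))]


def _nearest_bin_coeff(data: np.ndarray, fs: float, f: float, pad_pow2: bool) -> np.ndarray:
    """Complex DFT coefficient at the bin nearest ``f``, normalised by the
    *original* sample count so a unit sinusoid gives magnitude 0.5."""
    n = data.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(n))) if pad_pow2 else n
    spec = np.fft.rfft(data, n=nfft, axis=-1) / n
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    k = int(np.argmin(np.abs(freqs - f)))
    return spec[..., k]


def power_topography(e: EpochSet, f: float = 15.0, pad_pow2: bool = True) -> TopographyMap:
    """Squared DFT amplitude at the bin nearest ``f`` per channel, averaged
    across trials. Zero-padding to the next power of two (default) reduces
    scalloping when ``f`` falls between bins of the raw epoch length."""
    coeff = _nearest_bin_coeff(e.data, e.fs, f, pad_pow2)  # (trials, channels)
    return TopographyMap(values=(np.abs(coeff) ** 2).mean(axis=0), montage=e.montage, freq=f)


def phase_amplitude(
    e: EpochSet, channel: str | int, f: float = 15.0, pad_pow2: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (amplitude, phase) of the component nearest ``f`` at one
    channel. Amplitude is the sinusoid amplitude estimate (2|X_k|/n scaling);
    phase uses the cosine-reference convention (cos(2 pi f t) -> 0,
    sin -> -pi/2), in (-pi, pi]."""
    ci = e.montage.index(channel) if isinstance(channel, str) else int(channel)
    coeff = _nearest_bin_coeff(e.data[:, ci, :], e.fs, f, pad_pow2)
    return 2.0 * np.abs(coeff), np.angle(coeff)


def topography_similarity(a: TopographyMap, b: TopographyMap) -> float:
    """Pearson correlation between two maps, channel-wise by montage order."""
    if a.montage.channel_names != b.montage.channel_names:
        raise ValueError("maps are defined on different montages")
    return float(stats.pearsonr(a.values, b.values).statistic)


def performance_over_time(
    logs_by_subject: Sequence[Sequence[RoundLog]],
    n_classes: int = 4,
    trial_dur: float = 3.5,
) -> pd.DataFrame:
    """Round-wise online performance across simulated subjects.

    For every round index: each subject's distance-reducing step fraction is
    mapped through the ITR formula, then averaged across subjects (with the
    standard error of the mean); lost games are counted per round index.
    Returns a frame with columns round_index, mean_itr, se_itr, lost_count.
    """
    if not logs_by_subject:
        raise ValueError("no subjects")
    n_rounds = {len(logs) for logs in logs_by_subject}
    if len(n_rounds) != 1:
        raise ValueError("all subjects must have the same number of rounds")
    rows = []
    for ri in range(n_rounds.pop()):
        itrs = [
            itr_bits_per_min(
                logs[ri].fraction_distance_reducing, n_classes, trial_dur
            )
            for logs in logs_by_subject
        ]
        lost = sum(not logs[ri].won for logs in logs_by_subject)
        se = float(np.std(itrs, ddof=1) / np.sqrt(len(itrs))) if len(itrs) > 1 else 0.0
        rows.append(
            {
                "round_index": ri,
                "mean_itr": float(np.mean(itrs)),
                "se_itr": se,
                "lost_count": int(lost),
            }
        )
    return pd.DataFrame(rows)
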