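"""Epoch preprocessing: bandpass, onset cropping, decimation, artifact screen.

The training path mirrors the offline pipeline: 1–80 Hz zero-phase bandpass,
discard of the first 500 ms after stimulation onset (effective 3.5 s trials),
decimation from 1024 to 512 Hz, and a fixed peak-amplitude artifact rule.
The online path applies bandpass + crop only by default (downsampling and
screening are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "PreprocessParams",
    "bandpass",
    "crop_onset",
    "downsample",
    "reject_artifacts",
    "preprocess_training",
    "preprocess_online",
]


@dataclass(frozen=True)
class PreprocessParams:
    band: tuple[float, float] = (1.0, 80.0)
    discard: float = 0.5          # seconds dropped after stimulation onset
    fs_out: float | None = 512.0  # None: keep native rate
    amp_thresh: float | None = 100.0  # microvolts; None: no screening
    online_downsample: bool = False
    online_reject: bool = False


def bandpass(e: EpochSet, lo: float = 1.0, hi: float = 80.0, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth bandpass (applied forward–backward)."""
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= e.fs / 2:
        raise ValueError(f"hi={hi} Hz must be below Nyquist ({e.fs / 2} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=e.fs, output="sos")
    return replace(e, data=signal.sosfiltfilt(sos, e.data, axis=-1))


def crop_onset(e: EpochSet, discard: float = 0.5) -> EpochSet:
    """Drop the first ``discard`` seconds; records the offset in ``t0`` so
    reference signals stay phase-locked to stimulus onset."""
    n_drop = int(round(discard * e.fs))
    if n_drop >= e.n_samples:
        raise ValueError("discard must be shorter than the epoch")
    if n_drop == 0:
        return e
    return replace(e, data=e.data[:, :, n_drop:], t0=e.t0 + n_drop / e.fs)


def downsample(e: EpochSet, fs_out: float) -> EpochSet:
    """Decimate by an integer factor (bandpass first: the 1–80 Hz band is
    already below the new Nyquist, so plain sample picking is alias-free)."""
    if fs_out == e.fs:
        return e
    factor = e.fs / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs ({e.fs}) must be an integer multiple of fs_out ({fs_out})")
    return replace(e, data=e.data[:, :, :: int(round(factor))], fs=float(fs_out))


def reject_artifacts(
    e: EpochSet, amp_thresh: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose peak absolute amplitude exceeds ``amp_thresh`` (uV)
    on any channel. Returns the kept set and the rejected trial indices."""
    peaks = np.abs(e.data).max(axis=(1, 2))
    rejected = np.flatnonzero(peaks > amp_thresh)
    if rejected.size == e.n_trials:
        raise ValueError("artifact screening rejected every trial")
    keep = np.setdiff1d(np.arange(e.n_trials), rejected)
    return e.select(keep), rejected


def preprocess_training(
    e: EpochSet, params: PreprocessParams = PreprocessParams()
) -> tuple[EpochSet, np.ndarray]:
    """Full offline pipeline: bandpass -> crop -> downsample -> artifact screen."""
    out = bandpass(e, *params.band)
    out = crop_onset(out, params.discard)
    if params.fs_out is not None:
        out = downsample(out, params.fs_out)
    if params.amp_thresh is not None:
        return reject_artifacts(out, params.amp_thresh)
    return out, np.array([], dtype=int)


def preprocess_online(
    e: EpochSet, params: PreprocessParams = PreprocessParams()
) -> EpochSet:
    """Online pipeline: bandpass + crop (downsampling/screening opt-in)."""
    out = bandpass(e, *params.band)
    out = crop_onset(out, params.discard)
    if params.online_downsample and params.fs_out is not None:
        out = downsample(out, params.fs_out)
    if params.online_reject and params.amp_thresh is not None:
        out, _ = reject_artifacts(out, params.amp_thresh)
    return out
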