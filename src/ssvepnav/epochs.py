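"""Labelled EEG epoch container and on-disk session formats.

The in-memory container is :class:`EpochSet` (trials x channels x samples,
microvolts). Sessions round-trip through MNE's native FIF epochs format plus
a plain-text labels CSV; continuous EDF/BDF recordings with an events CSV
(columns ``trial_index, class, onset_sample``) can be epoched on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import Montage, standard_montage_32

__all__ = ["CLASSES", "EpochSet", "read_raw_session", "write_events_csv"]

#: Canonical class order (also the LDA tie-break order).
CLASSES: tuple[str, ...] = ("N", "E", "W", "S")


@dataclass
class EpochSet:
    """Labelled EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of str
        Per-trial gaze-target class, each in ``CLASSES``.
    montage : Montage
        Channel names/positions; channel axis order follows it.
    t0 : float
        Time of the first sample relative to stimulus onset, in seconds
        (becomes positive after onset cropping; reference signals use it to
        stay phase-locked to the stimulus).
    """

    data: np.ndarray = field(repr=False)
    fs: float
    labels: np.ndarray
    montage: Montage = field(default_factory=standard_montage_32)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def select(self, idx) -> "EpochSet":
        """Subset of trials (keeps labels aligned)."""
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def class_trials(self, class_id: str) -> np.ndarray:
        return self.data[self.labels == class_id]

    def concat(self, other: "EpochSet") -> "EpochSet":
        if other.fs != self.fs or other.n_samples != self.n_samples:
            raise ValueError("sampling rate / length mismatch")
        if other.t0 != self.t0:
            raise ValueError("onset offset mismatch")
        return replace(
            self,
            data=np.concatenate([self.data, other.data]),
            labels=np.concatenate([self.labels, other.labels]),
        )

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> Path:
        """Write to MNE FIF epochs (``<path>-epo.fif``) + labels CSV sidecar."""
        import mne

        path = Path(path)
        fif = path.with_name(path.stem + "-epo.fif")
        info = mne.create_info(
            list(self.montage.channel_names), self.fs, ch_types="eeg", verbose="error"
        )
        event_id = {c: i + 1 for i, c in enumerate(CLASSES)}
        events = np.column_stack(
            [
                np.arange(self.n_trials) * (self.n_samples + 1),
                np.zeros(self.n_trials, dtype=int),
                [event_id[c] for c in self.labels],
            ]
        )
        ep = mne.EpochsArray(
            self.data * 1e-6,  # FIF stores volts
            info,
            events=events,
            event_id=event_id,
            tmin=self.t0,
            verbose="error",
        )
        ep.save(fif, overwrite=True, verbose="error")
        write_events_csv(fif.with_suffix(".csv"), self.labels, fs=self.fs)
        return fif

    @classmethod
    def load(cls, path: str | Path, montage: Montage | None = None) -> "EpochSet":
        import mne

        ep = mne.read_epochs(Path(path), preload=True, verbose="error")
        montage = montage or standard_montage_32()
        if list(ep.ch_names) != list(montage.channel_names):
            raise ValueError("channel names in file do not match montage")
        inv = {i + 1: c for i, c in enumerate(CLASSES)}
        labels = np.array([inv[code] for code in ep.events[:, 2]], dtype=object)
        return cls(
            data=ep.get_data(copy=True) * 1e6,
            fs=float(ep.info["sfreq"]),
            labels=labels,
            montage=montage,
            t0=float(ep.tmin),
        )


def write_events_csv(path: str | Path, labels, fs: float, epoch_samples: int | None = None) -> None:
    """Events sidecar: ``trial_index, class, onset_sample`` (one row per trial)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_index", "class", "onset_sample"])
        step = epoch_samples if epoch_samples is not None else 0
        for i, lab in enumerate(labels):
            w.writerow([i, lab, i * step])


def read_raw_session(
    raw_path: str | Path,
    events_csv: str | Path,
    epoch_dur: float,
    montage: Montage | None = None,
) -> EpochSet:
    """Epoch a continuous EDF/BDF/FIF recording with an events CSV.

    The events CSV needs columns ``trial_index, class, onset_sample``; epochs
    of ``epoch_dur`` seconds are cut from each onset sample.
    """
    import mne

    raw_path = Path(raw_path)
    suffix = raw_path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(raw_path, preload=True, verbose="error")
    elif suffix == ".bdf":
        raw = mne.io.read_raw_bdf(raw_path, preload=True, verbose="error")
    elif suffix == ".fif":
        raw = mne.io.read_raw_fif(raw_path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {suffix}")

    montage = montage or standard_montage_32()
    missing = [c for c in montage.channel_names if c not in raw.ch_names]
    if missing:
        raise ValueError(f"recording lacks montage channels: {missing}")
    raw.pick(list(montage.channel_names))

    fs = float(raw.info["sfreq"])
    n_samp = int(round(epoch_dur * fs))
    sig = raw.get_data() * 1e6

    trials, labels = [], []
    with open(events_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            onset = int(row["onset_sample"])
            if onset + n_samp > sig.shape[1]:
                raise ValueError(f"trial {row['trial_index']} runs past end of recording")
            trials.append(sig[:, onset : onset + n_samp])
            labels.append(row["class"])
    return EpochSet(
        data=np.stack(trials), fs=fs, labels=np.array(labels, dtype=object), montage=montage
    )
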