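"""Synthetic gaze-dependent SSVEP EEG.

A single 15 Hz flicker in the centre of the visual field evokes a
steady-state response whose scalp topography depends on where the subject's
gaze sits relative to the flicker: fixating the East target puts the flicker
in the left hemifield, so the response peaks over the contralateral (right)
occipital cortex; West mirrors this; shifting gaze from South to North moves
the power maximum from an occipital towards a centro-occipital position.
The simulator emulates exactly this structure — the statistical signal a
spatial-topography decoder exploits — not the underlying biophysics:

* per-class spatial gain maps built as 2-D Gaussian bumps on the schematic
  scalp, peaking at O2 (E), O1 (W), Oz (S) and midway between Oz and the
  vertex (N);
* a stimulus-locked harmonic series at ``f_stim`` whose phases are drawn
  once per simulated subject and held fixed across trials;
* 1/f (pink) background noise per channel plus a narrowband 10 Hz alpha
  process weighted toward occipital channels;
* an ``snr_db`` knob defined as the ratio of 15 Hz signal power to noise
  power in a 1 Hz band around 15 Hz at the class's peak channel, calibrated
  analytically from the noise spectral shaping;
* a ``drift`` knob in [0, 1] that perturbs the gain maps of a second
  ("online") session, emulating the between-session topography changes seen
  when training-session decoders are used in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import CLASSES, EpochSet
from .montage import Montage, standard_montage_32

__all__ = [
    "SimConfig",
    "ClassTopography",
    "Simulator",
    "make_class_topographies",
    "generate_epoch",
    "generate_session",
]

# Gaussian bump width on the unit-radius schematic scalp at sharpness 1.
_SIGMA0 = 0.45
# Channels anchoring each class's gain-map peak (N's centre is the
# Oz–Cz midpoint; Pz is the nearest channel).
_PEAK_CHANNELS = {"E": "O2", "W": "O1", "S": "Oz", "N": "Pz"}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    snr_db is the per-trial SSVEP signal-to-noise ratio at the stimulation
    frequency, measured at the class's peak channel against the noise power
    in a 1 Hz band around ``f_stim``. ``drift`` in [0, 1] controls how much
    the online-session topographies deviate from the training-session ones
    (0 = identical sessions). ``seed`` fixes the subject-level draws
    (harmonic phases, drift perturbation); trial noise uses the separate
    per-session stream.
    """

    f_stim: float = 15.0
    n_harmonics: int = 3
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.5, 0.25)
    fs: float = 1024.0
    epoch_dur: float = 4.0
    snr_db: float = 10.0
    alpha_power: float = 1.0
    noise_rms: float = 10.0  # broadband pink-noise RMS per channel, microvolts
    topography_sharpness: float = 1.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_stim <= 0:
            raise ValueError("f_stim must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if len(self.harmonic_amplitudes) != self.n_harmonics:
            raise ValueError("harmonic_amplitudes length must equal n_harmonics")
        if self.fs <= 2 * self.f_stim * self.n_harmonics:
            raise ValueError("fs must exceed twice the highest harmonic frequency")
        if self.epoch_dur <= 0:
            raise ValueError("epoch_dur must be positive")
        if not 0.0 <= self.drift <= 1.0:
            raise ValueError("drift must be in [0, 1]")
        if self.topography_sharpness <= 0:
            raise ValueError("topography_sharpness must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_dur * self.fs))


@dataclass(frozen=True)
class ClassTopography:
    """Per-channel nonnegative gains for one gaze target, unit maximum."""

    class_id: str
    gains: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if np.any(g < 0):
            raise ValueError("gains must be nonnegative")
        if not np.isclose(g.max(), 1.0):
            raise ValueError("gains must be normalised to unit maximum")
        object.__setattr__(self, "gains", g)

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.gains))


def _gaussian_map(montage: Montage, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((montage.positions - center) ** 2).sum(axis=1)
    g = np.exp(-d2 / (2.0 * sigma**2))
    return g / g.max()


def make_class_topographies(
    montage: Montage, cfg: SimConfig
) -> list[ClassTopography]:
    """Gaussian-bump gain maps for the four gaze targets.

    E peaks right-occipital (contralateral to the flicker, which sits in the
    left hemifield when gazing East), W left-occipital, S at the occipital
    midline, N midway between occipital midline and vertex.
    """
    sigma = _SIGMA0 / cfg.topography_sharpness
    centers = _class_centers(montage)
    return [
        ClassTopography(c, _gaussian_map(montage, centers[c], sigma)) for c in CLASSES
    ]


def _class_centers(montage: Montage) -> dict[str, np.ndarray]:
    try:
        oz = montage.position("Oz")
        cz = montage.position("Cz")
        centers = {
            "E": montage.position(_PEAK_CHANNELS["E"]).copy(),
            "W": montage.position(_PEAK_CHANNELS["W"]).copy(),
            "S": oz.copy(),
            "N": (oz + cz) / 2.0,
        }
    except KeyError as err:
        raise ValueError(f"montage lacks a required channel: {err}") from err
    return centers


class Simulator:
    """Deterministic per-subject SSVEP generator.

    Subject-level quantities (harmonic phases per class, the drifted online
    topographies, the SNR calibration) are drawn once from ``cfg.seed``;
    trial noise comes from the generator passed to :meth:`generate_epoch` /
    the seed passed to :meth:`generate_session`.
    """

    def __init__(self, cfg: SimConfig | None = None, montage: Montage | None = None):
        self.cfg = cfg or SimConfig()
        self.montage = montage or standard_montage_32()
        self.topographies = {
            t.class_id: t for t in make_class_topographies(self.montage, self.cfg)
        }

        ss = np.random.SeedSequence(self.cfg.seed)
        phase_ss, drift_ss = ss.spawn(2)
        prng = np.random.default_rng(phase_ss)
        # Stimulus-locked phases: one draw per (class, harmonic) per subject.
        self.phases = {
            c: prng.uniform(-np.pi, np.pi, self.cfg.n_harmonics) for c in CLASSES
        }
        self.online_topographies = self._drifted_topographies(
            np.random.default_rng(drift_ss)
        )

        self._alpha_weights = self._occipital_alpha_weights()
        self._prepare_noise_shaping()
        self._calibrate_signal_amplitudes()

    # ------------------------------------------------------------ topography
    def topography(self, class_id: str, session: str = "train") -> ClassTopography:
        self._check_class(class_id)
        maps = self.topographies if session == "train" else self.online_topographies
        return maps[class_id]

    def _drifted_topographies(self, rng: np.random.Generator) -> dict[str, ClassTopography]:
        """Online-session gain maps: centres shift and gains roughen with drift."""
        d = self.cfg.drift
        centers = _class_centers(self.montage)
        sigma = _SIGMA0 / self.cfg.topography_sharpness
        out = {}
        for c in CLASSES:
            # draws happen regardless of d so that changing drift alone never
            # reshuffles other subject-level randomness
            ang = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(0.2, 0.4) * np.array([np.cos(ang), np.sin(ang)])
            rough = rng.normal(0.0, 0.5, self.montage.n_channels)
            g = _gaussian_map(self.montage, centers[c] + d * shift, sigma)
            g = g * np.exp(d * rough)
            out[c] = ClassTopography(c, g / g.max())
        return out

    def _occipital_alpha_weights(self) -> np.ndarray:
        oz = self.montage.position("Oz")
        d2 = ((self.montage.positions - oz) ** 2).sum(axis=1)
        return 0.25 + 0.75 * np.exp(-d2 / (2 * 0.6**2))

    # ---------------------------------------------------------------- noise
    def _prepare_noise_shaping(self) -> None:
        cfg = self.cfg
        n = cfg.n_samples
        freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
        # pink: amplitude ~ f^-1/2 (power ~ 1/f), flattened below 1 Hz
        g_pink = 1.0 / np.sqrt(np.clip(freqs, 1.0, None))
        g_pink[0] = 0.0
        if n % 2 == 0:
            g_pink[-1] = 0.0
        # alpha: narrowband Gaussian bump at 10 +/- ~1 Hz
        g_alpha = np.exp(-((freqs - 10.0) ** 2) / (2 * 0.5**2))
        g_alpha[0] = 0.0
        if n % 2 == 0:
            g_alpha[-1] = 0.0

        def total_var(g):  # variance of irfft of g * complex standard normal
            return 4.0 * np.sum(g**2) / n**2

        self._g_pink = g_pink * (cfg.noise_rms / np.sqrt(total_var(g_pink)))
        a_rms = cfg.alpha_power * cfg.noise_rms
        self._g_alpha = (
            g_alpha * (a_rms / np.sqrt(total_var(g_alpha))) if a_rms > 0 else g_alpha * 0.0
        )
        self._band = np.abs(freqs - cfg.f_stim) <= 0.5
        self._freqs = freqs

    def noise_band_power(self, class_id: str) -> float:
        """Expected noise power (uV^2) in the 1 Hz band around f_stim at the
        class's peak channel."""
        self._check_class(class_id)
        n = self.cfg.n_samples
        peak = self.topographies[class_id].peak_channel
        w = self._alpha_weights[peak]
        p_pink = 4.0 * np.sum(self._g_pink[self._band] ** 2) / n**2
        p_alpha = 4.0 * np.sum((w * self._g_alpha[self._band]) ** 2) / n**2
        return float(p_pink + p_alpha)

    def _calibrate_signal_amplitudes(self) -> None:
        amps = np.asarray(self.cfg.harmonic_amplitudes, dtype=float)
        self.signal_scale: dict[str, float] = {}
        for c in CLASSES:
            if np.all(amps == 0):
                self.signal_scale[c] = 0.0
                continue
            if amps[0] == 0:
                raise ValueError(
                    "snr_db is defined at the fundamental; its amplitude cannot be 0 "
                    "unless all harmonic amplitudes are 0"
                )
            target = self.noise_band_power(c) * 10.0 ** (self.cfg.snr_db / 10.0)
            # fundamental power at unit gain = (scale * a1)^2 / 2
            self.signal_scale[c] = float(np.sqrt(2.0 * target) / amps[0])

    def _draw_shaped_noise(self, g: np.ndarray, n_rows: int, rng: np.random.Generator) -> np.ndarray:
        n = self.cfg.n_samples
        z = rng.standard_normal((n_rows, g.size)) + 1j * rng.standard_normal(
            (n_rows, g.size)
        )
        return np.fft.irfft(z * g, n=n, axis=1)

    # --------------------------------------------------------------- epochs
    def generate_epoch(
        self, class_id: str, rng: np.random.Generator, session: str = "train"
    ) -> np.ndarray:
        """One (channels x samples) trial in microvolts, onset at t = 0."""
        self._check_class(class_id)
        cfg = self.cfg
        t = np.arange(cfg.n_samples) / cfg.fs
        amps = np.asarray(cfg.harmonic_amplitudes, dtype=float)
        wave = np.zeros_like(t)
        for h in range(cfg.n_harmonics):
            wave += amps[h] * np.sin(
                2 * np.pi * (h + 1) * cfg.f_stim * t + self.phases[class_id][h]
            )
        gains = self.topography(class_id, session).gains
        sig = self.signal_scale[class_id] * gains[:, None] * wave[None, :]
        pink = self._draw_shaped_noise(self._g_pink, self.montage.n_channels, rng)
        alpha = self._draw_shaped_noise(self._g_alpha, self.montage.n_channels, rng)
        return sig + pink + self._alpha_weights[:, None] * alpha

    def generate_session(
        self, n_sequences: int, seed, session: str = "train"
    ) -> EpochSet:
        """A block of ``n_sequences`` sequences; each sequence presents all 4
        targets in random order, so the label histogram is exactly uniform.
        ``seed`` may be an int or a ``numpy.random.SeedSequence``."""
        if n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        rng = np.random.default_rng(seed)
        data, labels = [], []
        for _ in range(n_sequences):
            for c in rng.permutation(np.array(CLASSES, dtype=object)):
                labels.append(str(c))
                data.append(self.generate_epoch(str(c), rng, session=session))
        return EpochSet(
            data=np.stack(data),
            fs=self.cfg.fs,
            labels=np.array(labels, dtype=object),
            montage=self.montage,
            t0=0.0,
        )

    @staticmethod
    def _check_class(class_id: str) -> None:
        if class_id not in CLASSES:
            raise ValueError(f"class_id must be one of {CLASSES}, got {class_id!r}")


# Functional wrappers -------------------------------------------------------

def generate_epoch(
    class_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    montage: Montage | None = None,
    session: str = "train",
) -> np.ndarray:
    return Simulator(cfg, montage).generate_epoch(class_id, rng, session=session)


def generate_session(
    n_sequences: int,
    cfg: SimConfig,
    seed: int,
    montage: Montage | None = None,
    session: str = "train",
) -> EpochSet:
    return Simulator(cfg, montage).generate_session(n_sequences, seed, session=session)
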