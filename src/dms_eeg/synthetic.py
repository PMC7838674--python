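"""Synthetic two-class motor-imagery EEG trials.

Emulates the statistical structure of a cued left/right motor-imagery
recording from the three central electrodes C3, Cz, C4: each channel is
band-limited 1/f^alpha background noise plus mu (~10 Hz) and beta (~20 Hz)
oscillations with random phases.  From shortly after the cue onward, the
oscillation amplitudes on the electrode contralateral to the imagined hand
are attenuated by a fixed factor — the event-related desynchronization
(ERD) that motor imagery produces over sensorimotor cortex.  Cz is drawn
from the same process for both classes and carries no class information.

The generator is fully deterministic given its seed, which makes every
downstream stage of the pipeline (feature encoding, network training,
ablation grids) testable without the original recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng
from scipy.signal import periodogram

CHANNELS = ("C3", "Cz", "C4")
#: electrode contralateral to the imagined hand (left hand -> right cortex -> C4)
CONTRALATERAL = {"left": "C4", "right": "C3"}
LABELS = ("left", "right")


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults mirror the emulated recording protocol.

    fs / duration_s / cue_time_s follow the cued-trial paradigm (9 s trials
    at 128 Hz, cue at t = 3 s).  ``onset_delay_s`` models the subject's
    reaction delay between cue and actual imagery onset.  ``erd_depth`` is
    the fractional amplitude attenuation of the contralateral mu/beta
    oscillations during imagery (0 = no class signal, 1 = full suppression).
    Background noise has a 1/f^``noise_exponent`` spectrum band-limited to
    ``noise_band`` (matching a 0.5-30 Hz acquisition filter) and unit
    standard deviation before scaling by ``noise_sigma``.
    """

    fs: float = 128.0
    duration_s: float = 9.0
    cue_time_s: float = 3.0
    onset_delay_s: float = 0.5
    mu_freq_hz: float = 10.0
    beta_freq_hz: float = 20.0
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    erd_depth: float = 0.7
    noise_sigma: float = 1.0
    noise_exponent: float = 1.0
    noise_band: tuple[float, float] = (0.5, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.duration_s > self.cue_time_s >= 0):
            raise ValueError("require duration_s > cue_time_s >= 0")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.onset_delay_s < 0:
            raise ValueError("onset_delay_s must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass
class Trial:
    """One labeled EEG trial: (n_channels, n_samples) plus metadata."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    label: str | None
    trial_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_names)} channel names")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def _background_noise(rng: Generator, n: int, fs: float, exponent: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Unit-variance 1/f^alpha Gaussian noise band-limited to ``band``."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    gain[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * gain, n)
    std = x.std()
    if std > 0:
        x /= std
    return x


def generate_trial(side: str, params: SynthParams,
                   rng: Generator | None = None, trial_id: int = 0) -> Trial:
    """Generate one trial of the given class.

    The random draws (noise, oscillation phases) are identical for both
    values of ``side``; the class enters only through which channel's
    oscillation envelope is attenuated.  With ``erd_depth = 0`` the two
    class-conditional processes are therefore identical by construction.
    """
    if side not in LABELS:
        raise ValueError(f"side must be one of {LABELS}, got {side!r}")
    if rng is None:
        rng = default_rng(params.seed)
    n = params.n_samples
    t = np.arange(n) / params.fs
    onset = params.cue_time_s + params.onset_delay_s
    contra = CONTRALATERAL[side]
    data = np.empty((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        noise = _background_noise(rng, n, params.fs, params.noise_exponent,
                                  params.noise_band)
        mu_phase, beta_phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
        env = np.ones(n)
        if ch == contra:  # Cz never attenuated: pure distractor
            env[t >= onset] = 1.0 - params.erd_depth
        data[ci] = (params.noise_sigma * noise
                    + params.mu_amp * env
                    * np.sin(2.0 * np.pi * params.mu_freq_hz * t + mu_phase)
                    + params.beta_amp * env
                    * np.sin(2.0 * np.pi * params.beta_freq_hz * t + beta_phase))
    return Trial(data=data, channel_names=CHANNELS, fs=params.fs,
                 label=side, trial_id=trial_id)


def generate_dataset(n_trials: int, params: SynthParams) -> list[Trial]:
    """Generate a balanced, shuffled, seeded list of labeled trials."""
    if n_trials < 2 or n_trials % 2 != 0:
        raise ValueError("n_trials must be an even integer >= 2")
    rng = default_rng(params.seed)
    labels = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials // 2))
    order = rng.permutation(n_trials)
    labels = labels[order]
    return [generate_trial(str(side), params, rng=rng, trial_id=i)
            for i, side in enumerate(labels)]


def bandpower_contrast(trials: list[Trial], band: tuple[float, float],
                       window: tuple[float, float]):
    """Mean periodogram band power per (class, channel) over a time window.

    This is the verification oracle for the generator: it lets tests assert
    that the lateralized mu/beta contrast exists (and sits on the correct
    electrode) before any network is trained.  Returns a pandas DataFrame
    indexed by class label with one column per channel.
    """
    import pandas as pd

    if not trials:
        raise ValueError("empty trial list")
    fs = trials[0].fs
    if not (0.0 <= band[0] < band[1] <= fs / 2.0):
        raise ValueError(f"band {band} outside [0, fs/2]")
    t0, t1 = window
    n = trials[0].n_samples
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if not (0 <= i0 < i1 <= n):
        raise ValueError(f"window {window} outside trial")
    channels = trials[0].channel_names
    acc: dict[tuple[str, str], list[float]] = {}
    for tr in trials:
        if tr.label is None:
            continue
        for ch in channels:
            seg = tr.channel(ch)[i0:i1]
            freqs, pxx = periodogram(seg, fs=fs)
            sel = (freqs >= band[0]) & (freqs <= band[1])
            acc.setdefault((tr.label, ch), []).append(float(pxx[sel].mean()))
    labels = sorted({k[0] for k in acc})
    return pd.DataFrame(
        {ch: [float(np.mean(acc[(lab, ch)])) for lab in labels] for ch in channels},
        index=labels)
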