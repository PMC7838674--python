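"""Short-time Fourier transform feature encoding.

Segmented trials become time-frequency images: each channel's signal is cut
into hopped, windowed frames, each frame is Fourier-transformed, magnitudes
are restricted to the analysis band and channels are stacked as the third
axis of one image.  Spectral leakage from the finite frames is controlled
by the choice of taper (boxcar, triang, hamming, hann, bartlett).

The production transform uses :func:`numpy.fft.fft`; :func:`dft_oracle` is
an O(N^2) direct-summation DFT kept as an independent correctness oracle —
every production frame must match it to machine precision on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows as _windows

from .io import DatasetBundle

WINDOW_NAMES = ("boxcar", "triang", "hamming", "hann", "bartlett")

_WINDOW_FUNCS = {
    "boxcar": lambda n: _windows.boxcar(n),
    "triang": lambda n: _windows.triang(n, sym=True),
    "hamming": lambda n: _windows.hamming(n, sym=True),
    "hann": lambda n: _windows.hann(n, sym=True),
    "bartlett": lambda n: _windows.bartlett(n, sym=True),
}


@dataclass(frozen=True)
class WindowSpec:
    """A named symmetric taper of a given length."""

    name: str = "hann"
    length: int = 64

    def __post_init__(self):
        if self.name not in WINDOW_NAMES:
            raise ValueError(f"unknown window {self.name!r}; "
                             f"choose from {WINDOW_NAMES}")
        if self.length < 1:
            raise ValueError("window length must be >= 1")


def window_coefficients(spec: WindowSpec) -> np.ndarray:
    """Return the symmetric taper coefficients w(0..N-1).

    boxcar: all ones; hann: 0.5 - 0.5 cos(2 pi n / (N-1));
    hamming: 0.54 - 0.46 cos(2 pi n / (N-1)); bartlett: triangle touching
    zero at both ends; triang: triangle that does not reach zero.
    """
    return np.asarray(_WINDOW_FUNCS[spec.name](spec.length), dtype=np.float64)


@dataclass(frozen=True)
class STFTConfig:
    """Windowing, hop and band parameters for the feature transform.

    Defaults: 64-sample (0.5 s at 128 Hz) window, hop 16, 64-point FFT —
    2 Hz frequency bins that resolve the mu and beta rhythms, and 21 frames
    over a 3 s segment.  ``band`` keeps only bins inside the acquisition
    passband.  ``log_magnitude`` applies log(1+|.|); ``normalize`` z-scores
    each trial's feature values.
    """

    window: WindowSpec = field(default_factory=WindowSpec)
    hop: int = 16
    n_fft: int = 64
    band: tuple[float, float] = (0.5, 30.0)
    log_magnitude: bool = True
    normalize: bool = True

    def __post_init__(self):
        if not (1 <= self.hop <= self.window.length <= self.n_fft):
            raise ValueError("require 1 <= hop <= window.length <= n_fft")
        if not (0.0 <= self.band[0] < self.band[1]):
            raise ValueError(f"invalid band {self.band}")


@dataclass
class FeatureTensor:
    """STFT-encoded trial: (n_freq_bins, n_frames, n_input_channels)."""

    values: np.ndarray
    bin_freqs: np.ndarray
    frame_times: np.ndarray
    label: str | None = None
    trial_id: int = 0

    @property
    def shape(self):
        return self.values.shape


def rotation_factor(N: int, k) -> np.ndarray:
    """The DFT rotation factor W_N^k = exp(-j 2 pi k / N)."""
    return np.exp(-2j * np.pi * np.asarray(k) / N)


def dft_oracle(x) -> np.ndarray:
    """Direct O(N^2) discrete Fourier transform.

    T(k) = sum_n t(n) W_N^{nk}.  This is the testing oracle for the fast
    production transform, computed by an explicit double loop; do not use
    it on long signals.
    """
    x = np.asarray(x, dtype=np.complex128)
    if x.size == 0:
        raise ValueError("empty input")
    n = x.size
    out = np.empty(n, dtype=np.complex128)
    for k in range(n):
        acc = 0.0 + 0.0j
        for i in range(n):
            acc += x[i] * np.exp(-2j * np.pi * i * k / n)
        out[k] = acc
    return out


def n_frames(n_samples: int, window_length: int, hop: int) -> int:
    if n_samples < window_length:
        raise ValueError(f"signal of {n_samples} samples shorter than "
                         f"window of {window_length}")
    return 1 + (n_samples - window_length) // hop


def stft(signal, cfg: STFTConfig) -> np.ndarray:
    """Hopped windowed DFT of a 1-D signal -> (n_fft, n_frames) complex.

    Frame m covers samples [m*hop, m*hop + N); no centering and no edge
    padding (a signal shorter than the window is an error), each frame is
    zero-padded from the window length to ``n_fft`` before the transform.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("stft expects a 1-D signal")
    N = cfg.window.length
    m = n_frames(x.size, N, cfg.hop)
    w = window_coefficients(cfg.window)
    frames = np.zeros((m, cfg.n_fft))
    for i in range(m):
        frames[i, :N] = x[i * cfg.hop : i * cfg.hop + N] * w
    return np.fft.fft(frames, n=cfg.n_fft, axis=1).T


def band_bins(fs: float, n_fft: int, band: tuple[float, float]) -> np.ndarray:
    """Indices of non-negative-frequency bins with f_lo <= f <= f_hi."""
    freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    idx = np.nonzero((freqs >= band[0]) & (freqs <= band[1]))[0]
    return idx


def encode_features(bundle: DatasetBundle, cfg: STFTConfig) -> list[FeatureTensor]:
    """Encode every trial of a segmented bundle into a FeatureTensor.

    Per channel: |STFT| (optionally log(1+|.|)), rows restricted to the
    configured band, channels stacked along the third axis; optional
    per-trial z-scoring over all values of the tensor.
    """
    if not bundle.trials:
        raise ValueError("empty bundle")
    fs = bundle.fs
    idx = band_bins(fs, cfg.n_fft, cfg.band)
    if idx.size == 0:
        raise ValueError(f"band {cfg.band} excludes all {cfg.n_fft}-point "
                         f"FFT bins at fs={fs}")
    freqs = idx * fs / cfg.n_fft
    out = []
    for tr in bundle.trials:
        mats = []
        for c in range(tr.data.shape[0]):
            spec = np.abs(stft(tr.data[c], cfg))[idx, :]
            if cfg.log_magnitude:
                spec = np.log1p(spec)
            mats.append(spec)
        values = np.stack(mats, axis=-1)
        if cfg.normalize:
            mean, std = values.mean(), values.std()
            values = (values - mean) / (std if std > 0 else 1.0)
        frame_times = (np.arange(values.shape[1]) * cfg.hop
                       + cfg.window.length / 2.0) / fs
        out.append(FeatureTensor(values=values, bin_freqs=freqs,
                                 frame_times=frame_times,
                                 label=tr.label, trial_id=tr.trial_id))
    return out


def feature_array(features: list[FeatureTensor]) -> np.ndarray:
    """Stack FeatureTensors into an (n, n_bins, n_frames, n_channels) array."""
    return np.stack([f.values for f in features])


def save_features(features: list[FeatureTensor], path) -> None:
    labels = np.array([f.label if f.label is not None else "" for f in features])
    np.savez(path, values=feature_array(features), labels=labels,
             bin_freqs=features[0].bin_freqs,
             frame_times=features[0].frame_times)


def load_features(path) -> list[FeatureTensor]:
    with np.load(path, allow_pickle=False) as f:
        values = f["values"]
        labels = [str(x) for x in f["labels"]]
        bin_freqs = f["bin_freqs"]
        frame_times = f["frame_times"]
    return [FeatureTensor(values=values[i], bin_freqs=bin_freqs,
                          frame_times=frame_times, label=labels[i] or None,
                          trial_id=i)
            for i in range(values.shape[0])]
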