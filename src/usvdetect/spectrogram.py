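"""Hanning-windowed short-time power spectrogram, restricted to the analysis band.

Mouse USVs are nearly mono-frequency whistles between 30 and 120 kHz that
modulate quickly, so the short-time Fourier transform needs short windows
(2.5-3.3 ms) with heavy overlap (75-85%) to resolve them at 250-300 kHz
sampling rates.  With the FFT length equal to the window length this gives a
frequency resolution of roughly 300-400 Hz and a hop of ~0.5 ms.  All later
processing works on the power values of the bins whose centre frequencies
fall inside the analysis band.

Edge handling is deliberately simple: frames start at sample 0, no padding
is applied, and a trailing partial frame is discarded, so the frame count is
``floor((n_samples - n_window) / hop) + 1``.  Frame timestamps are window
centres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sp_fft
from scipy.signal import get_window

from .audio_io import Recording
from .errors import ConfigError, TooShortError

__all__ = ["StftConfig", "PowerSpectrogram", "compute_power_spectrogram"]

_CHUNK_FRAMES = 8192  # bound transient memory of the batched FFT


@dataclass(frozen=True)
class StftConfig:
    """Short-time transform parameters.

    Parameters
    ----------
    window_length_ms
        Hanning window length in milliseconds (default 3.0; sensible range
        2.5-3.3 ms at 250-300 kHz sampling).
    overlap_fraction
        Fractional overlap of consecutive windows in [0, 1) (default 0.80,
        sensible range 0.75-0.85).
    band_low_hz, band_high_hz
        Closed analysis band; bins with centre frequencies outside
        [band_low_hz, band_high_hz] are discarded (defaults 30 and 120 kHz).
    fft_length_policy
        ``"window"`` (default): FFT length equals the window length in
        samples. ``"pow2"``: next power of two, trading exact bin spacing
        for speed.
    """

    window_length_ms: float = 3.0
    overlap_fraction: float = 0.80
    band_low_hz: float = 30_000.0
    band_high_hz: float = 120_000.0
    fft_length_policy: str = "window"

    def __post_init__(self) -> None:
        if not self.window_length_ms > 0:
            raise ConfigError("window_length_ms must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigError("overlap_fraction must lie in [0, 1)")
        if not self.band_low_hz < self.band_high_hz:
            raise ConfigError("band_low_hz must be below band_high_hz")
        if self.fft_length_policy not in ("window", "pow2"):
            raise ConfigError("fft_length_policy must be 'window' or 'pow2'")

    def window_samples(self, sample_rate: int) -> int:
        return int(round(self.window_length_ms * sample_rate / 1000.0))

    def hop_samples(self, sample_rate: int) -> int:
        n_win = self.window_samples(sample_rate)
        return max(1, int(round(n_win * (1.0 - self.overlap_fraction))))

    def fft_length(self, n_win: int) -> int:
        if self.fft_length_policy == "pow2":
            return 1 << (n_win - 1).bit_length()
        return n_win


@dataclass(frozen=True)
class PowerSpectrogram:
    """Time x frequency grid of non-negative power values inside the band.

    Attributes
    ----------
    power
        Array of shape (n_frames, n_bins); squared DFT magnitudes.
    frame_times_s
        Centre time of each frame in seconds, strictly increasing with
        constant step ``hop_s``.
    bin_freqs_hz
        Centre frequency of each retained bin, strictly increasing.
    hop_s, window_s
        Hop and window durations in seconds.
    """

    power: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    hop_s: float
    window_s: float

    @property
    def n_frames(self) -> int:
        return int(self.power.shape[0])

    @property
    def n_bins(self) -> int:
        return int(self.power.shape[1])


def compute_power_spectrogram(rec: Recording, cfg: StftConfig | None = None) -> PowerSpectrogram:
    """Compute the band-restricted Hanning power spectrogram of a recording.

    Each frame of ``round(window_length_ms * sample_rate / 1000)`` samples is
    multiplied by a Hanning window, discrete-Fourier transformed, and the
    squared magnitude is kept for the bins whose centre frequency lies in the
    closed analysis band.

    Raises
    ------
    TooShortError
        If the recording is shorter than one window.
    ConfigError
        If the band extends above the Nyquist frequency.
    """
    if cfg is None:
        cfg = StftConfig()
    fs = rec.sample_rate
    n_win = cfg.window_samples(fs)
    hop = cfg.hop_samples(fs)
    if rec.n_samples < n_win:
        raise TooShortError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{n_win}-sample analysis window"
        )
    if cfg.band_high_hz > fs / 2:
        raise ConfigError(
            f"band_high_hz={cfg.band_high_hz:g} exceeds the Nyquist frequency {fs / 2:g}"
        )

    nfft = cfg.fft_length(n_win)
    window = get_window("hann", n_win)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    bin_freqs = freqs[band]

    frames = sliding_window_view(rec.samples, n_win)[::hop]
    n_frames = frames.shape[0]
    power = np.empty((n_frames, bin_freqs.size), dtype=np.float64)
    for lo in range(0, n_frames, _CHUNK_FRAMES):
        hi = min(lo + _CHUNK_FRAMES, n_frames)
        spec = sp_fft.rfft(frames[lo:hi] * window, n=nfft, axis=1)
        power[lo:hi] = (spec.real**2 + spec.imag**2)[:, band]

    frame_times = (np.arange(n_frames) * hop + n_win / 2.0) / fs
    return PowerSpectrogram(
        power=power,
        frame_times_s=frame_times,
        bin_freqs_hz=bin_freqs,
        hop_s=hop / fs,
        window_s=n_win / fs,
    )
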