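"""Reading and writing PCM WAV audio.

Recordings of mouse ultrasonic vocalizations are single-channel 16-bit PCM
files sampled at 250-300 kHz.  Internally all audio is represented as a
:class:`Recording`: a float waveform normalized to [-1, 1] plus its sample
rate.  No resampling is ever performed; every millisecond-valued parameter
downstream is converted to samples or frames at run time using the carried
sample rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import AudioFormatError

__all__ = ["Recording", "read_wav", "write_wav"]

_log = logging.getLogger(__name__)

#: full-scale code for symmetric 16-bit conversion (read x/32768, write
#: round(x*32768) clipped to the int16 range)
_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class Recording:
    """A sampled waveform with amplitudes normalized to [-1, 1].

    Parameters
    ----------
    samples
        1-D float array of amplitude values in [-1, 1] (dimensionless).
    sample_rate
        Sampling rate in Hz (positive integer).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Recording.samples must be one-dimensional")
        if samples.size < 1:
            raise ValueError("Recording must contain at least one sample")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError("sample_rate must be a positive integer")
        peak = float(np.max(np.abs(samples))) if samples.size else 0.0
        if peak > 1.0:
            raise ValueError(f"sample values must lie in [-1, 1]; peak is {peak:.6g}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Duration in seconds, exactly n_samples / sample_rate."""
        return self.n_samples / self.sample_rate


def read_wav(path: str | Path) -> Recording:
    """Read a PCM WAV file into a normalized :class:`Recording`.

    Integer sample formats are rescaled to [-1, 1] (int16 by 1/32768, int32
    by 1/2**31, uint8 offset-binary by 1/128); 32/64-bit float data is taken
    as already normalized.  Multi-channel files are reduced to channel 0
    with a logged warning.

    Raises
    ------
    AudioFormatError
        If the file is missing, not a readable PCM WAV, or contains no audio.
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such audio file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy chunk warnings on odd metadata
            rate, data = wavfile.read(str(path))
    except (ValueError, EOFError) as exc:
        raise AudioFormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path} contains no audio samples")
    if data.ndim > 1:
        _log.warning("%s has %d channels; keeping channel 0 only", path, data.shape[1])
        data = data[:, 0]

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
        peak = float(np.max(np.abs(samples)))
        if peak > 1.0:
            _log.warning("%s float data exceeds full scale (peak %.3g); clipping", path, peak)
            samples = np.clip(samples, -1.0, 1.0)
    else:
        raise AudioFormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Recording(samples=samples, sample_rate=int(rate))


def write_wav(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` to disk as 16-bit PCM WAV.

    Values are quantized symmetrically (code = round(x * 32768), clipped to
    the int16 range), so ``read_wav(write_wav(...))`` recovers every sample
    to within one least-significant bit.  Out-of-range input would have been
    rejected by the Recording invariant; +1.0 maps to the maximum positive
    code 32767.
    """
    codes = np.clip(np.round(rec.samples * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), rec.sample_rate, codes)
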