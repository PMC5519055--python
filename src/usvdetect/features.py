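"""Per-element frequency contour and spectro-temporal parameter extraction.

Every detected element gets a frame-by-frame frequency track (the dominant
frequency of the whitened spectrum) and the standard parameter set: begin
and length, mean frequency and bandwidth, mean amplitude, and the
time/frequency/amplitude triples at the start, end, lowest-frequency and
highest-frequency points of the contour.  Amplitudes are read from the raw
(un-whitened) spectrum at the dominant bin so they reflect the recorded
level, not the noise-normalized one.

Units follow the conventional report layout: begin and length in seconds,
frequencies in Hz, amplitudes in dB, and the contour time points (t1, tn,
tfmin, tfmax) in milliseconds from the start of the file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrogram import PowerSpectrogram
from .segmentation import Segment

__all__ = ["FrequencyTrack", "Element", "extract_frequency_track", "compute_features"]

_AMP_FLOOR = np.finfo(np.float64).tiny


@dataclass(frozen=True)
class FrequencyTrack:
    """Per-frame contour of one element: times (ms), dominant frequencies (Hz), amplitudes (dB)."""

    times_ms: np.ndarray
    freqs_hz: np.ndarray
    amps_db: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times_ms) == len(self.freqs_hz) == len(self.amps_db)):
            raise ValueError("track sequences must have equal length")
        if len(self.times_ms) < 1:
            raise ValueError("track must contain at least one frame")


@dataclass(frozen=True)
class Element:
    """A detected syllable candidate with its full parameter set.

    ``fband_hz = fmax_hz - fmin_hz``; min/max ties resolve to the earliest
    frame.  ``track`` keeps the underlying contour.
    """

    begin_s: float
    length_s: float
    fmean_hz: float
    fband_hz: float
    amean_db: float
    t1_ms: float
    f1_hz: float
    a1_db: float
    tn_ms: float
    fn_hz: float
    an_db: float
    tfmin_ms: float
    fmin_hz: float
    afmin_db: float
    tfmax_ms: float
    fmax_hz: float
    afmax_db: float
    track: FrequencyTrack


def extract_frequency_track(
    ps: PowerSpectrogram, seg: Segment, raw_ps: PowerSpectrogram | None = None
) -> FrequencyTrack:
    """Dominant-frequency contour of a segment.

    Per frame of the segment, the dominant frequency is the centre frequency
    of the maximum-power bin of ``ps`` (normally the whitened spectrogram,
    where the noise floor is flat and the whistle bin wins).  The amplitude
    is the dB level of that same bin read from ``raw_ps`` (the un-whitened
    spectrogram) when given, else from ``ps``.
    """
    if seg.first_frame < 0 or seg.last_frame >= ps.n_frames:
        raise ValueError(
            f"segment frames [{seg.first_frame}, {seg.last_frame}] outside "
            f"spectrogram with {ps.n_frames} frames"
        )
    if raw_ps is not None and raw_ps.power.shape != ps.power.shape:
        raise ValueError("raw spectrogram shape differs from the whitened one")
    sl = slice(seg.first_frame, seg.last_frame + 1)
    block = ps.power[sl]
    dominant = block.argmax(axis=1)
    amp_source = (raw_ps.power[sl] if raw_ps is not None else block)
    amp_power = amp_source[np.arange(dominant.size), dominant]
    return FrequencyTrack(
        times_ms=ps.frame_times_s[sl] * 1000.0,
        freqs_hz=ps.bin_freqs_hz[dominant],
        amps_db=10.0 * np.log10(np.maximum(amp_power, _AMP_FLOOR)),
    )


def compute_features(track: FrequencyTrack, seg: Segment) -> Element:
    """Assemble the element parameter set from a contour and its segment."""
    freqs = track.freqs_hz
    amps = track.amps_db
    times = track.times_ms
    i_min = int(np.argmin(freqs))  # argmin/argmax take the earliest tie
    i_max = int(np.argmax(freqs))
    return Element(
        begin_s=seg.start_s,
        length_s=seg.duration_s,
        fmean_hz=float(freqs.mean()),
        fband_hz=float(freqs[i_max] - freqs[i_min]),
        amean_db=float(amps.mean()),
        t1_ms=float(times[0]),
        f1_hz=float(freqs[0]),
        a1_db=float(amps[0]),
        tn_ms=float(times[-1]),
        fn_hz=float(freqs[-1]),
        an_db=float(amps[-1]),
        tfmin_ms=float(times[i_min]),
        fmin_hz=float(freqs[i_min]),
        afmin_db=float(amps[i_min]),
        tfmax_ms=float(times[i_max]),
        fmax_hz=float(freqs[i_max]),
        afmax_db=float(amps[i_max]),
        track=track,
    )
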