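"""Synthetic USV-like recordings with exact ground-truth annotations.

The generator emulates the signal model the detector is built for: sparse,
narrowband, frequency-modulated whistles (constant tones, linear chirps, or
tones with an instantaneous frequency jump) between 30 and 120 kHz, lasting
tens of milliseconds, embedded in stationary broadband noise, plus short
(sub-10 ms) broadband click transients that imitate cage noise.  Every
syllable's placement, contour and level are recorded, so detection output
can be scored against an exact reference.

Syllables are amplitude-ramped (raised-cosine ramps) sinusoids whose phase
follows the sampled frequency contour; ground-truth intervals are the exact
ramp-to-ramp extents.  Per-syllable levels are set as in-band
tone-to-noise ratios (SNR, dB): the in-band noise power is measured on the
generated noise itself, so the requested SNR holds for white and colored
backgrounds alike.  Clicks never overlap syllables, which keeps false
positives attributable.  A fixed seed makes the output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .audio_io import Recording
from .errors import ConfigError
from .evaluation import IntervalSet

__all__ = ["SynthSpec", "SynthResult", "generate_recording", "snr_of", "CONTOUR_TYPES"]

CONTOUR_TYPES = ("constant", "linear_chirp", "frequency_jump")

#: guard distance (s) kept between a click and any syllable boundary
_CLICK_GUARD_S = 0.002


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic recording.

    Parameters
    ----------
    duration_s, sample_rate
        Total length (s) and sampling rate (Hz, default 300 kHz).
    n_syllables
        Number of whistles to place.
    syllable_dur_range_ms
        Uniform range of syllable durations, default (20, 100) ms.
    freq_range_hz
        Uniform range for contour frequencies, default 40-100 kHz; must lie
        inside the 30-120 kHz analysis band.
    contour_types
        Subset of ``CONTOUR_TYPES`` sampled uniformly per syllable.
    snr_db
        In-band tone-to-noise ratio; a scalar, or a (low, high) range
        sampled uniformly per syllable.
    noise_level_db
        RMS of the stationary background noise in dB re full scale
        (default -40, a realistic recorder noise floor well below
        full-scale input).
    noise_color
        ``"white"`` (default) or ``"lowpass"`` -- first-order low-frequency
        emphasis, exercising the pre-whitening stage.
    n_clicks, click_dur_range_ms, click_level_db
        Broadband transients: count, duration range (default 0.5-5 ms) and
        RMS level during the click.
    min_gap_ms
        Minimum spacing between consecutive syllables (default 50 ms, a
        typical within-bout inter-syllable interval).
    edge_margin_ms
        Syllable-free margin at both file edges (default 100 ms).
    ramp_ms
        Raised-cosine amplitude ramp at each syllable end (default 1 ms).
    seed
        Seed for the generator's random stream; fixed seed implies
        bit-identical output.
    """

    duration_s: float
    n_syllables: int
    sample_rate: int = 300_000
    syllable_dur_range_ms: tuple[float, float] = (20.0, 100.0)
    freq_range_hz: tuple[float, float] = (40_000.0, 100_000.0)
    contour_types: tuple[str, ...] = ("constant", "linear_chirp")
    snr_db: float | tuple[float, float] = 20.0
    noise_level_db: float = -40.0
    noise_color: str = "white"
    n_clicks: int = 0
    click_dur_range_ms: tuple[float, float] = (0.5, 5.0)
    click_level_db: float = -25.0
    min_gap_ms: float = 50.0
    edge_margin_ms: float = 100.0
    ramp_ms: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sample_rate <= 0:
            raise ConfigError("duration_s and sample_rate must be positive")
        if self.n_syllables < 0 or self.n_clicks < 0:
            raise ConfigError("n_syllables and n_clicks must be non-negative")
        lo, hi = self.syllable_dur_range_ms
        if not 0 < lo <= hi:
            raise ConfigError("syllable_dur_range_ms must be an increasing positive range")
        flo, fhi = self.freq_range_hz
        if not (0 < flo <= fhi < self.sample_rate / 2):
            raise ConfigError("freq_range_hz must be increasing and below Nyquist")
        unknown = set(self.contour_types) - set(CONTOUR_TYPES)
        if unknown or not self.contour_types:
            raise ConfigError(f"contour_types must be a non-empty subset of {CONTOUR_TYPES}")
        if self.noise_color not in ("white", "lowpass"):
            raise ConfigError("noise_color must be 'white' or 'lowpass'")
        if self.min_gap_ms < 0 or self.edge_margin_ms < 0 or self.ramp_ms < 0:
            raise ConfigError("gaps, margins and ramps must be non-negative")

    def snr_range(self) -> tuple[float, float]:
        if isinstance(self.snr_db, (int, float)):
            return (float(self.snr_db), float(self.snr_db))
        lo, hi = self.snr_db
        return (float(lo), float(hi))


@dataclass(frozen=True)
class SynthResult:
    """Generated audio plus its exact ground truth."""

    recording: Recording
    truth: IntervalSet
    syllables: pd.DataFrame
    clicks: pd.DataFrame


def _bandpass_sos(sample_rate: int, band: tuple[float, float] = (30_000.0, 120_000.0)):
    lo, hi = band
    nyq = sample_rate / 2.0
    hi = min(hi, nyq * 0.999)
    return signal.butter(8, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def _make_noise(rng: np.random.Generator, n: int, rms: float, color: str) -> np.ndarray:
    noise = rng.standard_normal(n)
    if color == "lowpass":
        # first-order low-frequency emphasis; pre-whitening must flatten it
        noise = signal.lfilter([1.0], [1.0, -0.9], noise)
    measured = float(np.sqrt(np.mean(noise**2)))
    return noise * (rms / measured)


def _contour(rng: np.random.Generator, kind: str, n: int,
             freq_range: tuple[float, float]) -> np.ndarray:
    flo, fhi = freq_range
    if kind == "constant":
        return np.full(n, rng.uniform(flo, fhi))
    if kind == "linear_chirp":
        f0, f1 = rng.uniform(flo, fhi, size=2)
        return np.linspace(f0, f1, n)
    # frequency_jump: two constant halves with an instantaneous step
    f0, f1 = rng.uniform(flo, fhi, size=2)
    out = np.empty(n)
    out[: n // 2] = f0
    out[n // 2:] = f1
    return out


def _place_syllables(
    rng: np.random.Generator, spec: SynthSpec, durations_s: np.ndarray
) -> np.ndarray:
    """Start times honouring edge margins and minimum gaps.

    The slack left over after stacking syllables, gaps and margins is split
    into random extra spacings (order statistics of uniforms), which yields
    an exact feasibility check and uniform-ish placement.
    """
    n = durations_s.size
    margin = spec.edge_margin_ms / 1000.0
    min_gap = spec.min_gap_ms / 1000.0
    occupied = durations_s.sum() + max(n - 1, 0) * min_gap + 2 * margin
    free = spec.duration_s - occupied
    if free < 0:
        raise ConfigError(
            f"cannot place {n} syllables totalling {durations_s.sum():.3f}s "
            f"(+gaps/margins) in {spec.duration_s:.3f}s"
        )
    cuts = np.sort(rng.uniform(0.0, free, size=n + 1))
    extra = np.diff(np.concatenate(([0.0], cuts)))[:n]
    starts = np.empty(n)
    t = margin
    for i in range(n):
        t += extra[i]
        starts[i] = t
        t += durations_s[i] + min_gap
    return starts


def generate_recording(spec: SynthSpec) -> SynthResult:
    """Synthesize a recording per spec; returns audio, truth intervals and tables."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n_total = int(round(spec.duration_s * fs))
    noise_rms = 10.0 ** (spec.noise_level_db / 20.0)
    samples = _make_noise(rng, n_total, noise_rms, spec.noise_color)

    # the requested SNR is relative to the noise power inside the analysis
    # band, measured on the actual noise realisation
    sos = _bandpass_sos(fs)
    inband = signal.sosfiltfilt(sos, samples)
    noise_power_inband = float(np.mean(inband**2))

    dur_lo, dur_hi = spec.syllable_dur_range_ms
    durations_s = rng.uniform(dur_lo, dur_hi, size=spec.n_syllables) / 1000.0
    starts_s = _place_syllables(rng, spec, durations_s)
    snr_lo, snr_hi = spec.snr_range()

    rows = []
    for i in range(spec.n_syllables):
        n_syl = int(round(durations_s[i] * fs))
        i0 = int(round(starts_s[i] * fs))
        kind = spec.contour_types[rng.integers(len(spec.contour_types))]
        freqs = _contour(rng, kind, n_syl, spec.freq_range_hz)
        snr = rng.uniform(snr_lo, snr_hi)
        amp = float(np.sqrt(2.0 * noise_power_inband * 10.0 ** (snr / 10.0)))
        phase = 2.0 * np.pi * np.cumsum(freqs) / fs
        tone = amp * np.sin(phase)
        n_ramp = min(int(round(spec.ramp_ms / 1000.0 * fs)), n_syl // 2)
        if n_ramp > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            tone[:n_ramp] *= ramp
            tone[-n_ramp:] *= ramp[::-1]
        samples[i0: i0 + n_syl] += tone
        rows.append(
            {
                "start_s": i0 / fs,
                "end_s": (i0 + n_syl) / fs,
                "duration_ms": n_syl / fs * 1000.0,
                "contour": kind,
                "f_min_hz": float(freqs.min()),
                "f_max_hz": float(freqs.max()),
                "snr_db": float(snr),
                "amplitude": amp,
            }
        )
    syllables = pd.DataFrame(
        rows,
        columns=["start_s", "end_s", "duration_ms", "contour",
                 "f_min_hz", "f_max_hz", "snr_db", "amplitude"],
    )

    clicks = _add_clicks(rng, spec, samples, syllables)

    peak = float(np.max(np.abs(samples)))
    if peak > 1.0:  # headroom guard; scales signal and noise alike
        samples /= peak * 1.0001
    rec = Recording(samples=samples, sample_rate=fs)
    truth = IntervalSet.from_pairs(
        list(zip(syllables["start_s"], syllables["end_s"])), source_label="truth"
    )
    return SynthResult(recording=rec, truth=truth, syllables=syllables, clicks=clicks)


def _add_clicks(
    rng: np.random.Generator,
    spec: SynthSpec,
    samples: np.ndarray,
    syllables: pd.DataFrame,
) -> pd.DataFrame:
    fs = spec.sample_rate
    n_total = samples.size
    click_rms = 10.0 ** (spec.click_level_db / 20.0)
    forbidden = [
        (s - _CLICK_GUARD_S, e + _CLICK_GUARD_S)
        for s, e in zip(syllables["start_s"], syllables["end_s"])
    ]
    rows = []
    attempts = 0
    max_attempts = 1000 * max(spec.n_clicks, 1)
    while len(rows) < spec.n_clicks:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError("could not place clicks without touching syllables")
        dur = rng.uniform(*spec.click_dur_range_ms) / 1000.0
        start = rng.uniform(0.0, spec.duration_s - dur)
        if any(start < e and start + dur > s for s, e in forbidden):
            continue
        n_click = max(int(round(dur * fs)), 2)
        i0 = int(round(start * fs))
        if i0 + n_click > n_total:
            continue
        burst = rng.standard_normal(n_click) * signal.windows.hann(n_click)
        burst *= click_rms / max(float(np.sqrt(np.mean(burst**2))), 1e-30)
        samples[i0: i0 + n_click] += burst
        rows.append({"start_s": i0 / fs, "end_s": (i0 + n_click) / fs,
                     "duration_ms": n_click / fs * 1000.0})
        forbidden.append((i0 / fs, (i0 + n_click) / fs))
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_ms"])


def snr_of(
    rec: Recording,
    truth: IntervalSet,
    band: tuple[float, float] = (30_000.0, 120_000.0),
    flank_ms: float = 50.0,
    guard_ms: float = 2.0,
) -> np.ndarray:
    """Measured per-syllable SNR: in-band RMS inside each interval vs flanking noise.

    For each truth interval the in-band RMS inside the interval is compared
    (in dB) with the RMS over noise-only flanking windows of up to
    ``flank_ms`` on each side, clipped so they never enter a neighbouring
    truth interval.  Intervals with no usable flanking audio yield NaN.
    """
    fs = rec.sample_rate
    filtered = signal.sosfiltfilt(_bandpass_sos(fs, band), rec.samples)
    guard = guard_ms / 1000.0
    flank = flank_ms / 1000.0
    ivs = truth.intervals
    out = np.full(len(truth), np.nan)
    for k, (start, end) in enumerate(ivs):
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if i1 <= i0 or i1 > rec.n_samples:
            continue
        inside = filtered[i0:i1]
        lo_prev = ivs[k - 1, 1] if k > 0 else 0.0
        hi_next = ivs[k + 1, 0] if k + 1 < len(ivs) else rec.duration_s
        left_lo = max(start - guard - flank, lo_prev + guard if k > 0 else 0.0)
        left_hi = start - guard
        right_lo = end + guard
        right_hi = min(end + guard + flank, hi_next - guard if k + 1 < len(ivs) else rec.duration_s)
        noise_parts = []
        if left_hi > left_lo:
            noise_parts.append(filtered[int(left_lo * fs): int(left_hi * fs)])
        if right_hi > right_lo:
            noise_parts.append(filtered[int(right_lo * fs): int(right_hi * fs)])
        if not noise_parts:
            continue
        noise = np.concatenate(noise_parts)
        if noise.size < int(0.001 * fs):  # need at least 1 ms of context
            continue
        rms_in = float(np.sqrt(np.mean(inside**2)))
        rms_noise = float(np.sqrt(np.mean(noise**2)))
        if rms_noise == 0.0:
            out[k] = np.inf if rms_in > 0 else np.nan
        else:
            out[k] = 20.0 * np.log10(rms_in / rms_noise)
    return out
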