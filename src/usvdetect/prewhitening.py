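"""Stationary background-noise estimation and spectral pre-whitening.

The detector's segmentation statistic measures how concentrated a frame's
energy is across frequency.  Stationary background noise with a sloped
spectrum would bias that statistic, so before segmentation the background
spectrum is estimated from quiet frames and divided out ("pre-whitening"),
leaving the noise floor spectrally flat.

The quiet frames are selected adaptively per recording: the per-frame level
is the dB of the mean in-band power, the noise ceiling is set two decibels
above the 95% quantile of those levels (L_noise = L_95 + 2 dB), and every
frame below the ceiling contributes to the bin-wise mean noise spectrum.
Because the ceiling sits above the 95% quantile, quiet frames always exist.
The dB reference is power 1.0 on the normalized [-1, 1] sample scale; only
level differences matter to the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError
from .spectrogram import PowerSpectrogram

__all__ = ["NoiseProfile", "frame_levels", "estimate_noise_profile", "whiten"]

#: relative floor applied to the mean noise spectrum, preventing division
#: blow-ups in dead bands
_SPECTRUM_FLOOR_REL = 1e-12

#: absolute floor under per-frame mean power before taking log10
_LEVEL_FLOOR = np.finfo(np.float64).tiny

#: minimum number of frames for the 95% level quantile to be meaningful
_MIN_FRAMES = 20


@dataclass(frozen=True)
class NoiseProfile:
    """Per-recording background noise estimate.

    Attributes
    ----------
    l95_db
        95% quantile of the per-frame levels (dB).
    noise_level_db
        Noise ceiling, exactly ``l95_db + 2``.
    mean_noise_spectrum
        Bin-wise mean power of all frames below the ceiling, floored at a
        small positive constant (length n_bins, strictly positive).
    n_frames_used
        Number of frames that entered the average.
    """

    l95_db: float
    noise_level_db: float
    mean_noise_spectrum: np.ndarray
    n_frames_used: int


def frame_levels(ps: PowerSpectrogram) -> np.ndarray:
    """Per-frame signal level: 10*log10 of the mean in-band power.

    A tiny floor keeps digitally silent frames finite.
    """
    if ps.n_frames == 0:
        raise EstimationError("cannot compute frame levels of an empty spectrogram")
    mean_power = np.maximum(ps.power.mean(axis=1), _LEVEL_FLOOR)
    return 10.0 * np.log10(mean_power)


def estimate_noise_profile(
    ps: PowerSpectrogram,
    level_quantile: float = 95.0,
    margin_db: float = 2.0,
) -> NoiseProfile:
    """Estimate the stationary background spectrum from low-level frames.

    The quantile uses linear interpolation between order statistics.
    Frames with level strictly below ``quantile + margin_db`` are averaged
    bin-wise; the result is floored at 1e-12 times its maximum bin.

    Raises
    ------
    EstimationError
        If fewer than 20 frames are available, or (guarded, though
        impossible by construction) no frame falls below the ceiling.
    """
    if ps.n_frames < _MIN_FRAMES:
        raise EstimationError(
            f"noise estimation needs at least {_MIN_FRAMES} frames, got {ps.n_frames}"
        )
    levels = frame_levels(ps)
    l95 = float(np.percentile(levels, level_quantile))
    noise_level = l95 + margin_db
    quiet = levels < noise_level
    n_used = int(np.count_nonzero(quiet))
    if n_used == 0:
        raise EstimationError("no frame lies below the noise ceiling")
    mean_spec = ps.power[quiet].mean(axis=0)
    floor = max(float(mean_spec.max()) * _SPECTRUM_FLOOR_REL, _LEVEL_FLOOR)
    mean_spec = np.maximum(mean_spec, floor)
    return NoiseProfile(
        l95_db=l95,
        noise_level_db=noise_level,
        mean_noise_spectrum=mean_spec,
        n_frames_used=n_used,
    )


def whiten(ps: PowerSpectrogram, profile: NoiseProfile) -> PowerSpectrogram:
    """Divide every frame by the mean background spectrum, bin for bin.

    The grid dimensions are unchanged; after whitening, stationary noise has
    unit expected power in every bin.

    Raises
    ------
    ValueError
        If the profile was estimated on a different bin layout.
    """
    if profile.mean_noise_spectrum.shape != (ps.n_bins,):
        raise ValueError(
            f"noise profile has {profile.mean_noise_spectrum.size} bins, "
            f"spectrogram has {ps.n_bins}"
        )
    return PowerSpectrogram(
        power=ps.power / profile.mean_noise_spectrum,
        frame_times_s=ps.frame_times_s,
        bin_freqs_hz=ps.bin_freqs_hz,
        hop_s=ps.hop_s,
        window_s=ps.window_s,
    )
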