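# Methods

This note documents the detection model implemented in `usvdetect`, the
parameters that matter, the numerical conventions, the design choices made
where the method description left the design open, and the limits of what
the synthetic validation shows.

## Signal model and assumptions

The detector targets nearly mono-frequency, frequency-modulated whistles
between 30 and 120 kHz lasting roughly 5–200 ms, recorded single-channel at
250–300 kHz and 16 bits. It assumes:

- the background is *stationary* over the file (its spectrum may be
  arbitrarily colored, but must not drift);
- vocalizations are *sparse*: background frames form the large majority of
  the file (see "Known limitations");
- interfering transients (cage noise, clicks) are broadband and short
  (typically under 10 ms).

Under these assumptions narrowness, not amplitude, is the discriminative
property, which is why the segmentation statistic is the per-frame energy
concentration rather than a level threshold.

## Pipeline

**Spectrogram.** Hanning-windowed short-time power spectrum. Frames start
at sample 0 with no padding; a trailing partial frame is discarded, so the
frame count is `floor((n_samples − n_win)/hop) + 1`. Frame timestamps are
window centres — the method description never defines them, and centres
make the boundary error symmetric. Only bins with centre frequencies inside
the closed analysis band are kept. The window is not amplitude-normalized:
any fixed normalization cancels in the whitening and energy-bandwidth
steps.

**Pre-whitening.** Per-frame level = `10·log10(mean in-band power)`, dB re
power 1.0 on the normalized sample scale (only level *differences* matter).
The noise ceiling is the 95% level quantile plus 2 dB; frames strictly
below it are averaged bin-wise into the background spectrum, which then
divides every frame. Because the ceiling lies above the 95% quantile, the
quiet-frame set is never empty.

**Segmentation.** Per frame, `ebw` is the minimal count of
descending-sorted bins whose cumulative power reaches `r_ebw` of the
total, and `ec = n_bins/ebw`. Local maxima of `ec` strictly above `ec_on`
seed segments; each seed is extended in both directions to the last
contiguous frame with `ec ≥ ec_off`; seeds inside an already-found segment
are skipped. Then, in order: segments whose gap is strictly below
`t_mindist` are merged transitively; merged segments strictly shorter than
`t_mindur` or strictly longer than `t_maxdur` are removed.

**Features.** Per retained segment, the dominant frequency of each frame
is the centre frequency of the maximum-power *whitened* bin (on the flat
whitened floor the whistle bin wins); its amplitude is the dB level of the
same bin in the *raw* spectrum, so reported amplitudes reflect recorded
levels. The parameter set follows directly; frequency min/max ties resolve
to the earliest frame, and `fmean` is the unweighted mean over frames.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `window_length_ms` | 3.0 | ms | resolves 300–400 Hz at 250–300 kHz while following fast FM; sensible range 2.5–3.3 |
| `overlap_fraction` | 0.80 | — | hop ≈ 0.5–0.6 ms, needed for 10-ms-scale events; range 0.75–0.85 |
| `band_low_hz`, `band_high_hz` | 30 000, 120 000 | Hz | the USV band; excludes low-frequency cage noise |
| `r_ebw` | 0.45 | — | mid-range of the workable 0.3–0.6 interval; detection is insensitive inside it |
| `on_quantile` | 0.001 | — | exceedance fraction of *background* ec values for the seed threshold (see below) |
| `off_quantile` | 0.05 | — | exceedance fraction for the stop threshold |
| `t_mindist_ms` | 5 | ms | gaps below this are spectrogram artefacts, not syllable boundaries |
| `t_mindur_ms` | 10 | ms | the validated operating point: trades very short calls for click immunity |
| `t_maxdur_ms` | 200 | ms | above the longest known syllable; removes merged noise chains |

All thresholds are recomputed per file; nothing is shared across
recordings.

## Threshold derivation (the open design point)

The method description from which this package descends states the two
segmentation thresholds as the "10% quantile" and "90% quantile" of the ec
track, with high ec meaning signal. Both direct readings fail on
measurement, and this is the package's one deliberate deviation:

- *Literal percentiles* (onset = 10th, offset = 90th) put the onset
  threshold below the offset threshold, so every extension stops at its
  seed and, after the duration filter, nothing survives. Measured recall
  on the 60-s synthetic session: 0. This reading is preserved as
  `literal_quantile_mode` for comparison, and the acceptance script
  reports its recall.
- *Exceedance quantiles of the whole track* (onset exceeded by 10% of
  frames, offset by 90%) are standard hysteresis in form, but any
  whole-track quantile in that range lies inside the background's own ec
  distribution when background dominates the file — by construction 90% of
  background frames then sit above the stop threshold, extensions bleed
  many frames past each whistle, and background runs merge into 10–200 ms
  chains that pass the duration filter. Measured on the same session:
  precision 0.05. Available as `threshold_reference="all"`.

The default therefore derives both thresholds from the ec distribution of
the *background frames only* — frames whose whitened level is below the
median frame level + 6 dB. The seed threshold is the ec value exceeded by
0.1% of background frames (background essentially never seeds), the stop
threshold the value exceeded by 5% (extension ends within a frame or two
of leaving a whistle). Because the reference population is chosen by
level, not by file share, the thresholds do not drift with calling rate.
The median is used for the background mask (rather than an upper level
quantile) because it stays inside the background for any signal duty below
50%; the 6 dB margin is uncritical anywhere in roughly 2–8 dB, since
whitened background levels cluster within a fraction of a dB while a frame
containing a whistle at a workable SNR sits more than 10 dB up.

## Numerical conventions

- Quantiles interpolate linearly between order statistics throughout.
- "Below threshold" comparisons are strict (`<`); ties are kept. The
  boundary cases are pinned by tests (an exactly-`t_mindur` segment is
  retained; an exactly-`t_mindist` gap is not merged).
- An all-zero frame has `ebw = n_bins` (maximally flat) by convention.
- The mean noise spectrum is floored at `1e-12` of its maximum bin so dead
  bands cannot blow up the division; frame levels are floored just above
  zero before the logarithm so digital silence stays finite.
- A segment starts at its first frame's timestamp and ends at its last
  frame's timestamp plus one hop; gaps are `next.start − prev.end`.
- 16-bit audio I/O uses the symmetric convention `code = round(x·32768)`
  clipped to the int16 range, read back as `code/32768`, giving sub-LSB
  round trips.
- Interval matching is greedy by decreasing overlap (ties: earliest
  start), one-to-one; any positive overlap matches by default, with an
  optional fraction-of-the-shorter-interval requirement.

## The synthetic generator

`usvdetect.synth` generates what the detector is designed for: ramped
sinusoids with constant, linearly chirping, or step-jump contours
(defaults: 20–100 ms, 40–100 kHz, ≥50 ms apart — a typical within-bout
inter-syllable spacing), in stationary white or low-pass-colored Gaussian
noise (default RMS −40 dBFS, a realistic recorder noise floor), plus
Hann-enveloped broadband clicks of 0.5–5 ms that never overlap syllables,
so any false positive is attributable. Per-syllable levels are calibrated
as in-band tone-to-noise ratios against the measured in-band noise power
of the actual noise realisation, and `snr_of` verifies attainment on the
generated audio. A fixed seed makes output bit-identical.

What the generator does *not* emulate — and hence what passing tests do
not show about real recordings: non-stationary backgrounds (animal
movement), reverberation, overlapping callers, harmonics, amplitude
modulation within a syllable, and the soft onsets/offsets of real calls.
Synthetic results are an upper bound on real-data performance.

## Known limitations

- **Signal duty.** The background-spectrum rule (95% level quantile +
  2 dB) assumes quiet frames dominate. Above roughly 10% signal duty the
  ceiling climbs into the vocalization population, tone power contaminates
  the background spectrum, and whitening suppresses the very bins that
  carry the calls — measured on a 12.5%-duty synthetic file, detection
  collapses entirely. Realistic single-caller duty (tens of syllables per
  minute) is well inside the envelope; dense bouts from highly motivated
  callers may not be.
- **Contour extremes of fast chirps.** The contour is sampled at frame
  centres, but a chirp's frequency extreme sits at the syllable edge, so
  `fmin`/`fmax` carry a bias of (slope × edge offset) — typically a few
  hundred Hz to a few kHz for steep chirps, larger than one frequency bin.
  The acceptance script reports this directly as the frequency-recovery
  rate (about half of mixed-contour elements recover both extremes within
  one bin; constant tones essentially always do).
- **Boundary timestamps.** The end-of-segment convention (last frame plus
  one hop) adds a systematic half-to-one hop to offsets; onset/offset
  recovery within two hops is measured at roughly 85–98% per session, not
  100%.
- **Very short calls.** The 10 ms duration floor deliberately discards
  sub-10-ms syllables; that is the price of click immunity.
- Edge-of-file events are not detected (no STFT padding), and overlapping
  callers are out of scope.
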