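# usvdetect

Automatic detection and measurement of mouse ultrasonic vocalization (USV)
syllables in high-sample-rate audio, with a built-in evaluation framework
and a synthetic-recording generator.

House mice emit whistle-like ultrasonic calls between roughly 30 and
120 kHz, typically 5–200 ms long, at very low signal-to-noise ratios and
amid broadband cage noise. Manually segmenting ten-minute recordings takes
hours per file and is subjective, so researchers in behavioural biology and
neuroscience need detectors whose error rates can be quantified against
manual "gold standard" annotations. `usvdetect` provides such a detector,
the scoring machinery, and a generator of realistic synthetic recordings
with exact ground truth, so the whole pipeline is testable without any
animal data.

## The detection statistic

What separates a USV from background is not amplitude but *narrowness*.
Per spectrogram frame, sort the in-band power spectrum `PS` by descending
power; the **energy bandwidth** is the smallest number of bins whose summed
power reaches a fixed fraction of the frame's total:

    ebw = min{ k : Σᵢ₌₁..k PSᵢ ≥ R_ebw · Σᵢ₌₁..N PSᵢ },   R_ebw = 0.45

and the **energy concentration** is `ec = N / ebw`, where `N` is the number
of frequency bins in the 30–120 kHz analysis band. A whistle concentrates
its energy in a handful of bins (`ec` large); stationary noise and clicks
spread it (`ec` small). The pipeline is:

1. **Spectrogram** — Hanning window (3 ms), 80% overlap, FFT length equal
   to the window, power restricted to 30–120 kHz.
2. **Pre-whitening** — the background spectrum, averaged over frames whose
   level lies below an adaptive noise ceiling (95% level quantile + 2 dB),
   is divided out of every frame.
3. **Segmentation** — seeded hysteresis on the `ec` track: local maxima
   above `ec_on` seed segments, extended until `ec` falls below `ec_off`;
   both thresholds are exceedance quantiles of the background frames' `ec`
   distribution. Segments closer than 5 ms are merged; segments shorter
   than 10 ms or longer than 200 ms are removed.
4. **Features** — per element, the dominant-frequency contour and the
   standard parameter set (begin, length, fmean, fband, amean, and the
   t/f/a triples at the start, end, lowest- and highest-frequency points).

Detections are scored against references with the standard counts
(`Nref`, `Nauto`, `Ncorr` matched one-to-one by temporal overlap):

    correct = 100·Ncorr/Nauto    false positives = 100·(Nauto−Ncorr)/Nauto
    false negatives = 100·(Nref−Ncorr)/Nref

## Worked example

Generate an 8-second synthetic recording (5 syllables at 20 dB SNR among
10 broadband clicks), detect, and score against the ground truth:

```sh
$ usvdetect synth demo.wav --duration-s 8 --n-syllables 5 --snr-db 20 --n-clicks 10 --seed 11
5 syllables, 10 clicks -> demo.wav
$ usvdetect detect demo.wav -o demo_out
5 elements
$ usvdetect evaluate demo_out/demo_elements.xml demo.truth.csv -o demo_report.csv
correct 100.0%  false positives 0.0%  false negatives 0.0%
```

The element table (`demo_out/demo_elements.csv`) holds one row per
detected syllable:

```
 begin  length   fmean     fband   amean
1.7889  0.0804 75788.6 59666.700 25.0649
2.9223  0.0264 68340.9   333.333 25.2504
3.1383  0.0792 78320.7   333.333 25.7507
5.3271  0.0288 61923.6 18000.000 24.8836
5.7879  0.0384 57963.5 16333.300 24.8540
```

`begin`/`length` are in seconds, frequencies in Hz, amplitudes in dB. The
second and third rows are constant-frequency whistles (`fband` of a single
bin step); the others are frequency-modulated. All five detections overlap
their true intervals and none of the ten clicks triggered a detection.
The same run also writes element metadata as XML and a JSON manifest
recording every resolved parameter, so a run can be reproduced exactly.

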