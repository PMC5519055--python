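"""Energy-bandwidth statistic, thresholds, hysteresis, corrections, pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from usvdetect import (
    EcTrack,
    IntervalSet,
    PowerSpectrogram,
    Recording,
    Segment,
    SegmentationConfig,
    SynthSpec,
    apply_time_corrections,
    compute_ebw,
    compute_ec_track,
    compute_thresholds,
    detect_segments,
    detect_usvs,
    generate_recording,
    match_elements,
)
from usvdetect.errors import ConfigError, EstimationError


def ebw_oracle(spectrum, r):
    """Independent sort-and-scan reference for the energy bandwidth."""
    vals = sorted(spectrum, reverse=True)
    acc = 0.0
    for v in vals:
        acc += v
    total = acc
    if not total > 0.0:
        return len(vals)
    acc = 0.0
    for k, v in enumerate(vals, start=1):
        acc += v
        if acc >= r * total:
            return k
    return len(vals)


def make_track(ec, ec_on, ec_off, hop_s=1e-3, n_bins=100):
    ec = np.asarray(ec, dtype=np.float64)
    return EcTrack(
        ebw=np.maximum((n_bins / np.maximum(ec, 1e-9)).round(), 1).astype(int),
        ec=ec,
        ec_on=float(ec_on),
        ec_off=float(ec_off),
        frame_times_s=np.arange(ec.size) * hop_s,
        hop_s=hop_s,
        n_bins=n_bins,
    )


def seg(start_s, end_s, hop_s=1e-3):
    return Segment(
        start_s=start_s,
        end_s=end_s,
        first_frame=int(round(start_s / hop_s)),
        last_frame=max(int(round(end_s / hop_s)) - 1, int(round(start_s / hop_s))),
        peak_ec=10.0,
    )


class TestComputeEbw:
    def test_single_loaded_bin_gives_one(self):
        spectrum = np.zeros(64)
        spectrum[17] = 5.0
        for r in (0.1, 0.45, 0.9):
            assert compute_ebw(spectrum, r) == 1

    def test_flat_ten_bins_at_half_gives_five(self):
        assert compute_ebw(np.ones(10), 0.5) == 5

    def test_all_zero_frame_returns_n_bins(self):
        assert compute_ebw(np.zeros(37), 0.45) == 37

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = rng.integers(2, 256)
            spectrum = rng.exponential(1.0, n)
            if rng.random() < 0.5:  # sparsify
                spectrum[rng.random(n) < 0.8] = 0.0
            r = rng.uniform(0.3, 0.6)
            assert compute_ebw(spectrum, r) == ebw_oracle(spectrum, r)

    @given(seed=st.integers(0, 10_000), r1=st.floats(0.05, 0.95), r2=st.floats(0.05, 0.95))
    def test_monotone_in_energy_fraction(self, seed, r1, r2):
        rng = np.random.default_rng(seed)
        spectrum = rng.exponential(1.0, 64)
        lo, hi = sorted((r1, r2))
        assert compute_ebw(spectrum, lo) <= compute_ebw(spectrum, hi)

    @given(seed=st.integers(0, 10_000), scale=st.floats(1e-6, 1e6))
    def test_invariant_to_positive_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        spectrum = rng.exponential(1.0, 48)
        assert compute_ebw(spectrum, 0.45) == compute_ebw(spectrum * scale, 0.45)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_ebw(np.array([]), 0.45)
        with pytest.raises(ConfigError):
            compute_ebw(np.ones(4), 1.5)


class TestEcTrackAndThresholds:
    @staticmethod
    def _ps(power):
        power = np.asarray(power, dtype=np.float64)
        return PowerSpectrogram(
            power=power,
            frame_times_s=np.arange(power.shape[0]) * 6e-4,
            bin_freqs_hz=30_000 + 333.0 * np.arange(power.shape[1]),
            hop_s=6e-4,
            window_s=3e-3,
        )

    def test_identical_flat_frames_give_constant_ec(self):
        track = compute_ec_track(self._ps(np.ones((30, 20))))
        assert np.all(track.ec == track.ec[0])

    def test_narrowband_frame_has_strict_maximum_ec(self):
        power = np.ones((30, 20))
        power[7] = 0.0
        power[7, 3] = 50.0
        track = compute_ec_track(self._ps(power))
        assert track.ec[7] > np.max(np.delete(track.ec, 7))

    def test_track_composes_per_frame_ebw(self):
        rng = np.random.default_rng(29)
        power = rng.exponential(1.0, size=(40, 32))
        cfg = SegmentationConfig()
        track = compute_ec_track(self._ps(power), cfg)
        for t in range(40):
            assert track.ebw[t] == compute_ebw(power[t], cfg.r_ebw)
        np.testing.assert_allclose(track.ec * track.ebw, 32.0)

    def test_exceedance_quantiles_on_1_to_100(self):
        """ec values 1..100: onset at the 90th percentile (90.1), offset at the 10th (10.9)."""
        cfg = SegmentationConfig(on_quantile=0.10, off_quantile=0.90)
        ec_on, ec_off = compute_thresholds(np.arange(1.0, 101.0), cfg)
        assert ec_on == pytest.approx(90.1)
        assert ec_off == pytest.approx(10.9)

    def test_literal_mode_inverts_threshold_order(self):
        cfg = SegmentationConfig(literal_quantile_mode=True)
        ec_on, ec_off = compute_thresholds(np.arange(1.0, 101.0), cfg)
        assert ec_on == pytest.approx(10.9)
        assert ec_off == pytest.approx(90.1)
        assert ec_on < ec_off

    def test_constant_track_gives_equal_thresholds(self):
        ec_on, ec_off = compute_thresholds(np.full(50, 4.2), SegmentationConfig())
        assert ec_on == ec_off == pytest.approx(4.2)

    @given(seed=st.integers(0, 10_000))
    def test_default_mode_orders_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        ec = rng.uniform(1.0, 100.0, size=200)
        ec_on, ec_off = compute_thresholds(ec, SegmentationConfig())
        assert ec_on >= ec_off

    def test_too_few_frames_raise(self):
        with pytest.raises(EstimationError):
            compute_thresholds(np.ones(10), SegmentationConfig())


class TestDetectSegments:
    def test_hand_traced_two_bump_track(self):
        track = make_track([1, 1, 5, 9, 5, 1, 1, 1, 6, 9, 6, 1], ec_on=8, ec_off=4)
        segs = detect_segments(track)
        assert [(s.first_frame, s.last_frame) for s in segs] == [(2, 4), (8, 10)]
        assert segs[0].start_s == pytest.approx(0.002)
        assert segs[0].end_s == pytest.approx(0.005)  # last frame time + hop

    def test_constant_track_yields_nothing(self):
        assert detect_segments(make_track([5.0] * 30, ec_on=5, ec_off=5)) == []

    def test_postconditions_on_random_tracks(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ec = rng.uniform(0.0, 10.0, size=120)
            track = make_track(ec, ec_on=7.0, ec_off=3.0)
            segs = detect_segments(track)
            for a, b in zip(segs, segs[1:]):
                assert a.last_frame < b.first_frame
            for s in segs:
                inside = ec[s.first_frame: s.last_frame + 1]
                assert inside.max() > 7.0
                assert np.all(inside >= 3.0)
                if s.first_frame > 0:
                    assert ec[s.first_frame - 1] < 3.0
                if s.last_frame < ec.size - 1:
                    assert ec[s.last_frame + 1] < 3.0

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(37)
        ec = rng.uniform(0.0, 10.0, size=200)
        base = detect_segments(make_track(ec, 7.0, 3.0))
        warped = detect_segments(make_track(np.exp(ec / 2.0), np.exp(3.5), np.exp(1.5)))
        assert [(s.first_frame, s.last_frame) for s in base] == [
            (s.first_frame, s.last_frame) for s in warped
        ]


class TestTimeCorrections:
    def test_small_gap_merges_into_one(self):
        segs = [seg(0.000, 0.020), seg(0.024, 0.044)]
        out = apply_time_corrections(segs, SegmentationConfig())
        assert len(out) == 1
        assert out[0].start_s == pytest.approx(0.0)
        assert out[0].end_s == pytest.approx(0.044)

    def test_short_segment_removed(self):
        out = apply_time_corrections([seg(0.0, 0.003)], SegmentationConfig())
        assert out == []

    def test_chain_of_five_merges_then_survives(self):
        """Five 8 ms segments, 4 ms apart: transitive merge to one 56 ms segment."""
        segs = [seg(0.012 * k, 0.012 * k + 0.008) for k in range(5)]
        out = apply_time_corrections(segs, SegmentationConfig())
        assert len(out) == 1
        assert out[0].duration_s == pytest.approx(0.056)

    def test_overlong_segment_removed(self):
        out = apply_time_corrections([seg(0.0, 0.5)], SegmentationConfig())
        assert out == []

    def test_boundary_equal_gap_is_not_merged(self):
        segs = [seg(0.000, 0.020), seg(0.025, 0.045)]
        out = apply_time_corrections(segs, SegmentationConfig())
        assert len(out) == 2

    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(0, 25),
        mindist=st.floats(1.0, 10.0),
        mindur=st.floats(2.0, 15.0),
    )
    def test_fuzzed_outputs_respect_all_rules(self, seed, n, mindist, mindur):
        rng = np.random.default_rng(seed)
        cfg = SegmentationConfig(
            t_mindist_ms=mindist, t_mindur_ms=mindur, t_maxdur_ms=mindur + 150.0
        )
        t, segs = 0.0, []
        for _ in range(n):
            t += rng.uniform(0.0005, 0.05)
            dur = rng.uniform(0.001, 0.25)
            segs.append(seg(t, t + dur))
            t += dur
        out = apply_time_corrections(segs, cfg)
        for s in out:
            assert cfg.t_mindur_ms / 1000 <= s.duration_s <= cfg.t_maxdur_ms / 1000
        for a, b in zip(out, out[1:]):
            assert b.start_s - a.end_s >= cfg.t_mindist_ms / 1000
        # transitivity: a second pass is a no-op
        again = apply_time_corrections(out, cfg)
        assert [(s.start_s, s.end_s) for s in again] == [(s.start_s, s.end_s) for s in out]


class TestDetectUsvs:
    def test_silence_yields_no_elements(self):
        rec = Recording(samples=np.zeros(600_000), sample_rate=300_000)
        assert detect_usvs(rec) == []

    def test_pure_noise_yields_no_elements(self):
        rng = np.random.default_rng(41)
        rec = Recording(samples=rng.normal(0, 0.01, 900_000).clip(-1, 1), sample_rate=300_000)
        assert detect_usvs(rec) == []

    def test_twenty_chirps_are_all_recovered(self):
        spec = SynthSpec(
            duration_s=20.0,
            n_syllables=20,
            syllable_dur_range_ms=(50.0, 50.0),
            freq_range_hz=(40_000.0, 80_000.0),
            contour_types=("linear_chirp",),
            snr_db=20.0,
            min_gap_ms=30.0,
            seed=8,
        )
        res = generate_recording(spec)
        elements = detect_usvs(res.recording)
        assert len(elements) == 20
        auto = IntervalSet.from_elements(elements)
        n_corr, _ = match_elements(auto, res.truth)
        assert n_corr == 20

    def test_elements_sorted_by_start(self, small_synth):
        elements = detect_usvs(small_synth.recording)
        begins = [e.begin_s for e in elements]
        assert begins == sorted(begins)
        assert len(elements) == 10


def test_config_validation():
    with pytest.raises(ConfigError):
        SegmentationConfig(r_ebw=0.0)
    with pytest.raises(ConfigError):
        SegmentationConfig(t_mindur_ms=300.0)
    with pytest.raises(ConfigError):
        SegmentationConfig(threshold_reference="median")
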