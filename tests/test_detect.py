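"""Modulus-maxima peak detector: threshold, extraction, pairing, localization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ppgwave as pw
from ppgwave.detect import ModulusMaximum, _chord_zero_crossing

FS = 100.0


def _mm(index, value, level=4):
    return ModulusMaximum(index=index, level=level, value=value)


class TestComputeThreshold:
    def test_constant_series_gives_half_the_value(self):
        assert pw.compute_threshold(np.full(1024, 3.0), t=256) == pytest.approx(1.5)

    def test_ramp_segments(self):
        # 1..1024 in 4 segments of 256: maxima (256, 512, 768, 1024), mean 640
        m = np.arange(1, 1025, dtype=float)
        assert pw.compute_threshold(m, t=256, factor=0.5) == pytest.approx(320.0)

    def test_canonical_window_splits_into_four_segments(self):
        assert 1024 // 256 == 4
        # trailing remainder shorter than one segment is ignored
        m = np.concatenate([np.full(1024, 2.0), np.full(100, 1000.0)])
        assert pw.compute_threshold(m, t=256) == pytest.approx(1.0)

    def test_series_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            pw.compute_threshold(np.ones(100), t=256)


class TestExtractModulusMaxima:
    def test_zero_series_has_no_maxima(self):
        with pytest.raises(ValueError):
            pw.extract_modulus_maxima(np.zeros(64), 4, 0.0)

    def test_single_triangle_peak(self):
        w = np.zeros(64)
        w[28:33] = [0.5, 1.0, 2.0, 1.0, 0.5]
        out = pw.extract_modulus_maxima(w, 4, 1.0)
        assert len(out) == 1
        assert out[0].index == 30 and out[0].value == 2.0 and out[0].sign == 1

    @given(seed=st.integers(min_value=0, max_value=2**16),
           eps=st.floats(min_value=0.05, max_value=2.0))
    def test_matches_neighbor_scan_oracle(self, seed, eps):
        w = np.random.default_rng(seed).normal(size=256)
        got = pw.extract_modulus_maxima(w, 5, eps)
        expected = []
        for i in range(1, 255):
            if abs(w[i]) > abs(w[i - 1]) and abs(w[i]) > abs(w[i + 1]) and abs(w[i]) > eps:
                expected.append((i, w[i]))
        assert [(m.index, m.value) for m in got] == expected


class TestCrossLevelRetain:
    def test_identical_lists_are_unchanged(self):
        ms = [_mm(10, 1.0), _mm(50, -2.0), _mm(90, 1.5)]
        assert pw.cross_level_retain(ms, list(ms), window=0) == ms

    def test_distant_partner_not_matched(self):
        a = [_mm(100, 1.0)]
        b = [_mm(140, 1.0, level=5)]
        assert pw.cross_level_retain(a, b, window=16) == []

    def test_opposite_sign_partner_not_matched(self):
        a = [_mm(100, 1.0)]
        b = [_mm(102, -1.0, level=5)]
        assert pw.cross_level_retain(a, b, window=16) == []

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_matches_bipartite_nearest_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(0, 20, size=2)
        a = sorted(rng.choice(500, size=na, replace=False).tolist())
        b = sorted(rng.choice(500, size=nb, replace=False).tolist())
        ma = [_mm(i, float(rng.choice([-1, 1])) * float(rng.uniform(0.5, 2))) for i in a]
        mb = [_mm(i, float(rng.choice([-1, 1])) * float(rng.uniform(0.5, 2)), 5) for i in b]
        window = int(rng.integers(0, 40))
        got = pw.cross_level_retain(ma, mb, window)
        # Oracle: walk ma in order; nearest unconsumed same-sign partner wins.
        available = list(mb)
        expected = []
        for m in ma:
            candidates = [x for x in available
                          if x.sign == m.sign and abs(x.index - m.index) <= window]
            if candidates:
                best = min(candidates, key=lambda x: abs(x.index - m.index))
                available.remove(best)
                expected.append(m)
        assert got == expected


class TestSelectPairs:
    def test_isolated_maximum_is_dropped(self):
        out = pw.select_pairs([_mm(100, 1.0)], pairing_window=30, refractory=20)
        assert out == []

    def test_refractory_keeps_the_larger_pair(self):
        ms = [_mm(100, 1.0), _mm(110, -1.0), _mm(112, 3.0), _mm(120, -3.0)]
        out = pw.select_pairs(ms, pairing_window=30, refractory=20)
        assert len(out) == 1
        assert out[0].pos.index == 112 and out[0].amplitude == pytest.approx(6.0)

    def test_negative_then_positive_polarity_accepted(self):
        ms = [_mm(100, -1.0), _mm(110, 1.0)]
        out = pw.select_pairs(ms, pairing_window=30, refractory=20)
        assert len(out) == 1
        assert out[0].neg.index == 100 and out[0].pos.index == 110

    def test_zero_crossing_lies_between_the_extrema(self):
        a, b = _mm(100, 2.0), _mm(120, -1.0)
        zc = _chord_zero_crossing(a, b)
        assert 100 <= zc <= 120
        # chord root: 100 + 2/3 * 20
        assert zc == 113

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_matches_independent_rule_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 12))
        idx = np.sort(rng.choice(600, size=n, replace=False))
        ms = [_mm(int(i), float(rng.choice([-1, 1])) * float(rng.uniform(0.5, 3))) for i in idx]
        window = int(rng.integers(5, 60))
        refractory = int(rng.integers(5, 60))
        got = pw.select_pairs(ms, pairing_window=window, refractory=refractory)

        # Oracle: recursive left-to-right pairing of adjacent opposite-sign
        # maxima, then sequential refractory resolution by amplitude.
        def form(rest):
            if len(rest) < 2:
                return []
            a, b = rest[0], rest[1]
            if a.sign != b.sign and b.index - a.index <= window:
                return [(a, b)] + form(rest[2:])
            return form(rest[1:])

        expected = []
        for a, b in form(ms):
            zc = _chord_zero_crossing(a, b)
            amp = abs(a.value) + abs(b.value)
            if expected and zc - expected[-1][0] < refractory:
                if amp > expected[-1][1]:
                    expected[-1] = (zc, amp)
            else:
                expected.append((zc, amp))
        assert [(p.zero_crossing, p.amplitude) for p in got] == [
            (zc, pytest.approx(amp)) for zc, amp in expected
        ]


class TestLocatePeaks:
    def test_gaussian_pulse_refines_to_the_apex(self):
        t = np.arange(1024)
        x = np.exp(-0.5 * ((t - 500) / 6.0) ** 2)
        sig = pw.Signal(x, FS)
        pair = pw.MaximumPair(pos=_mm(492, 1.0), neg=_mm(505, -1.0),
                              zero_crossing=498, amplitude=2.0)
        peaks = pw.locate_peaks([pair], sig, refine_window_ms=100.0)
        assert list(peaks.indices) == [500]

    def test_two_pairs_collapsing_to_one_apex_emit_one_peak(self):
        t = np.arange(1024)
        x = np.exp(-0.5 * ((t - 500) / 6.0) ** 2)
        sig = pw.Signal(x, FS)
        pairs = [
            pw.MaximumPair(pos=_mm(492, 1.0), neg=_mm(505, -1.0), zero_crossing=498, amplitude=2.0),
            pw.MaximumPair(pos=_mm(494, 1.0), neg=_mm(507, -1.0), zero_crossing=503, amplitude=2.0),
        ]
        peaks = pw.locate_peaks(pairs, sig, refine_window_ms=100.0)
        assert list(peaks.indices) == [500]


class TestDetectPeaks:
    def test_clean_record_detected_without_error(self, clean_record):
        peaks = pw.detect_peaks(clean_record.raw)
        result = pw.evaluate_detection(peaks, clean_record.peaks, tolerance_ms=50.0)
        assert result.FP == 0 and result.FN == 0

    def test_amplitude_scale_invariance_of_the_indices(self, clean_record):
        base = pw.detect_peaks(clean_record.raw).indices
        for alpha in (0.1, 1.0, 10.0):
            scaled = pw.Signal(alpha * clean_record.raw.samples, FS)
            assert np.array_equal(pw.detect_peaks(scaled).indices, base)

    def test_dc_offset_invariance_of_the_indices(self, clean_record):
        base = pw.detect_peaks(clean_record.raw).indices
        shifted = pw.Signal(clean_record.raw.samples + 0.5, FS)
        assert np.array_equal(pw.detect_peaks(shifted).indices, base)

    def test_output_respects_the_refractory(self):
        rec = pw.generate_ppg(pw.regime_config("walking", duration=60.0, seed=3))
        cfg = pw.DetectorConfig()
        peaks = pw.detect_peaks(rec.raw, cfg)
        min_gap = cfg.refractory_ms / 1000.0 * FS
        assert np.all(np.diff(peaks.indices) >= min_gap)

    def test_determinism(self, clean_record):
        a = pw.detect_peaks(clean_record.raw)
        b = pw.detect_peaks(clean_record.raw)
        assert np.array_equal(a.indices, b.indices)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            pw.detect_peaks(pw.Signal(np.zeros(100), FS))

    def test_correction_never_hurts_on_drifting_records(self):
        """Detection error with baseline correction <= without, in ensemble mean."""
        raw_err, cor_err = [], []
        for seed in range(20):
            rec = pw.generate_ppg(pw.regime_config("walking", duration=60.0, seed=seed))
            raw_err.append(pw.evaluate_detection(pw.detect_peaks(rec.raw), rec.peaks).error_percent)
            corrected, _ = pw.remove_baseline(rec.raw)
            cor_err.append(pw.evaluate_detection(pw.detect_peaks(corrected), rec.peaks).error_percent)
        assert np.mean(cor_err) <= np.mean(raw_err)
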