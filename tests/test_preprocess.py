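import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtshape.errors import DegenerateSeriesError
from qtshape.io_formats import EcgRecord
from qtshape.preprocess import (
    Beat,
    ExclusionReason,
    FilterSpec,
    apply_rr_exclusions,
    beat_window_length,
    extract_beats,
    lowpass_filter,
    normalize_beats,
    znormalize,
)

FS = 250.0
L = beat_window_length(FS)  # 400


def make_record(r_peaks, n_samples=3000, seed=0):
    gen = np.random.default_rng(seed)
    sig = gen.normal(scale=0.1, size=n_samples)
    return EcgRecord("test", sig[None, :], ["ch0"], FS, np.asarray(r_peaks))


class TestLowpassFilter:
    def test_dc_passthrough(self):
        x = np.full(2000, 0.8)
        np.testing.assert_allclose(lowpass_filter(x, FS), x, atol=1e-6)

    def test_passband_tone_retained(self):
        t = np.arange(0, 10, 1 / FS)
        out = lowpass_filter(np.sin(2 * np.pi * 20 * t), FS)
        assert np.abs(out[200:-200]).max() >= 10 ** (-3 / 20)

    def test_stopband_tone_suppressed(self):
        t = np.arange(0, 10, 1 / FS)
        out = lowpass_filter(np.sin(2 * np.pi * 80 * t), FS)
        assert np.abs(out[200:-200]).max() <= 10 ** (-40 / 20)

    def test_length_preserved(self, rng):
        x = rng.normal(size=1234)
        assert lowpass_filter(x, FS).shape == x.shape

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            lowpass_filter(np.zeros(100), 100.0, FilterSpec())

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(passband_edge_hz=60.0, stopband_edge_hz=50.0)


class TestExtractBeats:
    def test_short_window_padded(self):
        rec = make_record([200, 500, 750, 1100])
        beats = extract_beats(rec)
        b = beats[1]  # r=500, next=750 -> window [470, 730), 260 samples
        assert b.samples.shape == (L,)
        sig = rec.signal[0]
        np.testing.assert_array_equal(b.samples[:260], sig[470:730])
        pad = (sig[470] + sig[729]) / 2.0
        np.testing.assert_allclose(b.samples[260:], pad)

    def test_long_window_truncated(self):
        rec = make_record([200, 500, 1000, 1400])
        beats = extract_beats(rec)
        b = beats[1]  # window [470, 980) = 510 samples -> first 400 kept
        sig = rec.signal[0]
        np.testing.assert_array_equal(b.samples, sig[470:870])

    def test_three_peaks_one_interior(self):
        rec = make_record([300, 550, 800])
        beats = extract_beats(rec)
        assert len(beats) == 3
        assert [b.excluded for b in beats] == [True, False, True]
        assert beats[0].exclusion_reason is ExclusionReason.FIRST_OR_LAST
        assert beats[2].exclusion_reason is ExclusionReason.FIRST_OR_LAST

    def test_rr_fields_in_ms(self):
        rec = make_record([200, 500, 750, 1100])
        b = extract_beats(rec)[1]
        assert b.rr_prev_ms == pytest.approx(300 / FS * 1000)
        assert b.rr_next_ms == pytest.approx(250 / FS * 1000)

    def test_window_before_record_start_excluded(self):
        rec = make_record([10, 400, 700, 1000])
        beats = extract_beats(rec)
        # beat 0 is a boundary beat anyway; craft an interior one too close
        rec2 = make_record([5, 20, 400, 700])
        b = extract_beats(rec2)[1]  # start = 20 - 30 < 0
        assert b.excluded and b.exclusion_reason is ExclusionReason.OUT_OF_BOUNDS
        assert not beats[1].excluded

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError, match="3 R peaks"):
            extract_beats(make_record([100, 600]))

    def test_count_identity(self):
        rec = make_record([200, 500, 750, 1000, 1300, 1700])
        beats = apply_rr_exclusions(extract_beats(rec))
        interior = beats[1:-1]
        assert sum(b.excluded for b in interior) + sum(
            not b.excluded for b in interior
        ) == len(rec.r_peaks) - 2
        assert all(b.samples.shape == (L,) for b in beats)


def beat_with(rr_prev, rr_next):
    return Beat(beat_index=1, r_peak=1000, samples=np.zeros(L),
                rr_prev_ms=rr_prev, rr_next_ms=rr_next)


class TestRrExclusions:
    @pytest.mark.parametrize(
        "rr_prev,rr_next,reason",
        [
            (250.0, 1000.0, ExclusionReason.RR_SHORT),
            (2100.0, 1000.0, ExclusionReason.RR_LONG),
            (1000.0, 1600.0, ExclusionReason.RR_RATIO),  # ratio 0.625 < 0.70
            (1400.0, 1000.0, ExclusionReason.RR_RATIO),  # ratio 1.40 > 1.30
        ],
    )
    def test_excluded(self, rr_prev, rr_next, reason):
        b = apply_rr_exclusions([beat_with(rr_prev, rr_next)])[0]
        assert b.excluded and b.exclusion_reason is reason

    @pytest.mark.parametrize(
        "rr_prev,rr_next",
        [
            (1000.0, 1000.0),
            (300.0, 300.0),  # boundary values retained (strict inequalities)
            (2000.0, 2000.0),
            (700.0, 1000.0),  # ratio exactly 0.70
            (1300.0, 1000.0),  # ratio exactly 1.30
        ],
    )
    def test_retained(self, rr_prev, rr_next):
        b = apply_rr_exclusions([beat_with(rr_prev, rr_next)])[0]
        assert not b.excluded

    def test_already_excluded_untouched(self):
        b = beat_with(250.0, 1000.0)
        b.exclude(ExclusionReason.FIRST_OR_LAST)
        apply_rr_exclusions([b])
        assert b.exclusion_reason is ExclusionReason.FIRST_OR_LAST


class TestZnormalize:
    def test_known_values(self):
        nb = znormalize(np.array([1.0, 2.0, 3.0]))
        assert nb.mu == pytest.approx(2.0)
        assert nb.sigma == pytest.approx(np.sqrt(2.0 / 3.0))
        np.testing.assert_allclose(nb.z, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_moments(self, rng):
        nb = znormalize(rng.normal(2.0, 3.0, size=100))
        assert abs(nb.z.mean()) < 1e-9
        assert abs(nb.z.std() - 1.0) < 1e-9

    def test_idempotent(self, rng):
        z = znormalize(rng.normal(size=50)).z
        np.testing.assert_allclose(znormalize(z).z, z, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            znormalize(np.array([5.0, 5.0, 5.0]))

    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
        st.integers(min_value=0, max_value=2**32 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=30)
        np.testing.assert_allclose(
            znormalize(a * x + b).z, znormalize(x).z, atol=1e-9
        )


class TestNormalizeBeats:
    def test_degenerate_beat_flagged(self):
        good = beat_with(1000.0, 1000.0)
        good.samples = np.sin(np.linspace(0, 6, L))
        flat = Beat(beat_index=2, r_peak=2000, samples=np.zeros(L),
                    rr_prev_ms=1000.0, rr_next_ms=1000.0)
        X, idx = normalize_beats([good, flat])
        assert X.shape == (1, L)
        assert idx.tolist() == [0]
        assert flat.excluded and flat.exclusion_reason is ExclusionReason.DEGENERATE
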