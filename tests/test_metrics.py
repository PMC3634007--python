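"""Metric definitions, filter behaviour and their algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gravsep.errors import InvalidFilterError, TooShortError
from gravsep.metrics import (
    FilterSpec,
    apply_butterworth,
    bfen,
    compute_metric,
    enmo,
    euclidean_norm,
    hfen,
    hfen_plus,
    lfen,
)


def butterworth_gain(f_hz, cutoff_hz, order=4, kind="low"):
    """Analytic magnitude response of an analog Butterworth prototype."""
    ratio = f_hz / cutoff_hz if kind == "low" else cutoff_hz / f_hz
    return 1.0 / np.sqrt(1.0 + ratio ** (2 * order))


def steady_amplitude(values, fs, skip_s=60.0):
    """Amplitude of a steady-state sinusoid from its RMS in a middle window.

    A middle window avoids the start-up transient of a causal pass and
    both edge transients of a forward-backward pass.
    """
    n = len(values)
    mid = values[int(skip_s * fs) : n - int(skip_s * fs)]
    return np.sqrt(2.0) * np.std(mid)


class TestEuclideanNorm:
    @pytest.mark.parametrize(
        "vector, expected",
        [((0, 0, 1), 1.0), ((0.6, 0, 0.8), 1.0), ((0, 0, 2), 2.0)],
    )
    def test_point_values(self, make_recording, vector, expected):
        series = euclidean_norm(make_recording([vector]))
        assert series.values[0] == pytest.approx(expected, abs=1e-15)

    def test_static_tilt_reads_one_g(self, static_recording):
        angle = np.deg2rad(33.0)
        rec = static_recording(vector=(np.cos(angle), 0.0, np.sin(angle)))
        assert np.allclose(euclidean_norm(rec).values, 1.0, atol=1e-12)

    def test_rotation_invariance(self, make_recording, rng):
        data = rng.normal(0, 0.5, size=(500, 3))
        rotation = Rotation.random(random_state=7).as_matrix()
        a = euclidean_norm(make_recording(data)).values
        b = euclidean_norm(make_recording(data @ rotation.T)).values
        assert np.allclose(a, b, atol=1e-12)


class TestEnmo:
    def test_unit_gravity_is_zero(self, make_recording):
        assert enmo(make_recording([(0, 0, 1)])).values[0] == pytest.approx(0.0, abs=1e-15)

    def test_truncation(self, make_recording):
        rec = make_recording([(0, 0, 0.9)])
        assert enmo(rec, truncate=True).values[0] == 0.0
        assert enmo(rec, truncate=False).values[0] == pytest.approx(-0.1)

    def test_equals_en_minus_one_exactly(self, make_recording, rng):
        rec = make_recording(rng.normal(0, 1, size=(200, 3)))
        np.testing.assert_array_equal(
            enmo(rec, truncate=False).values, euclidean_norm(rec).values - 1.0
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=3, max_size=30))
    def test_truncation_monotonicity(self, values):
        from gravsep.recording import TriaxialRecording

        data = np.array(values[: 3 * (len(values) // 3)]).reshape(-1, 3)
        if len(data) == 0:
            return
        rec = TriaxialRecording(fs=80.0, data=data)
        clamped = enmo(rec, truncate=True).values
        free = enmo(rec, truncate=False).values
        assert np.all(clamped >= free)
        keep = free >= 0
        np.testing.assert_array_equal(clamped[keep], free[keep])


class TestButterworth:
    def test_dc_rejection_high_pass(self, static_recording):
        rec = static_recording(duration_s=180.0)
        for series in (hfen(rec, truncate=False), bfen(rec, truncate=False)):
            tail = series.values[int(120 * rec.fs) :]
            assert np.max(tail) < 1e-6

    def test_dc_rejection_zero_phase(self, static_recording):
        rec = static_recording(duration_s=180.0)
        series = hfen(rec, truncate=False, zero_phase=True)
        assert np.max(series.values[int(30 * rec.fs) : int(150 * rec.fs)]) < 1e-6

    @pytest.mark.parametrize("zero_phase, power", [(False, 1), (True, 2)])
    def test_lowpass_magnitude_matches_analytic_response(
        self, sinusoid_recording, zero_phase, power
    ):
        # causal single pass realises |H|; forward-backward realises |H|^2
        rec = sinusoid_recording(freq_hz=1.0, duration_s=240.0)
        spec = FilterSpec("low-pass", order=4, cutoff_low_hz=0.2)
        out = apply_butterworth(rec, spec, zero_phase=zero_phase)
        expected = butterworth_gain(1.0, 0.2, order=4, kind="low") ** power
        assert steady_amplitude(out.x, rec.fs, skip_s=80.0) == pytest.approx(
            expected, rel=0.02
        )

    def test_highpass_splits_band_power(self, make_recording):
        fs, dur = 80.0, 400.0
        t = np.arange(int(dur * fs)) / fs
        slow, fast = np.sin(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 2.0 * t)
        data = np.column_stack([slow + fast, np.zeros_like(t), np.zeros_like(t)])
        out = apply_butterworth(
            make_recording(data, fs=fs), FilterSpec("high-pass", cutoff_low_hz=0.2)
        )
        tail = out.x[int(200 * fs) :]
        spectrum = np.abs(np.fft.rfft(tail)) / (len(tail) / 2)
        freqs = np.fft.rfftfreq(len(tail), 1 / fs)
        amp_fast = spectrum[np.argmin(np.abs(freqs - 2.0))]
        amp_slow = spectrum[np.argmin(np.abs(freqs - 0.05))]
        assert amp_fast == pytest.approx(1.0, rel=0.01)
        assert amp_slow <= butterworth_gain(0.05, 0.2, kind="high") * 1.05

    def test_cutoff_above_nyquist_rejected(self, static_recording):
        rec = static_recording(fs=80.0)
        with pytest.raises(InvalidFilterError):
            apply_butterworth(rec, FilterSpec("low-pass", cutoff_low_hz=40.0))

    def test_too_short_for_zero_phase(self, make_recording):
        rec = make_recording(np.zeros((10, 3)))
        with pytest.raises(TooShortError):
            apply_butterworth(rec, FilterSpec("high-pass", cutoff_low_hz=0.2), zero_phase=True)

    def test_band_pass_requires_ordered_cutoffs(self):
        with pytest.raises(InvalidFilterError):
            FilterSpec("band-pass", cutoff_low_hz=15.0, cutoff_high_hz=0.2)


class TestFilteredMetrics:
    def test_static_baselines(self, static_recording):
        rec = static_recording(vector=(0.6, 0.0, 0.8), duration_s=240.0)
        window = slice(int(120 * rec.fs), None)
        assert np.max(hfen(rec, truncate=False).values[window]) < 1e-6
        assert np.allclose(lfen(rec).values[window], 1.0, atol=1e-6)
        assert np.max(np.abs(hfen_plus(rec, truncate=False).values[window])) < 1e-6

    def test_lfen_ignores_fast_translation(self, sinusoid_recording):
        rec = sinusoid_recording(freq_hz=2.0, amplitude_g=0.3, axis=0, base=(0, 0, 1), duration_s=240.0)
        window = slice(int(120 * rec.fs), None)
        leak = 0.3 * butterworth_gain(2.0, 0.2, kind="low")
        assert np.allclose(lfen(rec).values[window], 1.0, atol=leak + 1e-6)

    def test_bfen_tracks_hfen_in_passband(self, sinusoid_recording):
        rec = sinusoid_recording(freq_hz=1.0, amplitude_g=0.5, duration_s=240.0)
        window = slice(int(120 * rec.fs), None)
        h = hfen(rec, truncate=False).values[window]
        b = bfen(rec, truncate=False).values[window]
        assert np.mean(b) == pytest.approx(np.mean(h), rel=0.05)

    def test_bfen_rejects_30hz_hfen_passes_it(self, sinusoid_recording):
        rec = sinusoid_recording(freq_hz=30.0, amplitude_g=0.5, duration_s=240.0, fs=80.0)
        tail = slice(int(120 * rec.fs), None)
        bound = 0.5 * butterworth_gain(30.0, 15.0, order=4, kind="low") * 1.1
        assert np.mean(bfen(rec, truncate=False).values[tail]) < bound
        # a fully passed 0.5 g sinusoid has mean |signal| = 2/pi * 0.5
        assert np.mean(hfen(rec, truncate=False).values[tail]) > 0.8 * (2 / np.pi) * 0.5

    def test_hfen_axis_permutation_invariance(self, make_recording, rng):
        data = rng.normal(0, 0.4, size=(2000, 3)) + [0, 0, 1]
        a = hfen(make_recording(data), truncate=False).values
        b = hfen(make_recording(data[:, [2, 0, 1]]), truncate=False).values
        assert np.allclose(a, b, atol=1e-12)

    def test_hfen_plus_defining_identity(self, make_recording, rng):
        data = rng.normal(0, 0.3, size=(4000, 3)) + [0, 0, 1]
        rec = make_recording(data)
        combined = hfen_plus(rec, truncate=False).values
        parts = hfen(rec, truncate=False).values + lfen(rec).values - 1.0
        assert np.allclose(combined, parts, atol=1e-12)

    def test_filter_linearity_scales_norm(self, sinusoid_recording):
        rec = sinusoid_recording(freq_hz=1.0, amplitude_g=0.2, duration_s=120.0)
        scaled = rec.with_data(rec.data * 2.5)
        a = hfen(rec, truncate=False).values
        b = hfen(scaled, truncate=False).values
        assert np.allclose(b, 2.5 * a, atol=1e-12)

    def test_dispatcher_matches_direct_calls(self, sinusoid_recording):
        rec = sinusoid_recording(freq_hz=1.0, amplitude_g=0.3, base=(0, 0, 1), duration_s=120.0)
        np.testing.assert_array_equal(
            compute_metric(rec, "HFEN+", truncate=False).values,
            hfen_plus(rec, truncate=False).values,
        )
        with pytest.raises(ValueError, match="unknown metric"):
            compute_metric(rec, "NOPE")
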