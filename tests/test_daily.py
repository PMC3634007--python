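"""Calibration, wear classification, epoching, imputation, inclusion."""

import numpy as np
import pytest

from gravsep.daily import (
    CLIPPING,
    NONWEAR,
    WEAR,
    CalibrationModel,
    calibrate_static,
    combine_flags,
    detect_clipping,
    detect_nonwear,
    epoch_average,
    impute_blocks,
    participant_summary,
)
from gravsep.errors import CalibrationError
from gravsep.metrics import MetricSeries, euclidean_norm
from gravsep.recording import TriaxialRecording


def orientations():
    """Six static unit orientations spanning both signs of each axis."""
    return np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    )


def static_recs(points, n=200, fs=80.0):
    return [
        TriaxialRecording(fs=fs, data=np.tile(p, (n, 1))) for p in points
    ]


class TestCalibration:
    def test_perfect_points_give_identity(self):
        model = calibrate_static(static_recs(orientations()))
        assert np.allclose(model.offset, 0.0, atol=1e-9)
        assert np.allclose(model.gain, 1.0, atol=1e-9)

    def test_offset_recovery(self):
        points = orientations()
        corrupted = points.copy()
        corrupted[:, 0] -= 0.05  # raw = true - offset so fit adds +0.05 back
        model = calibrate_static(static_recs(corrupted))
        assert model.offset[0] == pytest.approx(0.05, abs=1e-3)

    def test_gain_recovery(self):
        corrupted = orientations() / np.array([1.0, 1.0, 1.02])
        model = calibrate_static(static_recs(corrupted))
        assert model.gain[2] == pytest.approx(1.02, abs=2e-3)

    def test_insufficient_diversity_rejected(self):
        one_sided = np.abs(orientations())  # never negative on any axis
        with pytest.raises(CalibrationError, match="both signs"):
            calibrate_static(static_recs(one_sided))

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError, match="at least 6"):
            calibrate_static(static_recs(orientations()[:4]))

    def test_calibration_improves_static_identity(self):
        rng = np.random.default_rng(3)
        # distorted sensor: small offsets and gains, 12 random orientations
        offset_true = np.array([0.03, -0.02, 0.01])
        gain_true = np.array([1.01, 0.98, 1.02])
        raw_points = []
        for _ in range(12):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            raw_points.append((v - offset_true) / gain_true)
        fit_recs = static_recs(np.array(raw_points[:8]))
        model = calibrate_static(fit_recs, tolerance_g=0.01, min_component_g=0.05)
        held_out = static_recs(np.array(raw_points[8:]))
        for rec in held_out:
            before = abs(euclidean_norm(rec).values.mean() - 1)
            after = abs(euclidean_norm(model.apply(rec)).values.mean() - 1)
            assert after <= before + 1e-12


class TestClipping:
    def make_day(self, data, fs=10.0):
        return TriaxialRecording(fs=fs, data=data)

    def test_normal_gravity_not_flagged(self):
        n = int(30 * 60 * 10)
        rec = self.make_day(np.tile([0.0, 0.0, 1.0], (n, 1)))
        assert all(f == WEAR for f in detect_clipping(rec).flags)

    def test_saturated_block_flagged(self):
        fs = 10.0
        n = int(30 * 60 * fs)
        data = np.tile([0.0, 0.0, 1.0], (n, 1))
        block = slice(0, int(15 * 60 * fs))
        hit = np.zeros(n, dtype=bool)
        hit[block] = np.arange(n)[block] % 10 == 0  # 10% of first block at +6 g
        data[hit, 0] = 6.0
        flags = detect_clipping(rec := self.make_day(data, fs)).flags
        assert flags[0] == CLIPPING and flags[1] == WEAR

    def test_zero_saturated_samples_not_flagged(self):
        n = int(15 * 60 * 10)
        data = np.tile([0.0, 0.0, 5.93], (n, 1))  # just below 0.99 * 6 g
        assert detect_clipping(self.make_day(data)).flags[0] == WEAR


class TestNonwear:
    def build_day(self, segments, fs=10.0, seed=0):
        """segments: list of (minutes, kind) with kind in {static, active}."""
        rng = np.random.default_rng(seed)
        chunks = []
        for minutes, kind in segments:
            n = int(minutes * 60 * fs)
            t = np.arange(n) / fs
            base = np.tile([0.0, 0.0, 1.0], (n, 1))
            if kind == "active":
                # movement visible on two axes, as on a worn limb
                base[:, 0] += 0.14 * np.sin(2 * np.pi * 1.0 * t)  # ~100 mg SD
                base[:, 1] += 0.07 * np.sin(2 * np.pi * 1.3 * t)
                base += rng.normal(0, 0.0026, size=base.shape)
            elif kind == "noisy-static":
                base += rng.normal(0, 0.0026, size=base.shape)
            chunks.append(base)
        return TriaxialRecording(fs=fs, data=np.vstack(chunks))

    def test_static_gap_inside_active_day_flagged(self):
        rec = self.build_day([(60, "active"), (120, "static"), (60, "active")])
        flags = detect_nonwear(rec).flags
        # the 2 h static core (blocks 4-11) must be flagged
        assert all(f == NONWEAR for f in flags[5:11])
        assert flags[0] == WEAR and flags[-1] == WEAR

    def test_oscillating_day_stays_wear(self):
        rec = self.build_day([(120, "active")])
        assert all(f == WEAR for f in detect_nonwear(rec).flags)

    def test_sensor_noise_below_threshold_is_nonwear(self):
        rec = self.build_day([(120, "noisy-static")])
        assert all(f == NONWEAR for f in detect_nonwear(rec).flags)

    def test_short_recording_warns_all_wear(self):
        rec = self.build_day([(30, "static")])
        with pytest.warns(UserWarning, match="shorter"):
            flags = detect_nonwear(rec).flags
        assert all(f == WEAR for f in flags)

    def test_block_boundaries_snap_to_clock(self):
        base = self.build_day([(120, "active")])
        shifted = TriaxialRecording(fs=base.fs, data=base.data, start_time=300.0)
        f0 = detect_nonwear(base)
        f1 = detect_nonwear(shifted)
        assert f0.first_block == f1.first_block == 0

    def test_combine_precedence(self):
        from gravsep.daily import BlockFlagSeries

        a = BlockFlagSeries(flags=np.array([WEAR, NONWEAR, NONWEAR], dtype=object), first_block=0)
        b = BlockFlagSeries(flags=np.array([WEAR, WEAR, CLIPPING], dtype=object), first_block=0)
        merged = combine_flags(a, b)
        assert list(merged.flags) == [WEAR, NONWEAR, CLIPPING]


class TestEpochAverage:
    def series(self, values, fs=80.0, name="ENMO"):
        return MetricSeries(name, np.asarray(values, dtype=float), fs)

    def test_constant_five_minutes(self):
        epochs = epoch_average(self.series(np.full(5 * 60 * 80, 0.1)))
        assert epochs.n_epochs == 5
        assert np.allclose(epochs.values, 0.1)

    def test_partial_trailing_epoch_dropped(self):
        epochs = epoch_average(self.series(np.zeros(int(4.5 * 60 * 80))))
        assert epochs.n_epochs == 4

    def test_alternating_samples_average(self):
        values = np.tile([0.0, 0.2], 60 * 40)
        assert np.allclose(epoch_average(self.series(values)).values, 0.1)

    def test_non_integer_samples_per_epoch_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            epoch_average(self.series(np.zeros(100), fs=0.77))


class TestImputation:
    def stack(self, n_days=3, epochs_per_day=30, value=0.0):
        return np.full((n_days, epochs_per_day), value)

    def test_same_clock_average(self):
        stack = self.stack()
        stack[0, 15:30] = 0.030
        stack[2, 15:30] = 0.050
        stack[1, 15:30] = 123.0  # flagged day-2 block, value irrelevant
        flagged = np.zeros((3, 2), dtype=bool)
        flagged[1, 1] = True
        imputed, mask = impute_blocks(stack, flagged, "ENMO")
        assert np.allclose(imputed[1, 15:30], 0.040)
        assert mask[1, 15:30].all() and not mask[0].any()

    @pytest.mark.parametrize("metric, fill", [("ENMO", 0.0), ("HFEN+", 0.0), ("EN", 1.0)])
    def test_default_fill_when_flagged_everywhere(self, metric, fill):
        stack = self.stack(value=0.7)
        flagged = np.zeros((3, 2), dtype=bool)
        flagged[:, 0] = True  # first block missing on every day
        imputed, _ = impute_blocks(stack, flagged, metric)
        assert np.allclose(imputed[:, :15], fill)
        assert np.allclose(imputed[:, 15:], 0.7)

    def test_no_flags_is_identity(self):
        stack = self.stack(value=0.3)
        imputed, mask = impute_blocks(stack, np.zeros((3, 2), dtype=bool), "ENMO")
        np.testing.assert_array_equal(imputed, stack)
        assert not mask.any()

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 0.1, size=(4, 60))
        flagged = rng.uniform(size=(4, 4)) < 0.3
        once, _ = impute_blocks(stack, flagged, "ENMO")
        twice, _ = impute_blocks(once, flagged, "ENMO")
        np.testing.assert_array_equal(once, twice)


class TestParticipantSummary:
    def test_full_wear_included(self):
        stack = np.full((7, 96 * 15), 0.05)
        flagged = np.zeros((7, 96), dtype=bool)
        summary = participant_summary(stack, flagged, "ENMO")
        assert summary.included and summary.wear_fraction == 1.0
        assert summary.mean_g == pytest.approx(0.05)

    @pytest.mark.parametrize("wear_frac, included", [(0.4, False), (0.5, False), (0.6, True)])
    def test_wear_threshold_is_strict(self, wear_frac, included):
        n_blocks = 10
        stack = np.full((1, n_blocks * 15), 0.05)
        flagged = np.zeros((1, n_blocks), dtype=bool)
        flagged[0, : int(round((1 - wear_frac) * n_blocks))] = True
        summary = participant_summary(stack, flagged, "ENMO")
        assert summary.included is included
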