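"""Filtering, Cardan decomposition, segmentation, resampling, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinemid import (FilterSpec, ParameterError, SchemaError, SegmentationError,
                     assemble_features, cardan_angles, compose_cardan,
                     disassemble_features, fit_normalizer, apply_normalizer,
                     invert_normalizer, lowpass_zero_phase, segment_kick,
                     time_normalize)
from kinemid.preprocess import N_VARIABLES, pass_correction_factor

FS = 333.0


def sinusoid(freq, fs=FS, seconds=3.0):
    t = np.arange(int(seconds * fs)) / fs
    return t, np.sin(2 * np.pi * freq * t)


def analytic_two_pass_gain(freq, spec: FilterSpec) -> float:
    """|H(f)|^2 of the dual-pass filter from the analytic Butterworth
    magnitude of the per-pass design (analog approximation, valid well
    below Nyquist)."""
    n = spec.order // 2 if spec.convention == "effective" else spec.order
    cutoff = spec.cutoff_hz / pass_correction_factor(n) if spec.convention == "effective" else spec.cutoff_hz
    per_pass_sq = 1.0 / (1.0 + (freq / cutoff) ** (2 * n))
    return per_pass_sq  # magnitude-squared of one pass = gain of both passes


class TestLowpassZeroPhase:
    def test_dc_gain_unity(self):
        x = np.full(500, 17.0)
        y = lowpass_zero_phase(x, FS)
        assert np.allclose(y, 17.0, atol=1e-9)

    def test_passband_gain_matches_analytic_response_with_zero_lag(self):
        spec = FilterSpec()
        t, x = sinusoid(1.0)
        y = lowpass_zero_phase(x, FS, spec)
        # amplitude by projection on the quadrature pair over exactly one
        # interior period (333 samples at 1 Hz)
        sl = slice(333, 666)
        basis = np.stack([np.sin(2 * np.pi * 1.0 * t[sl]), np.cos(2 * np.pi * 1.0 * t[sl])])
        coef_y = 2 * basis @ y[sl] / len(t[sl])
        ratio = np.hypot(*coef_y)
        assert ratio == pytest.approx(analytic_two_pass_gain(1.0, spec), rel=0.01)
        lag = np.argmax(np.correlate(y[sl], x[sl], mode="full")) - (len(x[sl]) - 1)
        assert lag == 0

    def test_stopband_rejection(self):
        _, x = sinusoid(100.0)
        y = lowpass_zero_phase(x, FS)
        assert np.max(np.abs(y[200:-200])) < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, z = rng.normal(size=400), rng.normal(size=400)
        a, b = 2.5, -1.2
        lhs = lowpass_zero_phase(a * x + b * z, FS)
        rhs = a * lowpass_zero_phase(x, FS) + b * lowpass_zero_phase(z, FS)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            lowpass_zero_phase(np.zeros(500), FS, FilterSpec(cutoff_hz=200.0))
        with pytest.raises(ParameterError):
            lowpass_zero_phase(np.zeros(10), FS)
        with pytest.raises(ParameterError):
            FilterSpec(order=5)

    def test_multichannel_matches_per_channel(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 4))
        Y = lowpass_zero_phase(X, FS)
        for j in range(4):
            assert np.allclose(Y[:, j], lowpass_zero_phase(X[:, j], FS))


class TestCardanAngles:
    def test_identity_is_zero(self):
        angles, gimbal = cardan_angles(np.eye(3))
        assert np.allclose(angles, 0.0, atol=1e-12)
        assert not gimbal

    def test_pure_rotation_about_first_axis(self):
        R = compose_cardan([90.0, 0.0, 0.0])
        angles, _ = cardan_angles(R)
        assert np.allclose(angles, [90.0, 0.0, 0.0], atol=1e-9)

    def test_compose_decompose_round_trip(self):
        target = np.array([10.0, 20.0, 30.0])
        angles, _ = cardan_angles(compose_cardan(target))
        assert np.allclose(angles, target, atol=1e-9)

    def test_recomposition_reproduces_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform([-180, -89, -180], [180, 89, 180])
            R = compose_cardan(a)
            angles, _ = cardan_angles(R)
            assert np.allclose(compose_cardan(angles), R, atol=1e-6)

    def test_gimbal_proximity_flagged(self):
        _, gimbal = cardan_angles(compose_cardan([10.0, 89.8, -5.0]))
        assert gimbal

    def test_non_rotation_rejected(self):
        with pytest.raises(SchemaError):
            cardan_angles(np.diag([1.0, 1.0, 2.0]))
        with pytest.raises(SchemaError):
            cardan_angles(np.diag([1.0, 1.0, -1.0]))  # det = -1


class TestSegmentKick:
    def test_constructed_ramp_and_peak(self):
        n = 300
        pos = np.concatenate([np.zeros(50), np.linspace(0, 1.0, n - 50)])
        t = np.arange(n, dtype=float)
        knee = -((t - 200.0) ** 2)
        start, end = segment_kick(pos, knee, FS)
        assert abs(start - 50) <= 2
        assert end == 200

    def test_monotone_knee_ends_at_last_sample(self):
        n = 200
        pos = np.linspace(0, 1.0, n)
        knee = np.linspace(0, 120.0, n)
        start, end = segment_kick(pos, knee, FS)
        assert end == n - 1

    def test_no_motion_raises(self):
        with pytest.raises(SegmentationError):
            segment_kick(np.zeros(100), np.linspace(0, 1, 100), FS)

    def test_peak_at_start_raises(self):
        pos = np.linspace(0, 1.0, 100)
        knee = -np.arange(100.0)  # maximal at index 0
        with pytest.raises(SegmentationError):
            segment_kick(pos, knee, FS)


class TestTimeNormalize:
    @given(n_in=st.integers(5, 400))
    @settings(max_examples=30, deadline=None)
    def test_linear_ramp_invariance(self, n_in):
        ramp = np.linspace(-3.0, 8.0, n_in)
        out = time_normalize(ramp, 101)
        assert out.shape == (101,)
        assert np.allclose(out, np.linspace(-3.0, 8.0, 101), atol=1e-9)
        assert out[0] == ramp[0] and out[-1] == ramp[-1]

    def test_idempotent_on_grid(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=101)
        assert np.array_equal(time_normalize(x, 101), x)

    def test_quadratic_within_interpolation_error_bound(self):
        t51 = np.linspace(0.0, 1.0, 51)
        out = time_normalize(t51 ** 2, 101)
        truth = np.linspace(0.0, 1.0, 101) ** 2
        # piecewise-linear error bound: h^2/8 * max|f''| with h = 1/50
        assert np.max(np.abs(out - truth)) <= (1 / 50) ** 2 / 8 * 2 + 1e-12

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            time_normalize(np.arange(10.0), n_points=1)
        with pytest.raises(SchemaError):
            time_normalize(np.array([1.0]))


class TestAssembleFeatures:
    def test_row_length_and_round_trip(self, tiny_features, tiny_dataset):
        assert tiny_features.values.shape[1] == 27 * 101
        stack = disassemble_features(tiny_features)
        assert stack.shape == (len(tiny_features), 101, 27)
        # round trip: re-assembling the disassembled stack preserves samples
        recon = stack.transpose(0, 2, 1).reshape(len(tiny_features), -1)
        assert np.array_equal(recon, tiny_features.values)

    def test_missing_variable_schema_error(self, tiny_dataset):
        rec = tiny_dataset.records[0].with_waveforms(
            time_normalize(tiny_dataset.records[0].waveforms))
        bad = rec.with_waveforms(rec.waveforms)
        bad.waveforms = bad.waveforms[:, :26]
        with pytest.raises(SchemaError, match="subject"):
            assemble_features([bad])

    def test_wrong_grid_schema_error(self, tiny_dataset):
        with pytest.raises(SchemaError, match="grid"):
            assemble_features([tiny_dataset.records[0]])


class TestNormalizer:
    def test_hand_computed_column(self):
        col = np.array([[0.0], [1.0], [2.0]])
        stats = fit_normalizer(col)
        z = (col - stats.mean) / stats.sd
        assert np.allclose(z.ravel(), [-1.2247, 0.0, 1.2247], atol=1e-4)
        out = apply_normalizer(col, stats)
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_training_extremes_hit_plus_minus_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 7))
        out = apply_normalizer(X, fit_normalizer(X))
        assert np.allclose(out.min(axis=0), -1.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_constant_column_maps_to_zero(self):
        X = np.column_stack([np.full(5, 3.3), np.arange(5.0)])
        out = apply_normalizer(X, fit_normalizer(X))
        assert np.all(out[:, 0] == 0.0)

    def test_train_row_transforms_consistently(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 6))
        stats = fit_normalizer(X)
        full = apply_normalizer(X, stats)
        assert np.allclose(apply_normalizer(X[3:4], stats), full[3:4])

    def test_invertibility(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 9))
        stats = fit_normalizer(X)
        back = invert_normalizer(apply_normalizer(X, stats), stats)
        assert np.allclose(back, X, atol=1e-9)


def test_preprocessing_is_deterministic(tiny_dataset):
    from kinemid import preprocess_dataset
    a = preprocess_dataset(tiny_dataset)
    b = preprocess_dataset(tiny_dataset)
    assert np.array_equal(a.values, b.values)
    assert a.labels.equals(b.labels)
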