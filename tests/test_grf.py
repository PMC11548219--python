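"""Force filtering, ground transform, stance detection and normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import butter, freqz

from shoegait import grf
from shoegait.errors import ConfigurationError, DataError, OffsetError, UsageError
from shoegait.io import ForceStream
from shoegait.orientation import OrientationTrace, rotation_ground


def _stream(time, total_fz=None, forces=None):
    n = len(time)
    if forces is None:
        forces = np.zeros((n, 4, 3))
        if total_fz is not None:
            forces[:, 0, 2] = total_fz
    return ForceStream(time=np.asarray(time, float), forces=forces)


def _grf(time, total_fz=None, forces=None):
    s = _stream(time, total_fz, forces)
    return grf.LocalizedGrf(time=s.time, forces=s.forces)


# --- low-pass -----------------------------------------------------------


def test_lowpass_preserves_dc():
    t = np.arange(0.0, 2.0, 1 / 400)
    stream = _stream(t, total_fz=np.full_like(t, 100.0))
    out = grf.lowpass_forces(stream)
    np.testing.assert_allclose(out.forces[:, 0, 2], 100.0, atol=1e-9)


@pytest.mark.parametrize(
    "freq, min_gain, max_gain",
    [(5.0, 0.99, 1.01), (150.0, 0.0, 0.03)],
)
def test_lowpass_frequency_response(freq, min_gain, max_gain):
    """Passband sinusoids survive; 150 Hz is attenuated by > 97%."""
    fs = 400.0
    t = np.arange(0.0, 4.0, 1 / fs)
    stream = _stream(t, total_fz=np.sin(2 * np.pi * freq * t))
    out = grf.lowpass_forces(stream, fs=fs)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    amplitude = np.abs(out.forces[mid, 0, 2]).max()
    assert min_gain <= amplitude <= max_gain
    # cross-check against the analytic squared Butterworth magnitude
    b, a = butter(4, 50 / (fs / 2), btype="low")
    w, h = freqz(b, a, worN=[freq], fs=fs)
    assert amplitude == pytest.approx(np.abs(h[0]) ** 2, abs=0.02)


def test_lowpass_rejects_low_sampling_rate():
    t = np.arange(0.0, 1.0, 1 / 80)
    with pytest.raises(ConfigurationError):
        grf.lowpass_forces(_stream(t), fs=80.0)


# --- offsets ------------------------------------------------------------


def test_offset_removal_recovers_constant_shift(rng):
    t = np.arange(0.0, 2.0, 1 / 400)
    truth = np.zeros((len(t), 4, 3))
    truth[t > 1.0, :, 2] = 300.0  # loaded second half
    offsets = rng.normal(0, 3.0, (4, 3))
    stream = _stream(t, forces=truth + offsets)
    out = grf.remove_offsets(stream, swing_mask=(t <= 1.0))
    np.testing.assert_allclose(out.forces[t <= 1.0], 0.0, atol=1e-9)
    np.testing.assert_allclose(out.forces, truth, atol=1e-9)


def test_zero_offset_input_unchanged():
    t = np.arange(0.0, 1.0, 1 / 400)
    stream = _stream(t, total_fz=np.zeros_like(t))
    out = grf.remove_offsets(stream, swing_mask=np.ones_like(t, bool))
    np.testing.assert_array_equal(out.forces, stream.forces)


def test_no_unloaded_samples_is_offset_error():
    t = np.arange(0.0, 1.0, 1 / 400)
    with pytest.raises(OffsetError):
        grf.remove_offsets(_stream(t), swing_mask=np.zeros_like(t, bool))


# --- ground transform ---------------------------------------------------


def test_transform_identity_angles_is_noop(rng):
    t = np.arange(0.0, 0.5, 1 / 400)
    forces = rng.normal(0, 50, (len(t), 4, 3))
    stream = _stream(t, forces=forces)
    zeros = np.zeros_like(t)
    out = grf.transform_to_ground(stream, OrientationTrace(t, zeros, zeros, zeros))
    np.testing.assert_allclose(out.forces, forces, atol=1e-12)


def test_transform_quarter_turn_about_y():
    t = np.arange(0.0, 0.1, 1 / 400)
    forces = np.zeros((len(t), 4, 3))
    forces[:, 2, 2] = 10.0
    stream = _stream(t, forces=forces)
    phi = np.full_like(t, 90.0)
    out = grf.transform_to_ground(
        stream, OrientationTrace(t, np.zeros_like(t), phi, np.zeros_like(t))
    )
    np.testing.assert_allclose(out.forces[:, 2, 0], 10.0, atol=1e-12)
    np.testing.assert_allclose(out.forces[:, 2, 2], 0.0, atol=1e-12)


def test_transform_matches_per_sample_matrix_oracle(rng):
    t = np.arange(0.0, 0.2, 1 / 400)
    forces = rng.normal(0, 100, (len(t), 4, 3))
    theta = rng.normal(0, 20, len(t))
    phi = rng.normal(0, 20, len(t))
    stream = _stream(t, forces=forces)
    out = grf.transform_to_ground(
        stream, OrientationTrace(t, theta, phi, np.zeros_like(t))
    )
    for k in (0, len(t) // 2, len(t) - 1):
        R = rotation_ground(theta[k], phi[k])
        for i in range(4):
            np.testing.assert_allclose(out.forces[k, i], R @ forces[k, i],
                                       atol=1e-12)


@given(theta=st.floats(-90, 90), phi=st.floats(-90, 90))
def test_transform_preserves_force_magnitude(theta, phi):
    t = np.array([0.0, 1 / 400])
    forces = np.tile(np.array([[3.0, -4.0, 12.0]]), (2, 4, 1))
    out = grf.transform_to_ground(
        _stream(t, forces=forces),
        OrientationTrace(t, np.full(2, theta), np.full(2, phi), np.zeros(2)),
    )
    np.testing.assert_allclose(
        np.linalg.norm(out.forces, axis=2), 13.0, atol=1e-9
    )


# --- stance detection ---------------------------------------------------


def test_no_load_gives_no_stances():
    t = np.arange(0.0, 1.0, 1 / 400)
    assert grf.detect_stance_phases(_grf(t, np.zeros_like(t))) == []


def test_rectangular_pulse_single_phase():
    t = np.arange(0.0, 2.0, 1 / 400)
    fz = np.where((t >= 0.5) & (t < 1.1), 600.0, 0.0)
    phases = grf.detect_stance_phases(_grf(t, fz))
    assert len(phases) == 1
    p = phases[0]
    assert t[p.start_idx] == pytest.approx(0.5, abs=1 / 400)
    assert t[p.end_idx] == pytest.approx(1.1, abs=1 / 400)


def test_boundaries_match_linear_scan_oracle(noisy_session):
    """Detected boundaries coincide with an exhaustive 15 N crossing scan."""
    session, _, _ = noisy_session
    stream = grf.lowpass_forces(session.force)
    stream = grf.remove_offsets(stream, grf.unloaded_mask(stream))
    g = grf.LocalizedGrf(time=stream.time, forces=stream.forces)
    phases = grf.detect_stance_phases(g)
    assert len(phases) >= 2
    total = g.total_vertical
    for p in phases:
        assert total[p.start_idx] > 15.0
        if p.start_idx > 0:
            assert total[p.start_idx - 1] <= 15.0
        if p.end_idx < len(total):
            assert total[p.end_idx] <= 15.0


def test_time_reversed_trace_gives_mirrored_phases():
    t = np.arange(0.0, 3.0, 1 / 400)
    fz = 600.0 * np.clip(np.sin(2 * np.pi * 0.8 * t), 0, None)
    phases = grf.detect_stance_phases(_grf(t, fz))
    rev = grf.detect_stance_phases(_grf(t, fz[::-1].copy()))
    n = len(t)
    fwd = sorted((p.start_idx, p.end_idx) for p in phases)
    mirrored = sorted((n - p.end_idx, n - p.start_idx) for p in rev)
    assert fwd == mirrored


def test_empty_signal_is_usage_error():
    with pytest.raises(UsageError):
        grf.detect_stance_phases(
            grf.LocalizedGrf(time=np.array([]), forces=np.zeros((0, 4, 3)))
        )


# --- normalization ------------------------------------------------------


def test_normalized_stance_has_101_points(analyzed_noiseless):
    result, _ = analyzed_noiseless
    for stance in result.stances:
        assert stance.values.shape == (4, 3, 101)
        assert stance.total.shape == (3, 101)


def test_linear_ramp_resampled_exactly():
    t = np.arange(0.0, 1.0, 1 / 400)
    fz = 100.0 * t
    g = _grf(t, fz)
    phase = grf.StancePhase(start_idx=40, end_idx=360, duration=t[359] - t[40])
    stance = grf.normalize_stance(g, phase)
    expected = 100.0 * np.linspace(t[40], t[359], 101)
    np.testing.assert_allclose(stance.values[0, 2], expected, atol=1e-9)


def test_normalization_matches_dense_oracle(rng):
    t = np.arange(0.0, 1.0, 1 / 400)
    fz = rng.normal(0, 100, len(t))
    g = _grf(t, fz)
    phase = grf.StancePhase(start_idx=10, end_idx=390, duration=t[389] - t[10])
    stance = grf.normalize_stance(g, phase)
    pct_times = np.linspace(t[10], t[389], 101)
    ref = np.interp(pct_times, t[10:390], fz[10:390])
    np.testing.assert_allclose(stance.values[0, 2], ref, atol=1e-12)


def test_stance_endpoints_equal_signal_values():
    t = np.arange(0.0, 1.0, 1 / 400)
    fz = np.sin(t * 7) * 100 + 200
    g = _grf(t, fz)
    phase = grf.StancePhase(start_idx=25, end_idx=300, duration=t[299] - t[25])
    stance = grf.normalize_stance(g, phase)
    assert stance.values[0, 2, 0] == pytest.approx(fz[25], abs=1e-12)
    assert stance.values[0, 2, 100] == pytest.approx(fz[299], abs=1e-12)


def test_too_short_phase_is_data_error():
    t = np.arange(0.0, 1.0, 1 / 400)
    g = _grf(t, np.ones_like(t))
    with pytest.raises(DataError):
        grf.normalize_stance(g, grf.StancePhase(0, 2, 0.005))


# --- segment summaries and contributions --------------------------------


def _constant_stance(per_sensor_fz, fx=0.0):
    values = np.zeros((4, 3, 101))
    for i, fz in enumerate(per_sensor_fz):
        values[i, 2] = fz
        values[i, 0] = fx
    return grf.NormalizedStance(values=values)


def test_constant_bodyweight_summary():
    mass = 70.0
    stance = _constant_stance([mass * 9.81 / 4] * 4)
    summary = grf.segment_summary([stance], body_mass=mass)
    np.testing.assert_allclose(summary.total_per_mass[2], 9.81, atol=1e-12)


def test_linear_total_segment_means_are_bin_averages():
    values = np.zeros((4, 3, 101))
    values[0, 2] = np.arange(101.0)  # total z = 0..100
    stance = grf.NormalizedStance(values=values)
    summary = grf.segment_summary([stance], body_mass=1.0)
    expected = [np.mean(np.arange(10 * k + 1, 10 * k + 11)) for k in range(10)]
    np.testing.assert_allclose(summary.total_per_mass[2], expected, atol=1e-12)


def test_two_identical_stances_average_to_one(noisy_session):
    stance = _constant_stance([100, 50, 25, 25])
    one = grf.segment_summary([stance], 60.0)
    two = grf.segment_summary([stance, stance], 60.0)
    np.testing.assert_allclose(one.total_per_mass, two.total_per_mass)
    np.testing.assert_allclose(one.contributions, two.contributions)


def test_only_heel_loaded_contribution():
    stance = _constant_stance([200.0, 0.0, 0.0, 0.0])
    shares = grf.contribution_percent(stance)
    np.testing.assert_allclose(shares[0, 2], 100.0)
    np.testing.assert_allclose(shares[1:, 2], 0.0)


def test_two_equal_sensors_split_evenly():
    stance = _constant_stance([80.0, 80.0, 0.0, 0.0])
    shares = grf.contribution_percent(stance)
    np.testing.assert_allclose(shares[0, 2], 50.0)
    np.testing.assert_allclose(shares[1, 2], 50.0)


def test_contributions_sum_to_100_where_defined(rng):
    values = rng.normal(0, 50, (4, 3, 101))
    stance = grf.NormalizedStance(values=values)
    shares = grf.contribution_percent(stance)
    total = shares.sum(axis=0)
    defined = ~np.isnan(total)
    np.testing.assert_allclose(total[defined], 100.0, atol=1e-9)
    # oracle: direct ratio on one defined cell
    seg_means_sensor = stance.values[:, :, 1:].reshape(4, 3, 10, 10).mean(-1)
    seg_means_total = stance.total[:, 1:].reshape(3, 10, 10).mean(-1)
    d, s_ = next(zip(*np.where(np.abs(seg_means_total) >= 1.0)))
    np.testing.assert_allclose(
        shares[:, d, s_], 100 * seg_means_sensor[:, d, s_] / seg_means_total[d, s_]
    )


def test_near_zero_total_marked_undefined():
    stance = _constant_stance([0.2, -0.2, 0.1, -0.1])
    shares = grf.contribution_percent(stance)
    assert np.isnan(shares[:, 2]).all()
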