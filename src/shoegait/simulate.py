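"""Synthetic straight-line walking sessions with exact ground truth.

The simulator emits what the instrumented shoe would record — a 70 Hz toe
IMU stream (specific force plus orientation quaternion) and a 400 Hz
four-sensor plantar force stream — from an analytic toe trajectory whose
per-stride length and minimum toe clearance (MTC) are drawn from a cohort
profile. Two default profiles encode the young- and older-adult statistical
structure (height-normalized stride and MTC means and CVs, cohort heights
and masses, contact style); every random draw flows through one explicit
seed.

Trajectory model. Each session is standing -> stride 1 -> ... -> stride n,
where a stride is one swing followed by one flat-foot interval. During
swing the forward coordinate follows a minimum-jerk (quintic) profile
reaching the stride length; the toe clearance follows a smooth band-limited
two-peak curve (early peak 3x MTC, mid-swing dip pinned to the MTC, late
peak 2x MTC; see :class:`_HeightCurve`); the foot pitches about the lateral
axis with an amplitude depending on contact style. Flat-foot intervals are
perfectly still, which is what lets the zero-velocity assumption of the
analysis hold exactly in the noiseless limit.

Force model. Each flat-foot interval carries one stance: the total vertical
force is a double-bump curve peaking near 1.1 body weights, the fore-aft
force is a braking-then-propulsion biphasic wave, and smooth per-sensor
weight functions split the total across heel, metatarsal and toe sensors
(heel-first style loads the heel early; the flat style of the older cohort
shifts early load toward the toe and metatarsals). These waveform shapes
are plausibility templates for testing the force pipeline, not measured
curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BPoly

from .calibration import CalibrationModel
from .errors import UsageError
from .io import ForceStream, ImuStream, RawSession, SessionMeta
from .orientation import G


@dataclass(frozen=True)
class GaitProfile:
    """Statistical structure of one participant group."""

    group: str
    norm_stride_mean: float  # stride length / height
    norm_stride_cv: float
    norm_mtc_mean: float  # MTC / height
    norm_mtc_cv: float
    cadence: float  # strides / s
    stance_fraction: float  # fraction of the stride cycle with the toe down
    height_mean: float  # m
    height_sd: float
    mass_mean: float  # kg
    mass_sd: float
    contact_style: str  # "heel_first" | "flat"

    def __post_init__(self):
        if not 0.4 < self.stance_fraction < 0.8:
            raise UsageError("stance fraction must lie in (0.4, 0.8)")
        if min(self.norm_stride_mean, self.norm_mtc_mean, self.cadence,
               self.height_mean, self.mass_mean) <= 0:
            raise UsageError("profile means must be positive")
        if min(self.norm_stride_cv, self.norm_mtc_cv) < 0:
            raise UsageError("profile CVs must be non-negative")
        if self.contact_style not in ("heel_first", "flat"):
            raise UsageError(f"unknown contact style {self.contact_style!r}")


@dataclass(frozen=True)
class SensorNoise:
    """Measurement imperfections applied to the emitted streams."""

    accel_noise_sd: float = 0.05  # m/s^2, white noise on each accel axis
    accel_gain_error: tuple = (1.03, 0.98, 1.02)  # true per-axis gains
    accel_bias: tuple = (0.15, -0.10, 0.05)  # m/s^2, true per-axis biases
    force_noise_sd: float = 1.0  # N, white noise per force channel
    quat_angle_noise_sd: float = 0.2  # deg, small random attitude error
    force_offset_sd: float = 0.5  # N, constant per-channel offset


NO_NOISE = SensorNoise(
    accel_noise_sd=0.0,
    accel_gain_error=(1.0, 1.0, 1.0),
    accel_bias=(0.0, 0.0, 0.0),
    force_noise_sd=0.0,
    quat_angle_noise_sd=0.0,
    force_offset_sd=0.0,
)


def default_profiles() -> tuple[GaitProfile, GaitProfile]:
    """The young and older cohort profiles (young, older).

    Height-normalized stride/MTC means and CVs and the cohort height and
    mass distributions follow the group comparison results; cadence and
    stance fraction are typical self-paced walking values.
    """
    young = GaitProfile(
        group="young",
        norm_stride_mean=0.670,
        norm_stride_cv=0.0534,
        norm_mtc_mean=0.0196,
        norm_mtc_cv=0.30,
        cadence=0.93,
        stance_fraction=0.60,
        height_mean=1.67,
        height_sd=0.066,
        mass_mean=60.2,
        mass_sd=16.6,
        contact_style="heel_first",
    )
    older = GaitProfile(
        group="older",
        norm_stride_mean=0.655,
        norm_stride_cv=0.0858,
        norm_mtc_mean=0.0120,
        norm_mtc_cv=0.71,
        cadence=0.85,
        stance_fraction=0.63,
        height_mean=1.54,
        height_sd=0.054,
        mass_mean=54.6,
        mass_sd=7.9,
        contact_style="flat",
    )
    return young, older


@dataclass
class StrideParams:
    """Sampled participant and per-stride ground-truth parameters."""

    height: float  # m
    mass: float  # kg
    stride_lengths: np.ndarray  # m, per stride
    mtcs: np.ndarray  # m, per stride


@dataclass
class SimTruth:
    """Exact per-stride truth recorded alongside the emitted streams."""

    height: float
    mass: float
    stride_lengths: np.ndarray
    mtcs: np.ndarray
    flat_windows: list[tuple[float, float]]  # s, toe-down intervals
    swing_spans: list[tuple[float, float]]  # s, per stride


def sample_strides(
    profile: GaitProfile, n_strides: int, rng_seed: int | np.random.Generator
) -> StrideParams:
    """Draw one participant (height, mass) and per-stride length and MTC.

    Stride lengths are Normal(mean, cv * mean). MTC is lognormal with the
    profile's mean and CV: at the older cohort's CV of 0.71 a truncated
    normal cannot carry that much relative spread while staying positive,
    whereas the lognormal matches both moments exactly and never needs the
    0.001 m floor. Reproducible for a fixed seed.
    """
    if n_strides < 1:
        raise UsageError("need at least one stride")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    height = float(np.clip(rng.normal(profile.height_mean, profile.height_sd),
                           1.2, 2.1))
    mass = float(np.clip(rng.normal(profile.mass_mean, profile.mass_sd), 30.0, 150.0))
    stride_mean = profile.norm_stride_mean * height
    lengths = rng.normal(stride_mean, profile.norm_stride_cv * stride_mean,
                         size=n_strides)
    lengths = np.clip(lengths, 0.2, 2.5)
    mtc_mean = profile.norm_mtc_mean * height
    cv = profile.norm_mtc_cv
    sigma_ln = np.sqrt(np.log1p(cv * cv))
    mu_ln = np.log(mtc_mean) - 0.5 * sigma_ln * sigma_ln
    mtcs = np.maximum(rng.lognormal(mu_ln, sigma_ln, size=n_strides), 0.001)
    return StrideParams(height=height, mass=mass, stride_lengths=lengths, mtcs=mtcs)


# ---------------------------------------------------------------------------
# Trajectory


class _HeightCurve:
    """Analytic vertical IMU travel: zero on flat feet, a smooth two-peak
    trigonometric curve during each swing.

    Within a swing (progress s in [0, 1]) the travel is

        z(s) = sin^3(pi s) * (a + b cos(2 pi s) + c sin(2 pi s)
                              + (c/2) sin(4 pi s))

    The sin^3 envelope pins value, velocity and acceleration to zero at the
    swing boundaries; the coefficients are solved per stride so the toe
    CLEARANCE (z + mount height) passes through 3x MTC at 25% swing, exactly
    the MTC with zero slope at 50% (the sin(4 pi s) term cancels the
    asymmetry slope there), and 2x MTC at 75%. The harmonic content stays
    below ~4 cycles per swing, matching the band-limited character of real
    foot motion.
    """

    _E25 = np.sin(np.pi * 0.25) ** 3  # envelope value at 25% / 75% swing

    def __init__(self, swings: list[tuple[float, float]], coeffs: np.ndarray,
                 order: int = 0):
        self.swings = swings  # [(t0, t1)] per stride
        self.coeffs = np.asarray(coeffs, dtype=float)  # (n, 3): a, b, c
        self.order = order
        self._starts = np.array([s for s, _ in swings])
        self._ends = np.array([e for _, e in swings])

    @classmethod
    def solve(cls, swings, mtcs, initial_height: float) -> "_HeightCurve":
        coeffs = np.empty((len(swings), 3))
        for k, mtc in enumerate(mtcs):
            g25 = (3.0 * mtc - initial_height) / cls._E25
            g50 = mtc - initial_height
            g75 = (2.0 * mtc - initial_height) / cls._E25
            a = 0.5 * (g25 + g75)
            c = 0.5 * (g25 - g75)
            b = a - g50
            coeffs[k] = (a, b, c)
        return cls(swings, coeffs)

    def derivative(self, n: int) -> "_HeightCurve":
        return _HeightCurve(self.swings, self.coeffs, self.order + n)

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        idx = np.searchsorted(self._starts, t, side="right") - 1
        for k in range(len(self.swings)):
            t0, t1 = self.swings[k]
            sel = (idx == k) & (t < t1)
            if not sel.any():
                continue
            T = t1 - t0
            s = (t[sel] - t0) / T
            a, b, c = self.coeffs[k]
            if self.order == 0:
                out[sel] = self._z(s, a, b, c)
            elif self.order == 2:
                out[sel] = self._d2z(s, a, b, c) / T**2
            else:
                raise NotImplementedError("only value and 2nd derivative")
        return out

    @staticmethod
    def _z(s, a, b, c):
        e = np.sin(np.pi * s) ** 3
        g = a + b * np.cos(2 * np.pi * s) + c * np.sin(2 * np.pi * s) \
            + 0.5 * c * np.sin(4 * np.pi * s)
        return e * g

    @staticmethod
    def _d2z(s, a, b, c):
        pi = np.pi
        sn, cn = np.sin(pi * s), np.cos(pi * s)
        e = sn**3
        de = 3 * pi * sn**2 * cn
        d2e = 3 * pi**2 * sn * (2 * cn**2 - sn**2)
        g = a + b * np.cos(2 * pi * s) + c * np.sin(2 * pi * s) \
            + 0.5 * c * np.sin(4 * pi * s)
        dg = 2 * pi * (-b * np.sin(2 * pi * s) + c * np.cos(2 * pi * s)
                       + c * np.cos(4 * pi * s))
        d2g = 4 * pi**2 * (-b * np.cos(2 * pi * s) - c * np.sin(2 * pi * s)
                           - 2 * c * np.sin(4 * pi * s))
        return d2e * g + 2 * de * dg + e * d2g


@dataclass
class ToeTrajectory:
    """Analytic C^2 toe path: forward position, height and pitch vs time."""

    forward: BPoly
    height: _HeightCurve
    pitch_deg: BPoly
    duration: float
    truth: SimTruth
    d2_forward: BPoly = field(init=False)
    d2_height: _HeightCurve = field(init=False)

    def __post_init__(self):
        self.d2_forward = self.forward.derivative(2)
        self.d2_height = self.height.derivative(2)


def toe_trajectory(
    params: StrideParams,
    profile: GaitProfile,
    lead_in_s: float = 1.0,
    initial_height: float = 0.03,
) -> ToeTrajectory:
    """Build the session toe path from sampled stride parameters.

    The path starts with ``lead_in_s`` of quiet standing; each stride is a
    swing of (1 - stance_fraction)/cadence seconds followed by a flat-foot
    interval of stance_fraction/cadence seconds.

    The height channel is the vertical travel of the IMU itself, so that toe
    clearance (travel + ``initial_height``) peaks at 3x the stride's MTC
    early in swing, dips to exactly the MTC at 50% swing, and peaks at 2x
    the MTC late in swing. For small MTC draws the travel goes negative
    (the toe-mounted IMU dips below its standing height), which is exactly
    what the additive clearance definition implies for shuffling gait.
    """
    cycle = 1.0 / profile.cadence
    t_swing = (1.0 - profile.stance_fraction) * cycle
    t_flat = profile.stance_fraction * cycle
    pitch_amp = 25.0 if profile.contact_style == "heel_first" else 10.0

    fw_t, fw_v = [0.0], [[0.0, 0.0, 0.0]]
    pt_t, pt_v = [0.0], [[0.0, 0.0, 0.0]]
    flat_windows = [(0.0, lead_in_s)]
    swing_spans = []
    t = lead_in_s
    y = 0.0
    for L in params.stride_lengths:
        t0, t1 = t, t + t_swing
        swing_spans.append((t0, t1))
        # forward: rest -> rest quintic (minimum jerk between the knots)
        fw_t += [t0, t1]
        fw_v += [[y, 0.0, 0.0], [y + L, 0.0, 0.0]]
        # pitch: plantarflexion after toe off, dorsiflexion before landing
        pt_t += [t0, t0 + 0.25 * t_swing, t0 + 0.6 * t_swing, t1]
        pt_v += [[0.0, 0.0, 0.0], [-0.6 * pitch_amp, 0.0, 0.0],
                 [0.4 * pitch_amp, 0.0, 0.0], [0.0, 0.0, 0.0]]
        y += L
        t = t1 + t_flat
        flat_windows.append((t1, t))
    duration = t
    for knots, vals in ((fw_t, fw_v), (pt_t, pt_v)):
        knots.append(duration)
        vals.append([vals[-1][0], 0.0, 0.0])
    height = _HeightCurve.solve(swing_spans, params.mtcs, initial_height)
    # realized MTC: the analytic clearance minimum in the central swing
    realized = np.empty(len(swing_spans))
    s_grid = np.linspace(0.3, 0.7, 2001)
    for k, (t0, t1) in enumerate(swing_spans):
        a, b, c = height.coeffs[k]
        z = _HeightCurve._z(s_grid, a, b, c)
        realized[k] = z.min() + initial_height
    truth = SimTruth(
        height=params.height,
        mass=params.mass,
        stride_lengths=params.stride_lengths.copy(),
        mtcs=realized,
        flat_windows=flat_windows,
        swing_spans=swing_spans,
    )
    return ToeTrajectory(
        forward=BPoly.from_derivatives(fw_t, fw_v),
        height=height,
        pitch_deg=BPoly.from_derivatives(pt_t, pt_v),
        duration=duration,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Sensor synthesis


def synthesize_imu(
    trajectory: ToeTrajectory,
    noise: SensorNoise,
    imu_rate: float = 70.0,
    rng_seed: int | np.random.Generator = 0,
) -> ImuStream:
    """Emit the IMU stream the toe-mounted sensor would record.

    The world specific force (analytic second derivative plus gravity) is
    rotated into the pitching sensor frame, then corrupted by the inverse of
    the calibration model (divide by gain, add bias) and white noise; the
    quaternions carry a small random attitude error.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t = np.arange(0.0, trajectory.duration, 1.0 / imu_rate)
    ay_w = trajectory.d2_forward(t)
    az_w = trajectory.d2_height(t)
    pitch = np.radians(trajectory.pitch_deg(t))
    fx_w = np.zeros_like(t)
    fy_w = ay_w
    fz_w = az_w + G
    # local = Rx(pitch)^T world
    c, s = np.cos(pitch), np.sin(pitch)
    fx_l = fx_w
    fy_l = c * fy_w + s * fz_w
    fz_l = -s * fy_w + c * fz_w
    local = np.column_stack([fx_l, fy_l, fz_l])
    gain = np.asarray(noise.accel_gain_error, dtype=float)
    bias = np.asarray(noise.accel_bias, dtype=float)
    raw = local / gain + bias
    if noise.accel_noise_sd > 0:
        raw = raw + rng.normal(0.0, noise.accel_noise_sd, size=raw.shape)
    half = 0.5 * pitch
    quat = np.column_stack(
        [np.cos(half), np.sin(half), np.zeros_like(half), np.zeros_like(half)]
    )
    if noise.quat_angle_noise_sd > 0:
        quat = _perturb_quaternions(quat, noise.quat_angle_noise_sd, rng)
    return ImuStream(time=t, accel=raw, quat=quat)


def _perturb_quaternions(
    quat: np.ndarray, angle_sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Left-multiply each quaternion by a small random rotation."""
    n = len(quat)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    half = 0.5 * np.radians(rng.normal(0.0, angle_sd_deg, size=n))
    dq = np.column_stack([np.cos(half), np.sin(half)[:, None] * axes])
    w1, x1, y1, z1 = dq.T
    w2, x2, y2, z2 = quat.T
    return np.column_stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _sensor_weights(u: np.ndarray, style: str) -> np.ndarray:
    """Smooth (4, n) load-share curves over stance progress u in [0, 1]."""

    def bump(center, width, amp=1.0):
        return amp * np.exp(-(((u - center) / width) ** 2))

    if style == "heel_first":
        raw = np.stack(
            [
                bump(0.10, 0.22),  # heel dominates early stance
                bump(0.75, 0.25, 0.35),  # MT1 minor, late
                bump(0.50, 0.24, 0.80),  # MT5 mid stance
                bump(0.88, 0.18),  # toe dominates push-off
            ]
        )
    else:  # flat contact: early load shifted toward toe and metatarsals
        raw = np.stack(
            [
                bump(0.12, 0.22, 0.55),
                bump(0.15, 0.25, 0.40) + bump(0.70, 0.28, 0.45),
                bump(0.40, 0.30, 0.90),
                bump(0.12, 0.20, 0.45) + bump(0.85, 0.20, 0.85),
            ]
        )
    return raw / raw.sum(axis=0, keepdims=True)


def synthesize_forces(
    trajectory: ToeTrajectory,
    profile: GaitProfile,
    mass: float,
    noise: SensorNoise,
    force_rate: float = 400.0,
    rng_seed: int | np.random.Generator = 0,
) -> ForceStream:
    """Emit the four-sensor force stream in the shoe-local frame.

    Each flat-foot window carries one stance; forces are zero (noise and
    offsets only) elsewhere. Ground-frame forces are mapped to the sensor
    frame with the inverse of the ground rotation at the toe's pitch angle.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t = np.arange(0.0, trajectory.duration, 1.0 / force_rate)
    bw = mass * G
    ground = np.zeros((t.size, 4, 3))
    for (w0, w1) in trajectory.truth.flat_windows:
        sel = (t >= w0) & (t < w1)
        if not sel.any():
            continue
        u = (t[sel] - w0) / (w1 - w0)
        shape = np.sin(np.pi * u) * (1.15 + 0.45 * np.cos(2.0 * np.pi * u))
        fz_tot = bw * 1.1 * shape / shape.max()
        fy_tot = -0.17 * bw * np.sin(2.0 * np.pi * u) * np.sin(np.pi * u)
        fx_tot = 0.05 * bw * np.sin(np.pi * u) * np.cos(np.pi * u)
        w = _sensor_weights(u, profile.contact_style)  # (4, n)
        ground[sel, :, 0] = (w * fx_tot).T
        ground[sel, :, 1] = (w * fy_tot).T
        ground[sel, :, 2] = (w * fz_tot).T
    # to the shoe-local frame: F_local = R_ground(theta)^T F_ground
    pitch = np.radians(trajectory.pitch_deg(t))
    c, s = np.cos(pitch), np.sin(pitch)
    fy_g = ground[:, :, 1]
    fz_g = ground[:, :, 2]
    local = ground.copy()
    local[:, :, 1] = c[:, None] * fy_g + s[:, None] * fz_g
    local[:, :, 2] = -s[:, None] * fy_g + c[:, None] * fz_g
    if noise.force_offset_sd > 0:
        local += rng.normal(0.0, noise.force_offset_sd, size=(4, 3))
    if noise.force_noise_sd > 0:
        local += rng.normal(0.0, noise.force_noise_sd, size=local.shape)
    return ForceStream(time=t, forces=local)


def true_calibration(noise: SensorNoise) -> CalibrationModel:
    """The calibration model that exactly undoes the simulated gain/bias."""
    return CalibrationModel(
        gain=np.asarray(noise.accel_gain_error, float),
        bias=np.asarray(noise.accel_bias, float),
    )


def sample_postures(
    noise: SensorNoise,
    n_postures: int = 20,
    rng_seed: int | np.random.Generator = 0,
    posture_noise_sd: float = 0.02,
) -> np.ndarray:
    """Stationary readings for calibration: gravity in random directions,
    pushed through the inverse sensor model plus posture noise."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    dirs = rng.normal(size=(n_postures, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    truth = G * dirs
    gain = np.asarray(noise.accel_gain_error, float)
    bias = np.asarray(noise.accel_bias, float)
    raw = truth / gain + bias
    if posture_noise_sd > 0:
        raw = raw + rng.normal(0.0, posture_noise_sd, size=raw.shape)
    return raw


# ---------------------------------------------------------------------------
# Whole sessions


def simulate_session(
    profile: GaitProfile,
    n_strides: int,
    noise: SensorNoise = SensorNoise(),
    rng_seed: int | np.random.Generator = 0,
    participant_id: str = "sim-000",
    imu_rate: float = 70.0,
    force_rate: float = 400.0,
) -> tuple[RawSession, SimTruth]:
    """Generate one complete session (both streams, metadata) plus its truth."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    params = sample_strides(profile, n_strides, rng)
    traj = toe_trajectory(params, profile)
    imu = synthesize_imu(traj, noise, imu_rate, rng)
    force = synthesize_forces(traj, profile, params.mass, noise, force_rate, rng)
    meta = SessionMeta(
        participant_id=participant_id,
        group=profile.group,
        height=params.height,
        body_mass=params.mass,
        force_rate_hz=force_rate,
        imu_rate_hz=imu_rate,
    )
    return RawSession(meta=meta, force=force, imu=imu), traj.truth


def write_truth(path: str | Path, truth: SimTruth) -> None:
    n = len(truth.stride_lengths)
    pd.DataFrame(
        {
            "stride_index": np.arange(n),
            "stride_length_m": truth.stride_lengths,
            "mtc_m": truth.mtcs,
            "swing_start_s": [s for s, _ in truth.swing_spans],
            "swing_end_s": [e for _, e in truth.swing_spans],
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
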