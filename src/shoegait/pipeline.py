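"""End-to-end session analysis: raw streams to stances, strides and summaries.

Mirrors the two-branch structure of the shoe-sensor algorithm: a force
branch (low-pass, offset removal, ground-frame transform, 15 N stance
detection, 101-point normalization, segment summaries) and a kinematics
branch (global-frame acceleration, flat-foot detection, per-stride ZUPT
double integration, stride length, toe clearance, MTC), both driven by one
orientation trace accumulated from the IMU quaternions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import grf, kinematics, stats
from .calibration import CalibrationModel, apply_calibration
from .io import RawSession
from .orientation import (
    OrientationTrace,
    accumulate_orientation,
    initial_angles_from_gravity,
    interpolate_orientation_to_force_clock,
)


@dataclass(frozen=True)
class RunConfig:
    """Processing thresholds; defaults are the algorithm's published values."""

    stance_threshold_n: float = grf.STANCE_THRESHOLD_N
    lowpass_cutoff_hz: float = grf.LOWPASS_CUTOFF_HZ
    min_stance_s: float = grf.MIN_STANCE_S
    min_swing_s: float = grf.MIN_SWING_S
    mtc_window: tuple = kinematics.MTC_WINDOW
    min_flat_s: float = kinematics.MIN_FLAT_S
    stationary_window_s: float = 0.5  # initial window used for leveling


@dataclass
class SessionResult:
    """Everything the pipeline derives from one session."""

    orientation: OrientationTrace
    stance_phases: list
    stances: list  # NormalizedStance per stance
    segment_summary: grf.SegmentSummary
    stride_records: list  # StrideRecord per stride
    participant: stats.ParticipantSummary

    @property
    def stride_lengths(self) -> np.ndarray:
        return np.array([r.stride_length for r in self.stride_records])

    @property
    def mtcs(self) -> np.ndarray:
        return np.array([r.min_toe_clearance for r in self.stride_records])


def analyze_session(
    session: RawSession,
    calibration: CalibrationModel | None = None,
    config: RunConfig = RunConfig(),
) -> SessionResult:
    """Run both analysis branches on one raw session."""
    imu = session.imu
    accel = (
        apply_calibration(calibration, imu.accel)
        if calibration is not None
        else imu.accel
    )

    # orientation: level from the initial stationary window, then accumulate
    n0 = max(2, int(config.stationary_window_s * session.meta.imu_rate_hz))
    init = initial_angles_from_gravity(accel[:n0].mean(axis=0))
    orientation = accumulate_orientation(imu, init)

    # force branch
    force = grf.lowpass_forces(session.force, cutoff=config.lowpass_cutoff_hz)
    force = grf.remove_offsets(force, grf.unloaded_mask(force))
    angles_f = interpolate_orientation_to_force_clock(orientation, force.time)
    ground = grf.transform_to_ground(force, angles_f)
    phases = grf.detect_stance_phases(
        ground,
        threshold_n=config.stance_threshold_n,
        min_stance_s=config.min_stance_s,
        min_swing_s=config.min_swing_s,
    )
    stances = [grf.normalize_stance(ground, p) for p in phases]
    summary = grf.segment_summary(stances, session.meta.body_mass)

    # kinematics branch
    accel_global = kinematics.to_global_accel(imu, orientation, calibrated_accel=accel)
    mask = kinematics.detect_flat_foot(
        imu, accel_global, calibrated_accel=accel, min_flat_s=config.min_flat_s
    )
    strides = kinematics.segment_strides(mask)
    traces = kinematics.integrate_with_zupt(accel_global, strides, mask)
    records = kinematics.extract_stride_records(
        traces, mask, initial_height=session.meta.imu_initial_height
    )

    lengths = np.array([r.stride_length for r in records])
    mtcs = np.array([r.min_toe_clearance for r in records])
    participant = stats.ParticipantSummary(
        participant_id=session.meta.participant_id,
        group=session.meta.group,
        mean_stride_length=float(lengths.mean()),
        cv_stride_length=stats.coefficient_of_variation(lengths),
        mean_mtc=float(mtcs.mean()),
        cv_mtc=stats.coefficient_of_variation(mtcs),
        norm_stride_length=stats.normalize_by_height(
            float(lengths.mean()), session.meta.height
        ),
        norm_mtc=stats.normalize_by_height(float(mtcs.mean()), session.meta.height),
    )
    return SessionResult(
        orientation=orientation,
        stance_phases=phases,
        stances=stances,
        segment_summary=summary,
        stride_records=records,
        participant=participant,
    )
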