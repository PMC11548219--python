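"""Stride kinematics by ZUPT double integration of toe acceleration.

Global-frame toe acceleration (gravity removed) is integrated twice per
stride. Flat-foot phases — samples where the raw specific-force norm is near
gravity and the dynamic acceleration is small — anchor the integration: each
stride runs from the midpoint of one flat-foot run to the midpoint of the
next, starts from zero velocity, and the residual end-of-stride velocity is
removed as a piecewise-linear drift ramp. The vertical displacement is
additionally pinned to zero at stride end. Stride length is the horizontal
displacement between consecutive swing starts; toe clearance is the vertical
displacement plus the IMU mount height, and the minimum toe clearance (MTC)
is the lowest clearance in mid-swing.

A 1.0-40 Hz Butterworth band-pass (:func:`bandpass_accel`) is provided for
drift suppression but is NOT applied before integration: at self-paced
walking cadence (~0.9 strides/s) the per-stride displacement is carried by
velocity content at and below 1 Hz, so a 1 Hz high-pass removes most of the
stride length itself (measured ~87% loss on noiseless synthetic gait). The
low-frequency drift it would target is instead cancelled exactly per stride
by the ZUPT linear drift model, which removes any constant acceleration
bias in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .errors import DataError, SegmentationError, UsageError
from .io import ImuStream
from .orientation import G, OrientationTrace

BANDPASS_LOW_HZ = 1.0
BANDPASS_HIGH_HZ = 40.0
FLAT_NORM_BAND = 0.8  # m/s^2, |raw accel norm - g| band for flat foot
FLAT_DYNAMIC_MAX = 1.0  # m/s^2, band-passed global accel norm bound
MIN_FLAT_S = 0.05  # minimum sustained flat-foot duration
MTC_WINDOW = (0.25, 0.75)  # central fraction of swing searched for the MTC
DEFAULT_INITIAL_HEIGHT = 0.03  # m, IMU mount height above ground


@dataclass
class GlobalAccelTrace:
    """Band-passed global-frame acceleration on the IMU clock, gravity removed."""

    time: np.ndarray
    accel: np.ndarray  # (n, 3)


@dataclass
class StrideTrace:
    """Integrated velocity/position over one stride window."""

    time: np.ndarray
    velocity: np.ndarray  # (n, 3), ZUPT-corrected
    position: np.ndarray  # (n, 3), vertical drift-corrected
    start_idx: int  # index into the session IMU clock
    end_idx: int


@dataclass
class StrideRecord:
    stride_index: int
    start_time: float
    end_time: float
    stride_length: float  # m
    clearance_trace: np.ndarray  # m, over the stride window
    min_toe_clearance: float  # m
    swing_span: tuple[float, float]  # s


def bandpass_accel(accel, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, 1.0 Hz to min(40, 0.45 fs)."""
    if fs <= 2.0:
        raise UsageError("sampling rate too low for the 1 Hz high-pass")
    high = min(BANDPASS_HIGH_HZ, 0.45 * fs)
    b, a = butter(4, [BANDPASS_LOW_HZ / (fs / 2), high / (fs / 2)], btype="band")
    return filtfilt(b, a, np.asarray(accel, dtype=float), axis=0)


def to_global_accel(
    imu: ImuStream,
    orientation: OrientationTrace,
    calibrated_accel: np.ndarray | None = None,
    bandpass: bool = False,
) -> GlobalAccelTrace:
    """Rotate IMU acceleration into the global frame and drop gravity.

    ``calibrated_accel`` substitutes for ``imu.accel`` when a calibration
    model has been applied upstream. ``bandpass=True`` additionally applies
    the 1.0-40 Hz filter; the default leaves the trace unfiltered because
    the stride-band signal lives partly below 1 Hz (see module docstring).
    """
    accel = imu.accel if calibrated_accel is None else np.asarray(calibrated_accel)
    if len(orientation.time) != len(imu.time):
        raise UsageError("orientation trace is not on the IMU clock")
    th = np.radians(orientation.theta)
    ph = np.radians(orientation.phi)
    ps = np.radians(orientation.psi)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(ph), np.sin(ph)
    cs, ss = np.cos(ps), np.sin(ps)
    # R = Rz(psi) @ Ry(phi) @ Rx(theta), batched
    R = np.empty((len(th), 3, 3))
    R[:, 0, 0] = cs * cp
    R[:, 0, 1] = cs * sp * st - ss * ct
    R[:, 0, 2] = cs * sp * ct + ss * st
    R[:, 1, 0] = ss * cp
    R[:, 1, 1] = ss * sp * st + cs * ct
    R[:, 1, 2] = ss * sp * ct - cs * st
    R[:, 2, 0] = -sp
    R[:, 2, 1] = cp * st
    R[:, 2, 2] = cp * ct
    world = np.einsum("tij,tj->ti", R, accel)
    world[:, 2] -= G
    if bandpass:
        world = bandpass_accel(world, imu.rate_hz)
    return GlobalAccelTrace(time=imu.time.copy(), accel=world)


def detect_flat_foot(
    imu: ImuStream,
    accel_global: GlobalAccelTrace,
    calibrated_accel: np.ndarray | None = None,
    min_flat_s: float = MIN_FLAT_S,
) -> np.ndarray:
    """Boolean flat-foot mask on the IMU clock.

    A sample is flat-foot when the specific-force norm is within 0.8 m/s^2 of
    gravity AND the gravity-removed global acceleration norm is below
    1.0 m/s^2, sustained for at least ``min_flat_s``.
    """
    accel = imu.accel if calibrated_accel is None else np.asarray(calibrated_accel)
    raw_norm = np.linalg.norm(accel, axis=1)
    dyn_norm = np.linalg.norm(accel_global.accel, axis=1)
    candidate = (np.abs(raw_norm - G) <= FLAT_NORM_BAND) & (dyn_norm < FLAT_DYNAMIC_MAX)
    min_len = max(2, int(np.ceil(min_flat_s * imu.rate_hz)))
    mask = np.zeros_like(candidate)
    for s, e in _runs(candidate):
        if e - s >= min_len:
            mask[s:e] = True
    if not mask.any():
        raise SegmentationError("no flat-foot phase found in the trial")
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    m = np.asarray(mask, dtype=bool)
    edges = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if m.size and m[0]:
        starts.insert(0, 0)
    if m.size and m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def segment_strides(mask: np.ndarray) -> list[tuple[int, int]]:
    """One stride per pair of consecutive flat-foot runs (midpoint to midpoint)."""
    runs = _runs(mask)
    if len(runs) < 2:
        raise SegmentationError(
            f"need >= 2 flat-foot runs to segment strides, found {len(runs)}"
        )
    mids = [(s + e) // 2 for s, e in runs]
    return [(mids[k], mids[k + 1]) for k in range(len(mids) - 1)]


def integrate_with_zupt(
    accel_global: GlobalAccelTrace,
    strides: list[tuple[int, int]],
    mask: np.ndarray,
) -> list[StrideTrace]:
    """Per-stride trapezoidal double integration with drift cancellation.

    Velocity starts from zero at the stride-opening flat-foot midpoint; the
    residual end-of-stride velocity (expected zero at the next flat foot) is
    removed per axis by subtracting the linear ramp v_err * (t-t0)/(t1-t0).
    The corrected velocity is integrated to position, and the vertical
    position is pinned to zero displacement at stride end by the same ramp
    construction.
    """
    t_all = accel_global.time
    out = []
    for s, e in strides:
        if e - s < 5:
            raise DataError(f"stride [{s},{e}) spans fewer than 5 samples")
        t = t_all[s : e + 1] if e + 1 <= len(t_all) else t_all[s:e]
        a = accel_global.accel[s : s + len(t)]
        v = cumulative_trapezoid(a, t, axis=0, initial=0.0)
        ramp = (t - t[0]) / (t[-1] - t[0])
        v = v - ramp[:, None] * v[-1]  # piecewise-linear drift cancellation
        p = cumulative_trapezoid(v, t, axis=0, initial=0.0)
        p[:, 2] -= ramp * p[-1, 2]  # zero vertical displacement at stride end
        out.append(
            StrideTrace(time=t, velocity=v, position=p, start_idx=s, end_idx=s + len(t))
        )
    return out


def stride_length(position: np.ndarray, swing_start_idx: int = 0) -> float:
    """Euclidean horizontal displacement from swing start to stride end."""
    p = np.asarray(position, dtype=float)
    delta = p[-1, :2] - p[swing_start_idx, :2]
    return float(np.hypot(delta[0], delta[1]))


def toe_clearance(
    position_z: np.ndarray, initial_height: float = DEFAULT_INITIAL_HEIGHT
) -> np.ndarray:
    """Clearance trace: drift-corrected vertical travel plus mount height."""
    return np.asarray(position_z, dtype=float) + initial_height


def minimum_toe_clearance(
    clearance: np.ndarray,
    time: np.ndarray,
    swing_span: tuple[float, float],
    window: tuple[float, float] = MTC_WINDOW,
) -> float:
    """Lowest clearance in the middle of the swing phase.

    Searches the central ``window`` (default 25-75%) of the swing for an
    interior local minimum; if none exists the window's global minimum is
    returned.
    """
    t0, t1 = swing_span
    lo = t0 + window[0] * (t1 - t0)
    hi = t0 + window[1] * (t1 - t0)
    sel = (time >= lo) & (time <= hi)
    if not sel.any():
        raise DataError("empty MTC search window")
    c = clearance[sel]
    interior = np.flatnonzero((c[1:-1] <= c[:-2]) & (c[1:-1] <= c[2:])) + 1
    if interior.size:
        return float(c[interior].min())
    return float(c.min())


def extract_stride_records(
    traces: list[StrideTrace],
    mask: np.ndarray,
    initial_height: float = DEFAULT_INITIAL_HEIGHT,
) -> list[StrideRecord]:
    """Assemble per-stride length / clearance / MTC records.

    Within each stride window the swing runs from the end of the opening
    flat-foot run to the start of the closing one.
    """
    runs = _runs(mask)
    records = []
    for k, tr in enumerate(traces):
        opening = next((r for r in runs if r[0] <= tr.start_idx < r[1]), None)
        closing = next((r for r in runs if r[0] <= tr.end_idx - 1 < r[1]), None)
        if opening is None or closing is None:
            raise SegmentationError(f"stride {k} is not bracketed by flat-foot runs")
        swing_start_local = min(opening[1] - tr.start_idx, len(tr.time) - 1)
        swing_end_local = max(min(closing[0] - tr.start_idx, len(tr.time) - 1), 0)
        clearance = toe_clearance(tr.position[:, 2], initial_height)
        swing_span = (float(tr.time[swing_start_local]), float(tr.time[swing_end_local]))
        records.append(
            StrideRecord(
                stride_index=k,
                start_time=float(tr.time[0]),
                end_time=float(tr.time[-1]),
                stride_length=stride_length(tr.position, swing_start_local),
                clearance_trace=clearance,
                min_toe_clearance=minimum_toe_clearance(
                    clearance, tr.time, swing_span
                ),
                swing_span=swing_span,
            )
        )
    return records


def write_stride_records(path: str | Path, records: list[StrideRecord]) -> None:
    pd.DataFrame(
        {
            "stride_index": [r.stride_index for r in records],
            "start_time": [r.start_time for r in records],
            "end_time": [r.end_time for r in records],
            "stride_length_m": [r.stride_length for r in records],
            "mtc_m": [r.min_toe_clearance for r in records],
        }
    ).to_csv(path, index=False, float_format="%.9g")
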