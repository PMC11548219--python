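"""Attitude tracking of the toe-mounted IMU.

The pipeline keeps three Euler angles on the IMU clock: theta (about the
foot-width axis x'), phi (about the foot-length axis y') and psi (about the
vertical axis z'), composed intrinsically as R = Rz(psi) @ Ry(phi) @ Rx(theta).
The same product restricted to (theta, phi) maps shoe-local forces to the
ground frame; the full product maps IMU-local acceleration to the global
frame.

Initial attitude comes from the stationary gravity reading. Two forms are
provided:

``initial_angles``
    The legacy arctan pair theta0 = -atan2(az0, ax0),
    phi0 = arctan(ax0 / sqrt(ay0^2 + az0^2)). These assume a mounting in
    which gravity at rest lies along the sensor x' axis; for a z'-up
    mounting they do NOT return the attitude that makes the Rz.Ry.Rx chain
    cancel gravity (see docs/methods.md).

``initial_angles_from_gravity``
    The accelerometer-leveling form theta0 = atan2(ay0, az0),
    phi0 = -arctan(ax0 / sqrt(ay0^2 + az0^2)), which is algebraically exact
    for the Rz.Ry.Rx chain with gravity-up specific force: it is what the
    end-to-end pipeline uses.

During walking the angles are advanced by decomposing each inter-sample
relative quaternion into intrinsic z-y-x Euler increments and summing them,
starting from the initial angles (psi0 = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DataError, StationarityError, UsageError
from .io import ImuStream

G = 9.81  # m/s^2, reference gravity magnitude

_GIMBAL_GUARD_DEG = 85.0


@dataclass(frozen=True)
class InitialAngles:
    """Stationary attitude estimate, degrees; psi0 is fixed at zero."""

    theta0: float
    phi0: float
    psi0: float = 0.0


@dataclass
class OrientationTrace:
    """Euler angle time series (degrees) on the IMU clock."""

    time: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        n = len(self.time)
        if not (len(self.theta) == len(self.phi) == len(self.psi) == n):
            raise UsageError("orientation channels must share one length")


def _check_stationary(a0: np.ndarray) -> np.ndarray:
    a0 = np.asarray(a0, dtype=float)
    norm = np.linalg.norm(a0)
    if not abs(norm - G) <= 0.5:
        raise StationarityError(
            f"stationary accel norm {norm:.3f} m/s^2 outside {G} +/- 0.5"
        )
    return a0


def initial_angles(a0) -> InitialAngles:
    """Initial attitude from a stationary calibrated accel triplet.

    Evaluates theta0 = -atan2(a_z0, a_x0) and
    phi0 = arctan(a_x0 / sqrt(a_y0^2 + a_z0^2)) in degrees, psi0 = 0.
    """
    ax, ay, az = _check_stationary(a0)
    theta0 = -np.degrees(np.arctan2(az, ax))
    phi0 = np.degrees(np.arctan(ax / np.hypot(ay, az))) if (ay, az) != (0.0, 0.0) else np.sign(ax) * 90.0
    return InitialAngles(theta0=float(theta0), phi0=float(phi0))


def initial_angles_from_gravity(a0) -> InitialAngles:
    """Leveling initial attitude consistent with the Rz.Ry.Rx chain.

    For an attitude R = Ry(phi) @ Rx(theta) the stationary specific force is
    R^T (0, 0, g) = (-g sin(phi), g cos(phi) sin(theta), g cos(phi) cos(theta)),
    so theta = atan2(ay0, az0) and phi = -arctan(ax0 / sqrt(ay0^2 + az0^2))
    recover it exactly. Used by the end-to-end pipeline.
    """
    ax, ay, az = _check_stationary(a0)
    theta0 = np.degrees(np.arctan2(ay, az))
    phi0 = -np.degrees(np.arctan(ax / np.hypot(ay, az))) if (ay, az) != (0.0, 0.0) else -np.sign(ax) * 90.0
    return InitialAngles(theta0=float(theta0), phi0=float(phi0))


def rotation_x(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_y(phi_deg: float) -> np.ndarray:
    p = np.radians(phi_deg)
    c, s = np.cos(p), np.sin(p)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_z(psi_deg: float) -> np.ndarray:
    y = np.radians(psi_deg)
    c, s = np.cos(y), np.sin(y)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_ground(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Shoe-local -> ground rotation, R = Ry(phi) @ Rx(theta)."""
    return rotation_y(phi_deg) @ rotation_x(theta_deg)


def rotation_global(theta_deg: float, phi_deg: float, psi_deg: float) -> np.ndarray:
    """IMU-local -> global rotation, R = Rz(psi) @ Ry(phi) @ Rx(theta)."""
    return rotation_z(psi_deg) @ rotation_y(phi_deg) @ rotation_x(theta_deg)


def accumulate_orientation(imu: ImuStream, init: InitialAngles) -> OrientationTrace:
    """Advance the attitude sequentially from the quaternion stream.

    The per-sample relative rotations q_rel(k) = q_k * q_{k-1}^{-1} are
    composed onto the initial attitude R(theta0, phi0, psi0), and each
    resulting attitude is decomposed into intrinsic z-y-x Euler angles;
    unwrapping keeps the channels free of +/-180 degree jumps. Composing
    the rotations (rather than summing per-step Euler increments) keeps the
    trace exact for arbitrary composed motion: summed increments integrate
    the world angular velocity, which coincides with the Euler-angle rates
    only for single-axis motion, and leaves a rate-independent error
    otherwise.
    """
    quat = np.asarray(imu.quat, dtype=float)
    norms = np.linalg.norm(quat, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise DataError("quaternions must be unit norm")
    # scipy uses scalar-last (x, y, z, w)
    rots = Rotation.from_quat(quat[:, [1, 2, 3, 0]])
    r_init = Rotation.from_euler(
        "ZYX", [init.psi0, init.phi0, init.theta0], degrees=True
    )
    # composed relative rotation from sample 0, applied to the initial pose
    absolute = rots * rots[0].inv() * r_init
    eul = absolute.as_euler("ZYX", degrees=True)  # columns: psi, phi, theta
    psi = np.unwrap(eul[:, 0], period=360.0)
    phi = eul[:, 1]
    theta = np.unwrap(eul[:, 2], period=360.0)
    # re-anchor at the requested initial angles (unwrap can shift by 360)
    psi += init.psi0 - psi[0]
    theta += init.theta0 - theta[0]
    if np.abs(phi).max() > _GIMBAL_GUARD_DEG:
        warnings.warn(
            "orientation |phi| exceeded the 85 deg gimbal guard; the z-y-x "
            "decomposition is ill-conditioned near phi = +/-90 deg",
            RuntimeWarning,
            stacklevel=2,
        )
    return OrientationTrace(time=np.asarray(imu.time, float).copy(),
                            theta=theta, phi=phi, psi=psi)


def write_orientation_trace(path, trace: OrientationTrace) -> None:
    """Export an orientation trace as CSV (time,theta,phi,psi)."""
    import pandas as pd

    pd.DataFrame(
        {"time": trace.time, "theta": trace.theta, "phi": trace.phi,
         "psi": trace.psi}
    ).to_csv(path, index=False, float_format="%.9g")


def interpolate_orientation_to_force_clock(
    orientation: OrientationTrace, force_time
) -> OrientationTrace:
    """Linearly interpolate each angle channel onto the force clock.

    Query times outside the orientation span are clamped to the end values.
    """
    force_time = np.asarray(force_time, dtype=float)
    if force_time.size == 0 or orientation.time.size == 0:
        raise UsageError("empty inputs to orientation interpolation")
    return OrientationTrace(
        time=force_time.copy(),
        theta=np.interp(force_time, orientation.time, orientation.theta),
        phi=np.interp(force_time, orientation.time, orientation.phi),
        psi=np.interp(force_time, orientation.time, orientation.psi),
    )
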