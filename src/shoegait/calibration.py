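"""Six-parameter accelerometer calibration from stationary postures.

The sensor is held still in N >= 6 distinct postures; in each the calibrated
specific-force norm must equal gravity. With per-axis gains g and biases b
the model reads a_cal = g * (a_raw - b), and the parameters minimize

    sum_k ( || g * (a_k - b) || - 9.81 )^2 .

The solver is a damped Gauss-Newton ("Newton iterative optimization")
iteration started from g = (1,1,1), b = (0,0,0): at each step the linearized
normal equations are solved with a Levenberg-style diagonal damping term that
is shrunk after accepted steps and grown until a step reduces the objective.
No cross-axis terms are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConvergenceError, IdentifiabilityError
from .orientation import G


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis gains (dimensionless) and biases (m/s^2)."""

    gain: np.ndarray
    bias: np.ndarray
    residual_rms: float = 0.0
    g_ref: float = G

    def __post_init__(self):
        object.__setattr__(self, "gain", np.asarray(self.gain, dtype=float))
        object.__setattr__(self, "bias", np.asarray(self.bias, dtype=float))
        if self.gain.shape != (3,) or self.bias.shape != (3,):
            raise IdentifiabilityError("gain and bias must be 3-vectors")
        if (self.gain <= 0).any():
            raise IdentifiabilityError("gains must be positive")


IDENTITY_CALIBRATION = CalibrationModel(gain=np.ones(3), bias=np.zeros(3))


@dataclass(frozen=True)
class PostureSet:
    """Stationary accel readings, one row per posture, shape (N, 3)."""

    readings: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "readings", np.atleast_2d(np.asarray(self.readings, dtype=float))
        )
        r = self.readings
        if r.ndim != 2 or r.shape[1] != 3:
            raise IdentifiabilityError("readings must be (N, 3)")
        if r.shape[0] < 6:
            raise IdentifiabilityError(
                f"need >= 6 postures to identify 6 parameters, got {r.shape[0]}"
            )
        # directions must span enough of the sphere for the normal equations
        dirs = r / np.linalg.norm(r, axis=1, keepdims=True)
        if np.linalg.matrix_rank(dirs, tol=1e-6) < 3:
            raise IdentifiabilityError("posture directions are coplanar/collinear")


def _residuals(params: np.ndarray, a: np.ndarray, g_ref: float) -> np.ndarray:
    gain, bias = params[:3], params[3:]
    return np.linalg.norm(gain * (a - bias), axis=1) - g_ref


def _jacobian(params: np.ndarray, a: np.ndarray) -> np.ndarray:
    gain, bias = params[:3], params[3:]
    c = gain * (a - bias)  # (N, 3)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    norm = np.where(norm == 0, 1.0, norm)
    d_gain = c * (a - bias) / norm  # d||c||/d gain_j = c_j (a_j - b_j)/||c||
    d_bias = -c * gain / norm  # d||c||/d bias_j = -c_j g_j/||c||
    return np.hstack([d_gain, d_bias])


def fit_calibration(
    postures: PostureSet,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> CalibrationModel:
    """Fit gains and biases by damped Gauss-Newton.

    Stops when the accepted parameter step norm falls below ``tol``; raises
    :class:`ConvergenceError` (carrying the last iterate) after ``max_iter``
    iterations without meeting it.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    a = postures.readings
    params = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    lam = 1e-3
    r = _residuals(params, a, G)
    cost = float(r @ r)
    for _ in range(max_iter):
        J = _jacobian(params, a)
        JtJ = J.T @ J
        g_vec = J.T @ r
        step = None
        for _try in range(50):
            try:
                step = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ)), -g_vec)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = params + step
            r_trial = _residuals(trial, a, G)
            cost_trial = float(r_trial @ r_trial)
            if cost_trial <= cost:  # accepted: objective non-increasing
                params, r, cost = trial, r_trial, cost_trial
                lam = max(lam / 10.0, 1e-12)
                break
            lam *= 10.0
        else:
            step = np.zeros(6)
        if np.linalg.norm(step) < tol:
            return CalibrationModel(
                gain=params[:3],
                bias=params[3:],
                residual_rms=float(np.sqrt(cost / len(a))),
            )
    raise ConvergenceError(
        f"calibration did not converge in {max_iter} iterations",
        last_model=CalibrationModel(
            gain=params[:3], bias=params[3:],
            residual_rms=float(np.sqrt(cost / len(a))),
        ),
    )


def apply_calibration(model: CalibrationModel, accel) -> np.ndarray:
    """Elementwise a_cal = gain * (a - bias) over an (N, 3) triplet sequence."""
    accel = np.asarray(accel, dtype=float)
    return model.gain * (accel - model.bias)


def write_calibration(path: str | Path, model: CalibrationModel) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "gain": [float(x) for x in model.gain],
                "bias": [float(x) for x in model.bias],
                "residual_rms": float(model.residual_rms),
                "g_ref": float(model.g_ref),
            },
            fh,
            sort_keys=False,
        )


def read_calibration(path: str | Path) -> CalibrationModel:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    return CalibrationModel(
        gain=np.asarray(d["gain"], float),
        bias=np.asarray(d["bias"], float),
        residual_rms=float(d.get("residual_rms", 0.0)),
    )
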