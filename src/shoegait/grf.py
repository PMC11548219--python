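"""Localized ground-reaction-force processing.

Raw shoe-local forces are low-pass filtered (4th-order Butterworth, 50 Hz,
zero-phase), offset-corrected against unloaded swing samples, rotated into
the ground frame with the (theta, phi) angles, segmented into stance phases
with the 15 N total-vertical-force rule, time-normalized to 101 points per
stance (0% heel contact, 100% toe off) and summarized per 10% segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, DataError, OffsetError, UsageError
from .io import ForceStream
from .orientation import OrientationTrace

STANCE_THRESHOLD_N = 15.0  # total vertical force marking stance on/offset
LOWPASS_CUTOFF_HZ = 50.0
MIN_STANCE_S = 0.2  # debounce: discard shorter candidate stances
MIN_SWING_S = 0.1  # debounce: merge stances separated by shorter swings
N_STANCE_POINTS = 101
CONTRIBUTION_EPS_N = 1.0  # |total segment mean| below this -> undefined share


@dataclass
class LocalizedGrf:
    """Ground-frame localized forces, same layout as :class:`ForceStream`.

    Axes: x horizontal-lateral, y horizontal-forward, z vertical.
    """

    time: np.ndarray
    forces: np.ndarray  # (n, 4, 3)

    @property
    def total_vertical(self) -> np.ndarray:
        return self.forces[:, :, 2].sum(axis=1)


@dataclass(frozen=True)
class StancePhase:
    start_idx: int
    end_idx: int  # exclusive of the sample where total Fz drops below 15 N
    duration: float

    def __post_init__(self):
        if self.start_idx >= self.end_idx:
            raise UsageError("stance start must precede its end")


@dataclass
class NormalizedStance:
    """One stance resampled to 101 points per channel.

    ``values`` has shape (4, 3, 101); ``total`` (3, 101) is the sensor sum.
    """

    values: np.ndarray
    total: np.ndarray = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4, 3, N_STANCE_POINTS):
            raise UsageError(f"stance values must be (4, 3, {N_STANCE_POINTS})")
        self.total = self.values.sum(axis=0)


@dataclass
class SegmentSummary:
    """Ten-segment stance summaries.

    ``total_per_mass``: (3, 10) mean total GRF per direction, N/kg.
    ``contributions``: (4, 3, 10) percentage shares, NaN where undefined.
    """

    total_per_mass: np.ndarray
    contributions: np.ndarray


def lowpass_forces(
    force: ForceStream, fs: float | None = None, cutoff: float = LOWPASS_CUTOFF_HZ
) -> ForceStream:
    """Zero-phase 4th-order Butterworth low-pass over all 12 channels."""
    if fs is None:
        fs = force.rate_hz
    if fs <= 2 * cutoff:
        raise ConfigurationError(
            f"sampling rate {fs:.1f} Hz must exceed twice the {cutoff} Hz cutoff"
        )
    b, a = butter(4, cutoff / (fs / 2), btype="low")
    flat = force.forces.reshape(len(force.time), 12)
    filtered = filtfilt(b, a, flat, axis=0)
    return ForceStream(time=force.time.copy(), forces=filtered.reshape(-1, 4, 3))


def remove_offsets(force: ForceStream, swing_mask) -> ForceStream:
    """Subtract each channel's median over unloaded (swing) samples."""
    swing_mask = np.asarray(swing_mask, dtype=bool)
    if swing_mask.shape != force.time.shape:
        raise UsageError("swing mask must match the force time base")
    n_unloaded = int(swing_mask.sum())
    if n_unloaded == 0 or n_unloaded / force.rate_hz < 0.1:
        raise OffsetError("need >= 0.1 s of unloaded samples for offset removal")
    offsets = np.median(force.forces[swing_mask], axis=0)  # (4, 3)
    return ForceStream(time=force.time.copy(), forces=force.forces - offsets)


def unloaded_mask(force: ForceStream, margin_n: float = 10.0) -> np.ndarray:
    """Heuristic swing mask from the raw total vertical force.

    Samples whose summed vertical force sits within ``margin_n`` of the
    20th-percentile baseline are treated as unloaded. Used to bootstrap
    offset removal before stance detection is possible.
    """
    total = force.total_vertical
    baseline = np.percentile(total, 20.0)
    return total < baseline + margin_n


def transform_to_ground(
    force: ForceStream, angles_on_force_clock: OrientationTrace
) -> LocalizedGrf:
    """Rotate each sensor's local force into the ground frame per sample."""
    ang = angles_on_force_clock
    if len(ang.time) != len(force.time):
        raise UsageError("orientation trace is not on the force clock")
    th = np.radians(ang.theta)
    ph = np.radians(ang.phi)
    ct, st = np.cos(th), np.sin(th)
    cp, sp = np.cos(ph), np.sin(ph)
    # R = Ry(phi) @ Rx(theta), batched over samples
    R = np.empty((len(th), 3, 3))
    R[:, 0, 0], R[:, 0, 1], R[:, 0, 2] = cp, sp * st, sp * ct
    R[:, 1, 0], R[:, 1, 1], R[:, 1, 2] = 0.0, ct, -st
    R[:, 2, 0], R[:, 2, 1], R[:, 2, 2] = -sp, cp * st, cp * ct
    rotated = np.einsum("tij,tsj->tsi", R, force.forces)
    return LocalizedGrf(time=force.time.copy(), forces=rotated)


def detect_stance_phases(
    grf: LocalizedGrf,
    threshold_n: float = STANCE_THRESHOLD_N,
    min_stance_s: float = MIN_STANCE_S,
    min_swing_s: float = MIN_SWING_S,
) -> list[StancePhase]:
    """Threshold the summed vertical force at 15 N with debouncing.

    A stance starts at the first sample where the total vertical force
    exceeds the threshold and ends at the first subsequent sample where it
    falls back below. Candidate stances separated by a swing shorter than
    ``min_swing_s`` are merged; stances shorter than ``min_stance_s`` are
    discarded.
    """
    total = grf.total_vertical
    if total.size == 0:
        raise UsageError("empty force signal")
    loaded = total > threshold_n
    edges = np.diff(loaded.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if loaded[0]:
        starts.insert(0, 0)
    if loaded[-1]:
        ends.append(len(total))
    phases = list(zip(starts, ends))
    t = grf.time
    # merge across short swings
    merged: list[list[int]] = []
    for s, e in phases:
        if merged and t[s] - t[min(merged[-1][1], len(t) - 1)] < min_swing_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        duration = t[min(e, len(t) - 1)] - t[s]
        if duration >= min_stance_s:
            out.append(StancePhase(start_idx=s, end_idx=e, duration=float(duration)))
    return out


def normalize_stance(grf: LocalizedGrf, phase: StancePhase) -> NormalizedStance:
    """Resample one stance onto 101 equally spaced points (0%..100%)."""
    last = min(phase.end_idx, len(grf.time)) - 1
    if last - phase.start_idx < 2:
        raise DataError("stance phase spans fewer than 3 samples")
    t = grf.time[phase.start_idx : last + 1]
    pct_times = np.linspace(t[0], t[-1], N_STANCE_POINTS)
    seg = grf.forces[phase.start_idx : last + 1]  # (m, 4, 3)
    values = np.empty((4, 3, N_STANCE_POINTS))
    for i in range(4):
        for d in range(3):
            values[i, d] = np.interp(pct_times, t, seg[:, i, d])
    return NormalizedStance(values=values)


def _segment_means(channel: np.ndarray) -> np.ndarray:
    """Means of samples 1-10, 11-20, ..., 91-100 (sample 0 excluded)."""
    return channel[..., 1:].reshape(*channel.shape[:-1], 10, 10).mean(axis=-1)


def segment_summary(
    stances: list[NormalizedStance], body_mass: float
) -> SegmentSummary:
    """Average mass-normalized total GRF and contribution shares per segment."""
    if not stances:
        raise UsageError("need at least one stance")
    if body_mass <= 0:
        raise UsageError("body mass must be positive")
    totals = np.stack([s.total for s in stances])  # (k, 3, 101)
    total_per_mass = _segment_means(totals).mean(axis=0) / body_mass  # (3, 10)
    contribs = np.stack([contribution_percent(s) for s in stances])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        contributions = np.nanmean(contribs, axis=0)
    return SegmentSummary(total_per_mass=total_per_mass, contributions=contributions)


def contribution_percent(
    stance: NormalizedStance, eps_n: float = CONTRIBUTION_EPS_N
) -> np.ndarray:
    """Per-sensor percentage share of the total, per direction and segment.

    Shares use signed segment means; a segment whose |total mean| < ``eps_n``
    is returned as NaN for every sensor rather than divided.
    """
    sensor_means = _segment_means(stance.values)  # (4, 3, 10)
    total_means = _segment_means(stance.total)  # (3, 10)
    defined = np.abs(total_means) >= eps_n
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = 100.0 * sensor_means / total_means[None]
    shares[:, ~defined] = np.nan
    return shares


def write_normalized_stance(path: str | Path, stance: NormalizedStance) -> None:
    """Export one stance as CSV: pct, fx1..fz4, total_x, total_y, total_z."""
    cols = {"pct": np.arange(N_STANCE_POINTS)}
    for i in range(4):
        for d, axis in enumerate(("fx", "fy", "fz")):
            cols[f"{axis}{i + 1}"] = stance.values[i, d]
    for d, axis in enumerate(("x", "y", "z")):
        cols[f"total_{axis}"] = stance.total[d]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
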