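"""Ocular event detection: blinks, saccades and fixations from raw gaze.

The chain is:

1. convert point-of-gaze to per-sample visual-angle steps (exact
   trigonometry on eye-to-screen vectors, no small-angle shortcut);
2. differentiate the cumulative angle with a Savitzky-Golay smoother
   (default: 19-sample window, order 2) into angular velocity and
   acceleration;
3. blinks = maximal zero-pupil runs, padded and merged;
4. saccades = runs above an adaptive, data-driven peak velocity
   threshold (iterated mean + 6*SD fixed point), with onsets/offsets
   refined to local velocity minima below an onset threshold
   (mean + 3*SD);
5. everything else becomes fixations; too-short events are invalid.

All constants live in :class:`DetectorParams` so tests can pin them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, savgol_filter

from oculofatigue.errors import (
    ConfigurationError,
    IntegrityError,
    SignalError,
)
from oculofatigue.io_gaze import GazeRecording, ScreenGeometry


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def visual_angle_deg(p: np.ndarray, q: np.ndarray, geometry: ScreenGeometry) -> np.ndarray:
    """Visual angle (degrees) subtended at the eye by screen points p and q.

    The eye sits on the normal through the screen center at the viewing
    distance; the angle is computed between the two eye-to-point vectors.
    For two points symmetric about the center and d cm apart this reduces
    to ``2*atan(d / (2*D))``.
    """
    d = geometry.viewing_distance_cm
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    vp = np.column_stack([p, np.full(len(p), d)])
    vq = np.column_stack([q, np.full(len(q), d)])
    dot = np.sum(vp * vq, axis=1)
    cross = np.linalg.norm(np.cross(vp, vq), axis=1)
    ang = np.degrees(np.arctan2(cross, dot))
    return ang if ang.size > 1 else float(ang[0])


# --------------------------------------------------------------------------
# series types
# --------------------------------------------------------------------------

@dataclass
class AngleSeries:
    """Per-sample visual-angle steps and their cumulative sum."""

    timestamps: np.ndarray
    step_deg: np.ndarray        # step_deg[i] = angle between samples i-1 and i; [0] = 0
    cumulative_deg: np.ndarray
    valid: np.ndarray           # False at/next to zero-pupil samples
    geometry: ScreenGeometry
    gaze_xy: np.ndarray

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))


@dataclass
class KinematicsSeries:
    """Smoothed angular velocity/acceleration plus a raw step velocity."""

    timestamps: np.ndarray
    velocity_dps: np.ndarray
    acceleration_dps2: np.ndarray
    raw_velocity_dps: np.ndarray
    valid: np.ndarray
    sampling_rate_hz: float


@dataclass
class PupilSeries:
    timestamps: np.ndarray
    pupil_mm: np.ndarray
    blink_mask: np.ndarray


@dataclass
class OcularEvent:
    """One blink, saccade or fixation with its per-event kinematics."""

    kind: str                      # blink | saccade | fixation
    onset_s: float
    offset_s: float
    onset_idx: int
    offset_idx: int                # inclusive sample index
    amplitude_deg: float = np.nan
    peak_velocity_dps: float = np.nan
    peak_acceleration_dps2: float = np.nan
    peak_deceleration_dps2: float = np.nan
    curvature_deg: float = np.nan
    center_xy_cm: tuple[float, float] | None = None
    partial: bool = False          # truncated by a record boundary

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise IntegrityError(
                f"{self.kind} event offset {self.offset_s} <= onset {self.onset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventSequence:
    """Ordered, non-overlapping events covering a recording.

    ``sample_class`` assigns every sample to exactly one of
    blink/saccade/fixation/invalid (coded 0..3).
    """

    events: list[OcularEvent]
    sample_class: np.ndarray
    timestamps: np.ndarray

    CLASS_CODES = {"blink": 0, "saccade": 1, "fixation": 2, "invalid": 3}

    def of_kind(self, kind: str, include_partial: bool = False) -> list[OcularEvent]:
        return [e for e in self.events
                if e.kind == kind and (include_partial or not e.partial)]

    def class_counts(self) -> dict[str, int]:
        names = ["blink", "saccade", "fixation", "invalid"]
        return {n: int(np.sum(self.sample_class == self.CLASS_CODES[n])) for n in names}


@dataclass(frozen=True)
class DetectorParams:
    """All event-detection constants, exposed for configuration."""

    sg_window_samples: int = 19
    sg_order: int = 2
    pt_init_dps: float = 100.0
    pt_sd_factor: float = 6.0
    onset_sd_factor: float = 3.0
    pt_tolerance_dps: float = 1.0
    pt_max_iter: int = 100
    min_saccade_s: float = 0.010
    min_fixation_s: float = 0.040
    min_blink_s: float = 0.010
    blink_margin_samples: int = 2
    pupil_cutoff_hz: float = 4.0
    pupil_filter_order: int = 3
    min_valid_samples: int = 100
    refine_on: str = "raw"        # "raw" | "smoothed" velocity for onset refinement


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def point_of_gaze_to_angles(recording: GazeRecording) -> AngleSeries:
    """Per-sample visual angle between consecutive points of gaze."""
    geom = recording.geometry
    if geom.viewing_distance_cm <= 0:
        raise ConfigurationError("viewing distance must be positive")
    xy = recording.gaze_xy
    n = len(recording)
    step = np.zeros(n)
    if n > 1:
        step[1:] = visual_angle_deg(xy[:-1], xy[1:], geom)
    closed = recording.pupil_mm == 0
    valid = ~closed
    # a step touching a closed-eye sample on either end is unreliable
    step_valid = valid.copy()
    step_valid[1:] &= valid[:-1]
    step = np.where(step_valid, step, 0.0)
    return AngleSeries(
        timestamps=recording.timestamps,
        step_deg=step,
        cumulative_deg=np.cumsum(step),
        valid=step_valid,
        geometry=geom,
        gaze_xy=xy,
    )


def angular_kinematics(
    angles: AngleSeries,
    window: int = 19,
    order: int = 2,
) -> KinematicsSeries:
    """Savitzky-Golay smoothed derivatives of the cumulative angle series."""
    n = angles.cumulative_deg.size
    if window % 2 == 0 or order >= window:
        raise ConfigurationError(f"window must be odd and > order, got {window}/{order}")
    if n < window:
        raise SignalError(f"series of {n} samples shorter than window {window}; need >= {window}")
    fs = angles.sampling_rate_hz
    dt = 1.0 / fs
    vel = savgol_filter(angles.cumulative_deg, window, order, deriv=1, delta=dt)
    acc = savgol_filter(angles.cumulative_deg, window, order, deriv=2, delta=dt)
    raw = angles.step_deg * fs
    half = window // 2
    valid = angles.valid.copy()
    valid[:half] = False
    valid[n - half:] = False
    # samples whose smoothing window touches an invalid step inherit invalidity
    bad = ~angles.valid
    if bad.any():
        kernel = np.ones(window, dtype=bool)
        spread = np.convolve(bad.astype(int), kernel.astype(int), mode="same") > 0
        valid &= ~spread
    return KinematicsSeries(
        timestamps=angles.timestamps,
        velocity_dps=vel,
        acceleration_dps2=acc,
        raw_velocity_dps=raw,
        valid=valid,
        sampling_rate_hz=fs,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop_inclusive) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_blinks(
    recording: GazeRecording,
    min_duration_s: float = 0.010,
    margin_samples: int = 2,
) -> list[OcularEvent]:
    """Blinks = maximal zero-pupil runs, padded by ``margin_samples`` and merged."""
    n = len(recording)
    t = recording.timestamps
    runs = _runs(recording.pupil_mm == 0)
    padded = []
    for a, b in runs:
        padded.append((max(0, a - margin_samples), min(n - 1, b + margin_samples)))
    merged: list[list[int]] = []
    for a, b in padded:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    events = []
    for a, b in merged:
        onset, offset = float(t[a]), float(t[b]) + _dt_after(t, b)
        if offset - onset < min_duration_s:
            continue
        events.append(OcularEvent(
            kind="blink", onset_s=onset, offset_s=offset,
            onset_idx=a, offset_idx=b,
            partial=(a == 0 or b == n - 1),
        ))
    return events


def _dt_after(t: np.ndarray, i: int) -> float:
    """Duration attributed to sample i (half-open convention)."""
    if i + 1 < t.size:
        return float(t[i + 1] - t[i])
    return float(np.median(np.diff(t))) if t.size > 1 else 0.0


def preprocess_pupil(
    recording: GazeRecording,
    blinks: Sequence[OcularEvent],
    cutoff_hz: float = 4.0,
    filter_order: int = 3,
) -> PupilSeries:
    """Interpolate blink gaps linearly, then zero-phase low-pass filter."""
    pupil = recording.pupil_mm.astype(float).copy()
    t = recording.timestamps
    n = pupil.size
    mask = np.zeros(n, dtype=bool)
    for b in blinks:
        mask[b.onset_idx:b.offset_idx + 1] = True
    mask |= pupil == 0
    if mask.all():
        raise SignalError("all samples are blink samples; no pupil signal")
    good = ~mask
    pupil[mask] = np.interp(t[mask], t[good], pupil[good])
    fs = recording.sampling_rate_hz
    nyq = fs / 2.0
    if cutoff_hz >= nyq:
        raise ConfigurationError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    b, a = butter(filter_order, cutoff_hz / nyq, btype="low")
    padlen = min(3 * max(len(a), len(b)), n - 1)
    filtered = filtfilt(b, a, pupil, padlen=padlen)
    return PupilSeries(timestamps=t, pupil_mm=filtered, blink_mask=mask)


def adaptive_peak_threshold(
    velocities: np.ndarray,
    init_dps: float = 100.0,
    sd_factor: float = 6.0,
    tolerance_dps: float = 1.0,
    max_iter: int = 100,
) -> float:
    """Fixed-point iteration PT <- mean + sd_factor*SD of velocities below PT."""
    v = np.asarray(velocities, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise SignalError("need >= 2 finite velocity samples for thresholding")
    pt = float(init_dps)
    for _ in range(max_iter):
        below = v[v < pt]
        if below.size < 2:
            break
        new = float(np.mean(below) + sd_factor * np.std(below))
        if abs(new - pt) < tolerance_dps:
            pt = new
            break
        pt = new
    return pt


def detect_saccades(
    kinematics: KinematicsSeries,
    blinks: Sequence[OcularEvent],
    params: DetectorParams = DetectorParams(),
    angles: AngleSeries | None = None,
) -> list[OcularEvent]:
    """Adaptive-threshold saccade detection with onset/offset refinement.

    ``angles`` supplies gaze positions for amplitude/curvature; without it
    amplitudes fall back to the integrated angular path.
    """
    v = kinematics.velocity_dps
    valid = kinematics.valid
    n = v.size
    if int(valid.sum()) < params.min_valid_samples:
        raise SignalError(
            f"only {int(valid.sum())} valid samples; need >= {params.min_valid_samples}"
        )
    vv = v[valid]
    pt = adaptive_peak_threshold(
        vv, params.pt_init_dps, params.pt_sd_factor,
        params.pt_tolerance_dps, params.pt_max_iter,
    )
    below = vv[vv < pt]
    onset_thr = float(np.mean(below) + params.onset_sd_factor * np.std(below)) \
        if below.size >= 2 else pt / 2.0

    refine = kinematics.raw_velocity_dps if params.refine_on == "raw" \
        else kinematics.velocity_dps

    blink_mask = np.zeros(n, dtype=bool)
    for b in blinks:
        blink_mask[b.onset_idx:b.offset_idx + 1] = True

    cand = _runs((v > pt) & valid)
    fs = kinematics.sampling_rate_hz
    t = kinematics.timestamps
    events: list[OcularEvent] = []
    for a, b in cand:
        peak_i = a + int(np.argmax(refine[a:b + 1]))
        a2 = _walk_to_minimum(refine, peak_i, -1, onset_thr)
        b2 = _walk_to_minimum(refine, peak_i, +1, onset_thr)
        if blink_mask[a2:b2 + 1].any():
            continue
        onset, offset = float(t[a2]), float(t[b2]) + _dt_after(t, b2)
        if offset - onset < params.min_saccade_s:
            continue
        if events and a2 <= events[-1].offset_idx:
            continue  # refined into the previous event
        events.append(_saccade_event(a2, b2, onset, offset, kinematics, angles))
    return events


def _walk_to_minimum(v: np.ndarray, start: int, direction: int, threshold: float) -> int:
    """Walk from ``start`` in ``direction`` to the first local minimum below ``threshold``.

    A missing neighbour at a record boundary counts as larger, so a
    boundary sample below the threshold terminates the walk.
    """
    n = v.size
    i = start
    while True:
        back = v[i - direction] if 0 <= i - direction < n else np.inf
        fwd = v[i + direction] if 0 <= i + direction < n else np.inf
        if v[i] < threshold and v[i] <= fwd and v[i] <= back:
            return i
        if not 0 <= i + direction < n:
            return i
        i += direction


def _saccade_event(
    a: int, b: int, onset: float, offset: float,
    kin: KinematicsSeries, angles: AngleSeries | None,
) -> OcularEvent:
    sl = slice(a, b + 1)
    peak_v = float(np.max(kin.raw_velocity_dps[sl]))
    acc = kin.acceleration_dps2[sl]
    peak_acc = float(np.max(acc)) if acc.size else np.nan
    peak_dec = float(abs(np.min(acc))) if acc.size else np.nan
    amplitude = np.nan
    curvature = np.nan
    if angles is not None:
        p0, p1 = angles.gaze_xy[a], angles.gaze_xy[b]
        amplitude = float(visual_angle_deg(p0, p1, angles.geometry))
        curvature = _curvature_deg(angles.gaze_xy[sl], angles.geometry)
    else:
        amplitude = float(np.sum(kin.raw_velocity_dps[sl]) / kin.sampling_rate_hz)
    return OcularEvent(
        kind="saccade", onset_s=onset, offset_s=offset,
        onset_idx=a, offset_idx=b,
        amplitude_deg=amplitude, peak_velocity_dps=peak_v,
        peak_acceleration_dps2=peak_acc, peak_deceleration_dps2=peak_dec,
        curvature_deg=curvature,
    )


def _curvature_deg(path_xy: np.ndarray, geometry: ScreenGeometry) -> float:
    """Max perpendicular deviation (deg) of the gaze path from the onset-offset chord."""
    if len(path_xy) < 3:
        return 0.0
    p0, p1 = path_xy[0], path_xy[-1]
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0.0
    rel = path_xy - p0
    dev_cm = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    d = float(np.max(dev_cm))
    return float(np.degrees(2.0 * np.arctan(d / (2.0 * geometry.viewing_distance_cm))))


def segment_events(
    recording: GazeRecording,
    blinks: Sequence[OcularEvent],
    saccades: Sequence[OcularEvent],
    min_fixation_s: float = 0.040,
) -> EventSequence:
    """Assign the complement of blinks+saccades to fixations; build the partition."""
    n = len(recording)
    t = recording.timestamps
    CC = EventSequence.CLASS_CODES
    cls = np.full(n, CC["fixation"], dtype=np.int8)
    occupied = np.zeros(n, dtype=bool)
    labeled = sorted(
        list(blinks) + list(saccades), key=lambda e: e.onset_idx,
    )
    for prev, nxt in zip(labeled, labeled[1:]):
        if nxt.onset_idx <= prev.offset_idx:
            raise IntegrityError(
                f"input events overlap: {prev.kind}[{prev.onset_idx},{prev.offset_idx}] "
                f"and {nxt.kind}[{nxt.onset_idx},{nxt.offset_idx}]"
            )
    for e in labeled:
        cls[e.onset_idx:e.offset_idx + 1] = CC[e.kind]
        occupied[e.onset_idx:e.offset_idx + 1] = True
    # stray zero-pupil samples not claimed by a blink are invalid
    cls[(recording.pupil_mm == 0) & ~occupied] = CC["invalid"]

    events: list[OcularEvent] = list(labeled)
    for a, b in _runs(cls == CC["fixation"]):
        onset, offset = float(t[a]), float(t[b]) + _dt_after(t, b)
        partial = a == 0 or b == n - 1
        if offset - onset < min_fixation_s:
            cls[a:b + 1] = CC["invalid"]
            continue
        center = recording.gaze_xy[a:b + 1].mean(axis=0)
        events.append(OcularEvent(
            kind="fixation", onset_s=onset, offset_s=offset,
            onset_idx=a, offset_idx=b,
            center_xy_cm=(float(center[0]), float(center[1])),
            partial=partial,
        ))
    events.sort(key=lambda e: e.onset_idx)
    return EventSequence(events=events, sample_class=cls, timestamps=t)


def detect_events(
    recording: GazeRecording,
    params: DetectorParams = DetectorParams(),
) -> tuple[EventSequence, PupilSeries, KinematicsSeries]:
    """Convenience wrapper running the full chain on one recording."""
    blinks = detect_blinks(recording, params.min_blink_s, params.blink_margin_samples)
    pupil = preprocess_pupil(recording, blinks, params.pupil_cutoff_hz,
                             params.pupil_filter_order)
    angles = point_of_gaze_to_angles(recording)
    kin = angular_kinematics(angles, params.sg_window_samples, params.sg_order)
    saccades = detect_saccades(kin, blinks, params, angles=angles)
    seq = segment_events(recording, blinks, saccades, params.min_fixation_s)
    return seq, pupil, kin
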