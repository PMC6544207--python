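"""Segment-level oculometric features from events and the pupil series.

Thirty-two features across four families (blink, pupil, fixation,
saccade) plus age and sex.  Features whose defining events are absent
are *missing* (NaN), never zero — except event frequencies, which are
genuinely zero when no event occurred.

Conventions fixed here and surfaced in :class:`FeatureParams`:

* PERCLOS = 100 * closed-eye samples / opened-eye samples (closed over
  *opened*, not total);
* inter-blink and inter-saccade intervals are gaps, previous offset to
  next onset; blink-to-saccade latency likewise offset to onset;
* PDIR uses linear interpolation between order statistics;
* SVA/SDA regressions include an intercept; the slope is reported;
* PH is the circular mean resultant length of the instantaneous-phase
  increments of the mean-removed pupil signal (analytic signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from oculofatigue.errors import ValidationError
from oculofatigue.event_detection import (
    AngleSeries,
    DetectorParams,
    EventSequence,
    OcularEvent,
    PupilSeries,
    angular_kinematics,
    detect_blinks,
    detect_saccades,
    point_of_gaze_to_angles,
    preprocess_pupil,
    segment_events,
    visual_angle_deg,
)
from oculofatigue.io_gaze import GazeRecording, Interval, SessionMeta

logger = logging.getLogger(__name__)

#: Canonical feature order used by every table in the toolkit.
FEATURE_COLUMNS = [
    "BF", "BD", "BGF", "IBI", "LBF", "LBR", "DBF", "BGR", "TBS", "PERCLOS",
    "PD", "PDIR", "PCV", "PH",
    "FF_disp_dist", "FD", "FF", "FF_disp", "FF_dist", "OD", "LFR",
    "SVA", "SCD", "SF", "SPV", "SDA", "SCR", "SA", "SPD", "SPA", "ISI",
    "KPA",
]


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds entering the feature definitions."""

    long_blink_s: float = 0.200
    long_fixation_s: float = 0.900
    ibi_cap_s: float = 20.0
    double_blink_gap_s: float = 0.700
    tbs_cap_s: float = 0.700
    isi_cap_s: float = 0.250
    gaze_shift_deg: float = 2.0
    fixation_pair_gap_s: float = 0.100
    min_saccades_for_slope: int = 3


@dataclass
class SegmentFeatures:
    """The 32 oculometrics + demographics for one segment; NaN = missing."""

    values: dict[str, float] = field(default_factory=dict)
    age: float = np.nan
    sex: str = "F"

    def __post_init__(self) -> None:
        full = {name: np.nan for name in FEATURE_COLUMNS}
        full.update(self.values)
        unknown = set(self.values) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValidationError(f"unknown feature names: {sorted(unknown)}")
        self.values = full

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = dict(self.values)
        row["age"] = self.age
        row["sex"] = self.sex
        return row


def _mean_or_nan(x: Sequence[float]) -> float:
    return float(np.mean(x)) if len(x) else np.nan


def blink_metrics(
    events: EventSequence,
    angles: AngleSeries | None,
    duration_s: float,
    params: FeatureParams = FeatureParams(),
) -> dict[str, float]:
    """BF, BD, BGF, IBI, LBF, LBR, DBF, BGR, TBS, PERCLOS."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    blinks = events.of_kind("blink")
    n = len(blinks)
    out: dict[str, float] = {}
    out["BF"] = n / duration_s
    long_blinks = [b for b in blinks if b.duration_s > params.long_blink_s]
    out["LBF"] = len(long_blinks) / duration_s
    if n == 0:
        out.update(BD=np.nan, IBI=np.nan, LBR=np.nan, BGR=np.nan, TBS=np.nan,
                   DBF=0.0, BGF=0.0)
    else:
        out["BD"] = _mean_or_nan([b.duration_s for b in blinks])
        out["LBR"] = len(long_blinks) / n
        gaps = [nxt.onset_s - prev.offset_s for prev, nxt in zip(blinks, blinks[1:])]
        kept = [g for g in gaps if g <= params.ibi_cap_s]
        out["IBI"] = _mean_or_nan(kept)
        out["DBF"] = sum(g < params.double_blink_gap_s for g in gaps) / duration_s
        shifted = _blinks_with_gaze_shift(events, blinks, angles, params.gaze_shift_deg)
        out["BGF"] = shifted / duration_s
        out["BGR"] = shifted / n
        out["TBS"] = _blink_saccade_latency(events, blinks, params.tbs_cap_s)
    closed = int(np.sum(events.sample_class == EventSequence.CLASS_CODES["blink"]))
    opened = int(np.sum(np.isin(events.sample_class,
                                [EventSequence.CLASS_CODES["saccade"],
                                 EventSequence.CLASS_CODES["fixation"]])))
    out["PERCLOS"] = 100.0 * closed / opened if opened else np.nan
    return out


def _blinks_with_gaze_shift(
    events: EventSequence,
    blinks: list[OcularEvent],
    angles: AngleSeries | None,
    shift_deg: float,
) -> int:
    """Count blinks whose flanking fixation centers differ by > shift_deg."""
    if angles is None:
        return 0
    fixations = events.of_kind("fixation", include_partial=True)
    count = 0
    for b in blinks:
        before = [f for f in fixations if f.offset_s <= b.onset_s]
        after = [f for f in fixations if f.onset_s >= b.offset_s]
        if not before or not after:
            continue
        c0 = np.array(before[-1].center_xy_cm)
        c1 = np.array(after[0].center_xy_cm)
        if visual_angle_deg(c0, c1, angles.geometry) > shift_deg:
            count += 1
    return count


def _blink_saccade_latency(
    events: EventSequence, blinks: list[OcularEvent], cap_s: float
) -> float:
    saccades = events.of_kind("saccade")
    latencies = []
    for b in blinks:
        nxt = [s for s in saccades if s.onset_s >= b.offset_s]
        if nxt:
            lat = nxt[0].onset_s - b.offset_s
            if lat < cap_s:
                latencies.append(lat)
    return _mean_or_nan(latencies)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = np.var(x)
    if vx == 0:
        return np.nan
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def saccade_metrics(
    events: EventSequence,
    duration_s: float,
    params: FeatureParams = FeatureParams(),
) -> dict[str, float]:
    """SF, SCD, SPV, SA, SCR, SPA, SPD, ISI, SVA, SDA."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    sacs = events.of_kind("saccade")
    out: dict[str, float] = {"SF": len(sacs) / duration_s}
    if not sacs:
        out.update(SCD=np.nan, SPV=np.nan, SA=np.nan, SCR=np.nan, SPA=np.nan,
                   SPD=np.nan, ISI=np.nan, SVA=np.nan, SDA=np.nan)
        return out
    out["SCD"] = _mean_or_nan([s.duration_s for s in sacs])
    out["SPV"] = float(np.nanmean([s.peak_velocity_dps for s in sacs]))
    out["SA"] = float(np.nanmean([s.amplitude_deg for s in sacs]))
    out["SCR"] = float(np.nanmean([s.curvature_deg for s in sacs]))
    out["SPA"] = float(np.nanmean([s.peak_acceleration_dps2 for s in sacs]))
    out["SPD"] = float(np.nanmean([s.peak_deceleration_dps2 for s in sacs]))
    gaps = [nxt.onset_s - prev.offset_s for prev, nxt in zip(sacs, sacs[1:])]
    out["ISI"] = _mean_or_nan([g for g in gaps if g < params.isi_cap_s])
    if len(sacs) >= params.min_saccades_for_slope:
        amp = np.array([s.amplitude_deg for s in sacs])
        out["SVA"] = _ols_slope(amp, [s.peak_velocity_dps for s in sacs])
        out["SDA"] = _ols_slope(amp, [s.duration_s for s in sacs])
    else:
        out["SVA"] = np.nan
        out["SDA"] = np.nan
    return out


def fixation_metrics(
    events: EventSequence,
    duration_s: float,
    params: FeatureParams = FeatureParams(),
    angles: AngleSeries | None = None,
) -> dict[str, float]:
    """FF, FD, LFR, FF_disp, FF_dist, FF_disp_dist, OD."""
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    fixes = events.of_kind("fixation")
    out: dict[str, float] = {"FF": len(fixes) / duration_s}
    if not fixes:
        out.update(FD=np.nan, LFR=np.nan, FF_disp=np.nan, FF_dist=np.nan,
                   FF_disp_dist=np.nan, OD=np.nan)
        return out
    out["FD"] = _mean_or_nan([f.duration_s for f in fixes])
    out["LFR"] = 100.0 * sum(f.duration_s > params.long_fixation_s for f in fixes) / len(fixes)
    centers = np.array([f.center_xy_cm for f in fixes])
    centroid = centers.mean(axis=0)
    out["OD"] = float(np.mean(np.linalg.norm(centers - centroid, axis=1)))

    disps, dists, ratios = [], [], []
    for prev, nxt in zip(fixes, fixes[1:]):
        if nxt.onset_s - prev.offset_s > params.fixation_pair_gap_s:
            continue
        disp = float(np.linalg.norm(np.array(nxt.center_xy_cm) - np.array(prev.center_xy_cm)))
        dist = _connecting_path_length(events, prev, nxt, angles)
        disps.append(disp)
        if not math.isnan(dist):
            dists.append(dist)
            if dist > 0:
                ratios.append(disp / dist)
    if len(disps) >= 2:
        out["FF_disp"] = _mean_or_nan(disps)
        out["FF_dist"] = _mean_or_nan(dists)
        out["FF_disp_dist"] = _mean_or_nan(ratios)
    else:
        out["FF_disp"] = np.nan
        out["FF_dist"] = np.nan
        out["FF_disp_dist"] = np.nan
    return out


def _connecting_path_length(
    events: EventSequence,
    prev: OcularEvent,
    nxt: OcularEvent,
    angles: AngleSeries | None,
) -> float:
    """Summed inter-sample gaze path length (cm) over the connecting saccade."""
    if angles is None:
        return np.nan
    sacs = [s for s in events.of_kind("saccade")
            if s.onset_s >= prev.offset_s and s.offset_s <= nxt.onset_s]
    if not sacs:
        return np.nan
    s = sacs[0]
    path = angles.gaze_xy[s.onset_idx:s.offset_idx + 1]
    if len(path) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def pupil_metrics(
    pupil: PupilSeries,
    included_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """PD, PDIR, PCV, PH on the filtered pupil series.

    Blink-mask samples are excluded from PD/PDIR/PCV; PH is computed on
    the contiguous included stretch (interpolated samples retained) so
    the analytic signal stays well defined.
    """
    if included_mask is None:
        included_mask = np.ones(pupil.pupil_mm.size, dtype=bool)
    keep = included_mask & ~pupil.blink_mask
    x = pupil.pupil_mm[keep]
    if x.size < 2:
        return {"PD": np.nan, "PDIR": np.nan, "PCV": np.nan, "PH": np.nan}
    pd_ = float(np.mean(x))
    q25, q75 = np.percentile(x, [25.0, 75.0])  # linear-interpolation quantiles
    pdir = float(q75 - q25)
    pcv = float(np.std(x) / pd_) if pd_ != 0 else np.nan
    y = pupil.pupil_mm[included_mask]
    ph = _phase_concentration(y)
    return {"PD": pd_, "PDIR": pdir, "PCV": pcv, "PH": ph}


def _phase_concentration(x: np.ndarray) -> float:
    """Mean resultant length of instantaneous-phase increments (1 = rhythmic)."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        return np.nan
    centered = x - np.mean(x)
    if np.allclose(centered, 0):
        return np.nan
    phase = np.unwrap(np.angle(hilbert(centered)))
    # drop edge samples where the analytic signal is distorted
    k = max(1, x.size // 50)
    dphi = np.diff(phase)[k:-k] if x.size > 2 * k + 1 else np.diff(phase)
    if dphi.size == 0:
        return np.nan
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def attention_dynamics(events: EventSequence) -> float:
    """Coefficient K: mean z(fixation duration) - z(next saccade amplitude)."""
    fixes = events.of_kind("fixation")
    sacs = events.of_kind("saccade")
    pairs: list[tuple[float, float]] = []
    for f in fixes:
        nxt = [s for s in sacs if s.onset_s >= f.offset_s]
        if nxt:
            pairs.append((f.duration_s, nxt[0].amplitude_deg))
    if len(pairs) < 3:
        return np.nan
    d = np.array([p[0] for p in pairs])
    a = np.array([p[1] for p in pairs])
    if np.std(d) == 0 or np.std(a) == 0:
        return np.nan
    zd = (d - d.mean()) / d.std()
    za = (a - a.mean()) / a.std()
    return float(np.mean(zd - za))


# --------------------------------------------------------------------------
# full-segment extraction
# --------------------------------------------------------------------------

def _mask_from_intervals(t: np.ndarray, intervals: Sequence[Interval]) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for iv in intervals:
        mask |= iv.contains(t)
    return mask


def compute_segment_features(
    recording: GazeRecording,
    segment_index: int,
    meta: SessionMeta,
    detector: DetectorParams = DetectorParams(),
    feature_params: FeatureParams = FeatureParams(),
) -> SegmentFeatures:
    """Run the full chain on the union of one segment's cycle intervals.

    KSS-pause and micro-break samples are excluded *before* any event or
    feature computation, per the masking rule of the protocol.
    """
    cycles = recording.cycle_intervals(segment_index, meta.cycles_per_segment)
    if not cycles:
        raise ValidationError(f"segment {segment_index} has no annotated cycles")
    t = recording.timestamps
    include = _mask_from_intervals(t, cycles)
    exclude = _mask_from_intervals(t, recording.intervals("kss_pause"))
    exclude |= _mask_from_intervals(t, recording.intervals("micro_break"))
    include &= ~exclude
    idx = np.nonzero(include)[0]
    if idx.size == 0:
        raise ValidationError(f"segment {segment_index}: no samples after masking")

    sub = GazeRecording(
        timestamps=t[idx],
        gaze_xy=recording.gaze_xy[idx],
        pupil_mm=recording.pupil_mm[idx],
        geometry=recording.geometry,
        annotations=[],
    )
    duration = float(sum(iv.end_s - iv.start_s for iv in cycles))

    try:
        blinks = detect_blinks(sub, detector.min_blink_s, detector.blink_margin_samples)
        pupil = preprocess_pupil(sub, blinks, detector.pupil_cutoff_hz,
                                 detector.pupil_filter_order)
    except Exception as exc:  # all-blink segment and similar degeneracies
        logger.warning("segment %d: pupil preprocessing failed (%s); features missing",
                       segment_index, exc)
        return SegmentFeatures(values={}, age=meta.age, sex=meta.sex)
    angles = point_of_gaze_to_angles(sub)
    kin = angular_kinematics(angles, detector.sg_window_samples, detector.sg_order)
    saccades = detect_saccades(kin, blinks, detector, angles=angles)
    seq = segment_events(sub, blinks, saccades, detector.min_fixation_s)

    values: dict[str, float] = {}
    values.update(blink_metrics(seq, angles, duration, feature_params))
    values.update(saccade_metrics(seq, duration, feature_params))
    values.update(fixation_metrics(seq, duration, feature_params, angles=angles))
    values.update(pupil_metrics(pupil))
    values["KPA"] = attention_dynamics(seq)
    return SegmentFeatures(values=values, age=meta.age, sex=meta.sex)
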