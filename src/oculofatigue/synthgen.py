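"""Synthetic gaze/pupil recordings and segment datasets with ground truth.

Two paths share one parameterization:

* the **slow path** renders an actual 360 Hz sample stream — an
  alternating fixation/saccade renewal process with raised-cosine
  saccade velocity pulses obeying a linear main sequence, Poisson
  blinks zeroing the pupil, and a slow pupil oscillation — so that the
  detection/extraction chain can be validated against known events;
* the **fast path** emits segment-level feature rows directly from the
  same generating parameters, so classifier-level experiments do not
  pay the rendering cost.

Latent fatigue is a per-segment scalar in [0, 1]; each feature drifts
linearly with it (signs: BF and PERCLOS increase, SF and SVA decrease,
PDIR configurable, others zero by default), and KSS is a monotone map
of latent fatigue plus discretized-logistic ordinal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from oculofatigue.errors import ConfigurationError, ValidationError
from oculofatigue.io_gaze import (
    GazeRecording,
    Interval,
    LabeledDataset,
    ScreenGeometry,
)
from oculofatigue.oculometrics import FEATURE_COLUMNS

DEFAULT_GEOMETRY = ScreenGeometry(viewing_distance_cm=58.0,
                                  screen_width_cm=27.8, screen_height_cm=22.4)


@dataclass(frozen=True)
class PopulationConfig:
    """Ranges from which per-participant baselines are drawn."""

    blink_rate_hz: tuple[float, float] = (0.15, 0.35)
    # kept below ~1.5 Hz so saccadic samples stay a small fraction of the
    # stream; the data-driven velocity threshold needs the below-threshold
    # distribution to be fixation-dominated
    saccade_rate_hz: tuple[float, float] = (0.9, 1.5)
    fixation_sd_s: tuple[float, float] = (0.05, 0.12)
    main_sequence_slope: tuple[float, float] = (35.0, 55.0)
    peak_velocity_noise: tuple[float, float] = (0.0, 10.0)
    pupil_baseline_mm: tuple[float, float] = (3.2, 4.8)
    pupil_osc_amp_mm: tuple[float, float] = (0.1, 0.35)
    pupil_noise_mm: tuple[float, float] = (0.0, 0.03)
    perclos_baseline_pct: tuple[float, float] = (3.0, 8.0)
    gaze_noise_deg: tuple[float, float] = (0.0, 0.05)
    age_years: tuple[float, float] = (20.0, 35.0)
    # fatigue drift spans (per unit latent fatigue), honoring declared signs
    bf_drift_hz: tuple[float, float] = (0.05, 0.15)
    perclos_drift_pct: tuple[float, float] = (2.0, 6.0)
    sf_drift_hz: tuple[float, float] = (-0.6, -0.25)
    sva_drift: tuple[float, float] = (-12.0, -5.0)
    pdir_drift_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"inverted range for {name}: ({lo}, {hi})")


@dataclass
class SyntheticProfile:
    """One participant's generating parameters."""

    participant_id: str
    blink_rate_hz: float
    saccade_rate_hz: float
    fixation_sd_s: float
    main_sequence_slope: float
    peak_velocity_noise: float
    pupil_baseline_mm: float
    pupil_osc_amp_mm: float
    pupil_noise_mm: float
    perclos_baseline_pct: float
    gaze_noise_deg: float
    age: float
    sex: str
    # per-unit-latent-fatigue drifts
    bf_drift_hz: float = 0.1
    perclos_drift_pct: float = 4.0
    sf_drift_hz: float = -0.4
    sva_drift: float = -8.0
    pdir_drift_mm: float = 0.0
    # monotone map latent fatigue -> expected KSS
    kss_intercept: float = 1.5
    kss_gain: float = 7.0
    kss_noise_scale: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blink_rate_hz <= 0 or self.saccade_rate_hz <= 0:
            raise ValidationError("event rates must be positive")
        if self.kss_gain < 0:
            raise ValidationError("KSS map must be non-decreasing in fatigue")

    def at_fatigue(self, f: float) -> dict[str, float]:
        """Generating feature values at latent fatigue level ``f``."""
        return {
            "BF": self.blink_rate_hz + self.bf_drift_hz * f,
            "PERCLOS": self.perclos_baseline_pct + self.perclos_drift_pct * f,
            "SF": max(0.3, self.saccade_rate_hz + self.sf_drift_hz * f),
            "SVA": max(10.0, self.main_sequence_slope + self.sva_drift * f),
            "PD": self.pupil_baseline_mm,
            "PDIR": self.pupil_osc_amp_mm * np.sqrt(2.0) + self.pdir_drift_mm * f,
        }

    def expected_kss(self, f: float) -> float:
        return self.kss_intercept + self.kss_gain * f


@dataclass
class GroundTruth:
    """Everything the generator knows: events, parameters, latent states."""

    events: list[dict] = field(default_factory=list)
    generating_features: dict[str, float] = field(default_factory=dict)
    latent_fatigue: float | list[float] = 0.0
    true_kss: float | list[float] = 0.0


def sample_participant_profile(
    config: PopulationConfig = PopulationConfig(),
    seed: int = 0,
    participant_id: str | None = None,
) -> SyntheticProfile:
    """Draw one participant's baselines from the population ranges."""
    rng = np.random.default_rng(seed)

    def draw(name: str) -> float:
        lo, hi = getattr(config, name)
        return float(rng.uniform(lo, hi))

    return SyntheticProfile(
        participant_id=participant_id or f"P{seed:03d}",
        blink_rate_hz=draw("blink_rate_hz"),
        saccade_rate_hz=draw("saccade_rate_hz"),
        fixation_sd_s=draw("fixation_sd_s"),
        main_sequence_slope=draw("main_sequence_slope"),
        peak_velocity_noise=draw("peak_velocity_noise"),
        pupil_baseline_mm=draw("pupil_baseline_mm"),
        pupil_osc_amp_mm=draw("pupil_osc_amp_mm"),
        pupil_noise_mm=draw("pupil_noise_mm"),
        perclos_baseline_pct=draw("perclos_baseline_pct"),
        gaze_noise_deg=draw("gaze_noise_deg"),
        age=draw("age_years"),
        sex="F" if rng.uniform() < 0.5 else "M",
        bf_drift_hz=draw("bf_drift_hz"),
        perclos_drift_pct=draw("perclos_drift_pct"),
        sf_drift_hz=draw("sf_drift_hz"),
        sva_drift=draw("sva_drift"),
        pdir_drift_mm=draw("pdir_drift_mm"),
        seed=seed,
    )


# --------------------------------------------------------------------------
# slow path: sample-stream rendering
# --------------------------------------------------------------------------

def _angle_to_cm(angle_deg: float, distance_cm: float) -> float:
    """Screen chord length (through center) subtending ``angle_deg``."""
    return 2.0 * distance_cm * np.tan(np.radians(angle_deg) / 2.0)


def synthesize_segment(
    profile: SyntheticProfile,
    fatigue_level: float = 0.0,
    duration_s: float = 200.0,
    fs: float = 360.0,
    seed: int = 0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    start_s: float = 0.0,
    annotate_cycles: int = 0,
) -> tuple[GazeRecording, GroundTruth]:
    """Render one segment's gaze/pupil stream with full ground truth.

    With ``annotate_cycles > 0`` the recording carries that many equal
    ``cycle:<k>`` annotations spanning the segment.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    min_event_s = 2.0 / profile.at_fatigue(fatigue_level)["SVA"]  # saccade duration
    if fs * min_event_s < 4:
        raise ConfigurationError(
            f"fs={fs} Hz renders the shortest saccade with fewer than 4 samples"
        )
    rng = np.random.default_rng(seed)
    gen = profile.at_fatigue(fatigue_level)
    n = int(round(duration_s * fs))
    t = start_s + np.arange(n) / fs
    D = geometry.viewing_distance_cm
    half_w = geometry.screen_width_cm / 2.0 - 2.0
    half_h = geometry.screen_height_cm / 2.0 - 2.0

    # ---- event schedule: alternating fixation / saccade ----
    sac_duration = 2.0 / gen["SVA"]           # raised cosine: T = 2A / (SVA*A)
    fix_mean = max(0.15, 1.0 / gen["SF"] - sac_duration)
    events: list[dict] = []
    xy = np.zeros((n, 2))
    pos = np.array([0.0, 0.0])
    cursor = 0
    fix_start = 0
    while cursor < n:
        fix_dur = max(0.15, rng.normal(fix_mean, profile.fixation_sd_s))
        fix_n = int(round(fix_dur * fs))
        fix_end = min(n, cursor + fix_n)
        xy[cursor:fix_end] = pos
        events.append({
            "kind": "fixation", "onset_idx": fix_start, "offset_idx": fix_end - 1,
            "onset_s": float(t[fix_start]), "offset_s": float(t[fix_end - 1]) + 1 / fs,
            "center_xy": pos.tolist(),
        })
        cursor = fix_end
        if cursor >= n:
            break
        # saccade to a new target inside the usable screen area
        for _ in range(20):
            amp = float(rng.uniform(3.0, 12.0))
            direction = rng.uniform(0, 2 * np.pi)
            step_cm = _angle_to_cm(amp, D)
            target = pos + step_cm * np.array([np.cos(direction), np.sin(direction)])
            if abs(target[0]) < half_w and abs(target[1]) < half_h:
                break
        else:
            target = np.array([0.0, 0.0])
            amp = float(np.degrees(2 * np.arctan(np.linalg.norm(pos - target) / (2 * D))))
        vpeak = gen["SVA"] * amp + rng.normal(0.0, profile.peak_velocity_noise)
        vpeak = max(vpeak, 50.0)
        T = 2.0 * amp / vpeak
        sac_n = max(4, int(round(T * fs)))
        if cursor + sac_n + 20 > n:
            # no room to finish a saccade: extend the last fixation instead
            xy[cursor:] = pos
            events[-1]["offset_idx"] = n - 1
            events[-1]["offset_s"] = float(t[n - 1]) + 1 / fs
            break
        sac_end = min(n, cursor + sac_n)
        # raised-cosine displacement fraction along the straight path
        tau = np.arange(1, sac_end - cursor + 1) / sac_n
        frac = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
        xy[cursor:sac_end] = pos + np.outer(frac, target - pos)
        events.append({
            "kind": "saccade", "onset_idx": cursor, "offset_idx": sac_end - 1,
            "onset_s": float(t[cursor]), "offset_s": float(t[sac_end - 1]) + 1 / fs,
            "amplitude_deg": amp, "peak_velocity_dps": vpeak,
        })
        pos = target
        cursor = sac_end
        fix_start = cursor

    # ---- gaze noise ----
    if profile.gaze_noise_deg > 0:
        noise_cm = _angle_to_cm(profile.gaze_noise_deg, D)
        xy = xy + rng.normal(0.0, noise_cm, size=xy.shape)

    # ---- blinks: Poisson count, placed inside fixation interiors ----
    pupil = np.full(n, profile.pupil_baseline_mm)
    osc_f = 0.2  # Hz, slow pupil oscillation
    pupil = pupil + profile.pupil_osc_amp_mm * np.sin(
        2 * np.pi * osc_f * (t - start_s) + rng.uniform(0, 2 * np.pi))
    if profile.pupil_noise_mm > 0:
        pupil = pupil + rng.normal(0.0, profile.pupil_noise_mm, size=n)

    n_blinks = rng.poisson(gen["BF"] * duration_s)
    perclos_frac = gen["PERCLOS"] / 100.0
    closed_total = duration_s * perclos_frac / (1.0 + perclos_frac)
    mean_bd = closed_total / n_blinks if n_blinks else 0.12
    blink_windows = _place_blinks(
        rng, events, n_blinks, mean_bd, fs, n, guard_s=0.11)
    for a, b in blink_windows:
        pupil[a:b + 1] = 0.0
        events.append({
            "kind": "blink", "onset_idx": a, "offset_idx": b,
            "onset_s": float(t[a]), "offset_s": float(t[b]) + 1 / fs,
        })
    events.sort(key=lambda e: e["onset_idx"])

    annotations: list[Interval] = []
    if annotate_cycles > 0:
        edges = np.linspace(start_s, start_s + duration_s, annotate_cycles + 1)
        annotations = [
            Interval(f"cycle:{k + 1}", float(edges[k]), float(edges[k + 1]))
            for k in range(annotate_cycles)
        ]

    recording = GazeRecording(
        timestamps=t, gaze_xy=xy, pupil_mm=pupil,
        geometry=geometry, annotations=annotations,
    )
    truth = GroundTruth(
        events=events,
        generating_features=gen,
        latent_fatigue=fatigue_level,
        true_kss=profile.expected_kss(fatigue_level),
    )
    return recording, truth


def _place_blinks(rng, events, n_blinks, mean_bd, fs, n, guard_s=0.11):
    """Place blinks in fixation interiors, away from saccades and each other."""
    guard = int(round(guard_s * fs))
    slots = []
    for e in events:
        if e["kind"] != "fixation":
            continue
        a, b = e["onset_idx"] + guard, e["offset_idx"] - guard
        if b > a:
            slots.append((a, b))
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n_blinks and attempts < n_blinks * 50 and slots:
        attempts += 1
        a, b = slots[rng.integers(len(slots))]
        dur = max(0.05, rng.normal(mean_bd, 0.2 * mean_bd))
        w = int(round(dur * fs))
        if b - a <= w:
            continue
        start = int(rng.integers(a, b - w))
        candidate = (start, start + w - 1)
        if any(not (candidate[1] + guard < p[0] or candidate[0] - guard > p[1])
               for p in placed):
            continue
        placed.append(candidate)
    return sorted(placed)


# --------------------------------------------------------------------------
# fast path: dataset-level generation
# --------------------------------------------------------------------------

#: Observation noise of fast-path feature rows, as a fraction of the
#: generating value (keeps classes separable but not degenerate).
FAST_PATH_NOISE = 0.06

_BASELINES = {  # plausible levels for features without declared fatigue drift
    "BD": 0.15, "BGF": 0.05, "IBI": 3.0, "LBF": 0.02, "LBR": 0.1,
    "DBF": 0.02, "BGR": 0.2, "TBS": 0.3,
    "PCV": 0.05, "PH": 0.85,
    "FF_disp_dist": 0.95, "FD": 0.35, "FF": 2.0, "FF_disp": 3.0,
    "FF_dist": 3.2, "OD": 4.0, "LFR": 5.0,
    "SCD": 0.05, "SPV": 300.0, "SDA": 0.004, "SCR": 0.3, "SA": 7.0,
    "SPD": 9000.0, "SPA": 9000.0, "ISI": 0.15, "KPA": 0.0,
}


_NONNEGATIVE = {"BF", "BD", "BGF", "IBI", "LBF", "DBF", "TBS", "PERCLOS",
                "PD", "PDIR", "PCV", "FD", "FF", "FF_disp", "FF_dist",
                "FF_disp_dist", "OD", "SCD", "SF", "SPV", "SCR", "SA",
                "SPD", "SPA", "ISI", "SDA", "SVA"}
_UNIT_RANGE = {"LBR", "BGR", "PH"}


def _clip_feature(name: str, value: float) -> float:
    """Keep fast-path noise inside each feature's declared range."""
    if name in _UNIT_RANGE:
        return float(np.clip(value, 0.0, 1.0))
    if name == "LFR":
        return float(np.clip(value, 0.0, 100.0))
    if name in _NONNEGATIVE:
        return max(0.0, value)
    return value


def _latent_trajectory(rng, n_segments: int) -> np.ndarray:
    """Monotone-in-expectation latent fatigue over segments, in [0, 1]."""
    f0 = rng.uniform(0.0, 0.35)
    f1 = rng.uniform(0.55, 1.0)
    base = f0 + (f1 - f0) * np.arange(n_segments) / max(1, n_segments - 1)
    jitter = rng.normal(0.0, 0.08, size=n_segments)
    return np.clip(base + jitter, 0.0, 1.0)


def _ordinal_kss(rng, expected: float, scale: float) -> int:
    noisy = expected + rng.logistic(0.0, scale)
    return int(np.clip(round(noisy), 1, 10))


def generate_dataset(
    n_participants: int = 38,
    n_segments: int = 12,
    fatigued_fraction: float = 0.45,
    seed: int = 0,
    config: PopulationConfig = PopulationConfig(),
    kss_threshold: int = 5,
) -> tuple[LabeledDataset, GroundTruth]:
    """Fast-path labeled dataset of n_participants x n_segments feature rows.

    The latent-fatigue -> KSS map is calibrated so the expected fraction
    of KSS >= ``kss_threshold`` segments matches ``fatigued_fraction``.
    """
    if n_participants < 2:
        raise ValidationError("need at least 2 participants")
    if not 0.0 < fatigued_fraction < 1.0:
        raise ValidationError("fatigued_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    latents: list[float] = []
    true_kss: list[float] = []

    # calibrate the KSS intercept: with trajectories ~ f0+U ramp, latent
    # fatigue is roughly uniform on [0.2, 0.85]; pick the intercept so
    # that P(round(intercept + gain*f + logistic) >= threshold) matches
    # the target fraction (quick Monte Carlo, generator-internal RNG).
    cal = np.random.default_rng(1234)
    gain = 7.0
    scale = 0.6
    f_samples = np.concatenate(
        [_latent_trajectory(cal, n_segments) for _ in range(200)])
    lo, hi = -2.0, 4.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        kss = mid + gain * f_samples + cal.logistic(0.0, scale, size=f_samples.size)
        frac = np.mean(np.clip(np.round(kss), 1, 10) >= kss_threshold)
        if frac > fatigued_fraction:
            hi = mid
        else:
            lo = mid
    intercept = 0.5 * (lo + hi)

    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        profile = sample_participant_profile(
            config, seed=int(rng.integers(0, 2**31 - 1)), participant_id=pid)
        profile = replace(profile, kss_intercept=intercept,
                          kss_gain=gain, kss_noise_scale=scale)
        traj = _latent_trajectory(rng, n_segments)
        for s, f in enumerate(traj):
            gen = profile.at_fatigue(float(f))
            row: dict[str, object] = {
                "participant_id": pid, "segment_index": s + 1,
                "age": profile.age, "sex": profile.sex,
            }
            for name in FEATURE_COLUMNS:
                base = gen[name] if name in gen else _BASELINES[name]
                sd = abs(base) * FAST_PATH_NOISE + 1e-3
                row[name] = _clip_feature(name, float(base + rng.normal(0.0, sd)))
            kss = _ordinal_kss(rng, profile.expected_kss(float(f)),
                               profile.kss_noise_scale)
            row["kss"] = kss
            rows.append(row)
            latents.append(float(f))
            true_kss.append(profile.expected_kss(float(f)))

    frame = pd.DataFrame(rows)
    dataset = LabeledDataset(frame, kss_threshold=kss_threshold)
    truth = GroundTruth(latent_fatigue=latents, true_kss=true_kss)
    return dataset, truth
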