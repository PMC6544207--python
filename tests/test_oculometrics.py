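import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from oculofatigue.event_detection import (
    DetectorParams,
    EventSequence,
    OcularEvent,
    PupilSeries,
)
from oculofatigue.io_gaze import Interval, SessionMeta
from oculofatigue.oculometrics import (
    FEATURE_COLUMNS,
    FeatureParams,
    SegmentFeatures,
    attention_dynamics,
    blink_metrics,
    compute_segment_features,
    fixation_metrics,
    pupil_metrics,
    saccade_metrics,
)
from oculofatigue.synthgen import synthesize_segment

FS = 360.0


def _seq(events, n_samples=72000):
    """EventSequence wrapper around hand-built events (no sample classes)."""
    cls = np.full(n_samples, EventSequence.CLASS_CODES["fixation"], dtype=np.int8)
    return EventSequence(events=events, sample_class=cls,
                         timestamps=np.arange(n_samples) / FS)


def _blink(onset, dur):
    return OcularEvent(kind="blink", onset_s=onset, offset_s=onset + dur,
                       onset_idx=int(onset * FS), offset_idx=int((onset + dur) * FS))


def _saccade(onset, dur, amplitude=5.0, peak_v=250.0):
    return OcularEvent(kind="saccade", onset_s=onset, offset_s=onset + dur,
                       onset_idx=int(onset * FS), offset_idx=int((onset + dur) * FS),
                       amplitude_deg=amplitude, peak_velocity_dps=peak_v,
                       peak_acceleration_dps2=1e4, peak_deceleration_dps2=1e4,
                       curvature_deg=0.1)


def _fixation(onset, dur, center=(0.0, 0.0)):
    return OcularEvent(kind="fixation", onset_s=onset, offset_s=onset + dur,
                       onset_idx=int(onset * FS), offset_idx=int((onset + dur) * FS),
                       center_xy_cm=center)


class TestBlinkMetrics:
    def test_bf_count_over_duration(self):
        events = _seq([_blink(10 * i, 0.15) for i in range(20)])
        out = blink_metrics(events, None, 200.0)
        assert out["BF"] == pytest.approx(0.1)

    def test_perclos_closed_over_opened(self):
        cls = np.concatenate([
            np.full(900, EventSequence.CLASS_CODES["blink"], dtype=np.int8),
            np.full(8100, EventSequence.CLASS_CODES["fixation"], dtype=np.int8),
        ])
        seq = EventSequence(events=[], sample_class=cls,
                            timestamps=np.arange(9000) / FS)
        out = blink_metrics(seq, None, 25.0)
        assert out["PERCLOS"] == pytest.approx(100 * 900 / 8100, rel=1e-9)
        assert out["PERCLOS"] == pytest.approx(11.1, abs=0.02)

    def test_ibi_excludes_long_intervals(self):
        # blinks at 0, 0.5, 30 s (0.1 s long): gaps 0.4 and 29.4 s
        events = _seq([_blink(0.0, 0.1), _blink(0.5, 0.1), _blink(30.0, 0.1)])
        out = blink_metrics(events, None, 60.0)
        assert out["IBI"] == pytest.approx(0.4)

    def test_long_blink_features(self):
        events = _seq([_blink(0, 0.25), _blink(5, 0.1), _blink(10, 0.3)])
        out = blink_metrics(events, None, 100.0)
        assert out["LBF"] == pytest.approx(2 / 100.0)
        assert out["LBR"] == pytest.approx(2 / 3)

    def test_double_blink_frequency(self):
        # gaps: 0.3 (double), 5.0 (not)
        events = _seq([_blink(0, 0.1), _blink(0.4, 0.1), _blink(5.5, 0.1)])
        out = blink_metrics(events, None, 50.0)
        assert out["DBF"] == pytest.approx(1 / 50.0)

    def test_no_blinks_missing_semantics(self):
        out = blink_metrics(_seq([]), None, 100.0)
        assert out["BF"] == 0.0 and out["LBF"] == 0.0
        assert out["DBF"] == 0.0 and out["BGF"] == 0.0
        for k in ("BD", "IBI", "LBR", "BGR", "TBS"):
            assert math.isnan(out[k])

    def test_tbs_offset_to_onset_capped(self):
        events = _seq([
            _blink(0.0, 0.1), _saccade(0.3, 0.05),       # latency 0.2 < 0.7
            _blink(1.0, 0.1), _saccade(2.5, 0.05),       # latency 1.4 excluded
        ])
        out = blink_metrics(events, None, 10.0)
        assert out["TBS"] == pytest.approx(0.2)


class TestSaccadeMetrics:
    def test_exact_main_sequence_slope(self):
        events = _seq([_saccade(i, 0.05, amplitude=a, peak_v=50.0 * a)
                       for i, a in enumerate([2.0, 5.0, 9.0, 12.0])])
        out = saccade_metrics(events, 100.0)
        assert out["SVA"] == pytest.approx(50.0, abs=1e-9)

    def test_sf(self):
        events = _seq([_saccade(i * 1.5, 0.05) for i in range(120)])
        assert saccade_metrics(events, 200.0)["SF"] == pytest.approx(0.6)

    def test_sda_closed_form(self):
        # amplitudes [2,4,8], durations [0.02,0.03,0.05] -> OLS slope 0.005
        events = _seq([_saccade(0, 0.02, 2.0), _saccade(1, 0.03, 4.0),
                       _saccade(2, 0.05, 8.0)])
        out = saccade_metrics(events, 10.0)
        assert out["SDA"] == pytest.approx(0.005, abs=1e-12)

    def test_no_saccades(self):
        out = saccade_metrics(_seq([]), 10.0)
        assert out["SF"] == 0.0
        for k in ("SCD", "SPV", "SA", "SVA", "SDA", "ISI"):
            assert math.isnan(out[k])

    def test_slopes_need_three_saccades(self):
        events = _seq([_saccade(0, 0.02, 2.0), _saccade(1, 0.03, 4.0)])
        out = saccade_metrics(events, 10.0)
        assert math.isnan(out["SVA"])

    def test_isi_cap(self):
        events = _seq([_saccade(0.0, 0.05), _saccade(0.15, 0.05),
                       _saccade(1.0, 0.05)])
        # gaps: 0.10 (kept), 0.80 (excluded)
        assert saccade_metrics(events, 10.0)["ISI"] == pytest.approx(0.10)


class TestFixationMetrics:
    def test_od_square_corners(self):
        corners = [(-1, -1), (-1, 1), (1, 1), (1, -1)]
        events = _seq([_fixation(5 * i, 0.5, c) for i, c in enumerate(corners)])
        out = fixation_metrics(events, 100.0)
        assert out["OD"] == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_lfr_two_of_three(self):
        events = _seq([_fixation(0, 0.5), _fixation(2, 1.0), _fixation(4, 1.2)])
        out = fixation_metrics(events, 10.0)
        assert out["LFR"] == pytest.approx(100 * 2 / 3)

    def test_pair_gap_excludes_distant_fixations(self):
        events = _seq([
            _fixation(0.0, 0.5, (0, 0)), _fixation(0.55, 0.5, (3, 0)),  # gap 50 ms
            _fixation(2.0, 0.5, (6, 0)),                                # gap 950 ms
            _fixation(2.56, 0.5, (6, 4)),                               # gap 60 ms
        ])
        out = fixation_metrics(events, 10.0)
        assert out["FF_disp"] == pytest.approx((3 + 4) / 2)

    def test_straight_connecting_saccade_unity_ratio(self, geometry, noiseless_profile):
        rec, _ = synthesize_segment(noiseless_profile, duration_s=30.0, seed=9,
                                    geometry=geometry)
        from oculofatigue.event_detection import detect_events
        seq, _, _ = detect_events(rec, DetectorParams(blink_margin_samples=0))
        from oculofatigue.event_detection import point_of_gaze_to_angles
        angles = point_of_gaze_to_angles(rec)
        out = fixation_metrics(seq, 30.0, angles=angles)
        # synthetic saccades are straight lines -> path == chord
        assert out["FF_disp_dist"] == pytest.approx(1.0, abs=0.02)

    def test_single_fixation_missing_pairs(self):
        out = fixation_metrics(_seq([_fixation(0, 1.0)]), 10.0)
        assert math.isnan(out["FF_disp"])
        assert out["FF"] == pytest.approx(0.1)


class TestPupilMetrics:
    def _series(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        mask = np.zeros(values.size, dtype=bool) if mask is None else mask
        return PupilSeries(timestamps=np.arange(values.size) / FS,
                           pupil_mm=values, blink_mask=mask)

    def test_constant(self):
        out = pupil_metrics(self._series(np.full(1000, 4.0)))
        assert out["PD"] == pytest.approx(4.0)
        assert out["PDIR"] == 0.0
        assert out["PCV"] == 0.0
        assert math.isnan(out["PH"])

    def test_pdir_uniform_span(self):
        out = pupil_metrics(self._series(np.linspace(3.0, 5.0, 1001)))
        assert out["PDIR"] == pytest.approx(1.0, abs=1e-9)

    def test_ph_pure_sinusoid(self):
        t = np.arange(7200) / FS
        x = 4.0 + 0.3 * np.sin(2 * np.pi * 0.5 * t)
        out = pupil_metrics(self._series(x))
        assert out["PH"] == pytest.approx(1.0, abs=0.01)

    def test_blink_samples_excluded(self):
        x = np.full(1000, 4.0)
        x[:100] = 99.0  # artifact marked as blink
        mask = np.zeros(1000, dtype=bool)
        mask[:100] = True
        out = pupil_metrics(self._series(x, mask))
        assert out["PD"] == pytest.approx(4.0)


class TestAttentionDynamics:
    def test_degenerate_constant(self):
        events = _seq([x for i in range(4)
                       for x in (_fixation(2 * i, 0.5), _saccade(2 * i + 0.6, 0.05, 5.0))])
        assert math.isnan(attention_dynamics(events))

    def test_alternating_pairs_zero_mean(self):
        # z(durations) == z(amplitudes) pairwise -> KPA = 0
        events = []
        for i, (d, a) in enumerate([(0.2, 2.0), (0.4, 4.0), (0.6, 6.0)]):
            events.append(_fixation(3 * i, d))
            events.append(_saccade(3 * i + d + 0.01, 0.05, a))
        # amplitudes proportional to durations -> identical z-scores
        kpa = attention_dynamics(_seq(events))
        assert kpa == pytest.approx(0.0, abs=1e-12)

    def test_two_value_pairs_oracle(self):
        # durations z = [1,-1] paired with amplitudes z = [-1,1]:
        # mean((1-(-1)), (-1-1)) = 0 by the coefficient-K definition
        events = [
            _fixation(0.0, 0.6), _saccade(0.7, 0.05, 2.0),
            _fixation(1.0, 0.2), _saccade(1.3, 0.05, 8.0),
            _fixation(2.0, 0.6), _saccade(2.7, 0.05, 2.0),
            _fixation(3.0, 0.2), _saccade(3.3, 0.05, 8.0),
        ]
        kpa = attention_dynamics(_seq(events))
        # anti-correlated pairs cancel in the mean: hand computation gives 0
        assert kpa == pytest.approx(0.0, abs=1e-9)

    def test_focal_positive(self):
        # long fixations followed by small saccades -> focal (positive K)
        events = [
            _fixation(0.0, 1.0), _saccade(1.1, 0.05, 2.0),
            _fixation(2.0, 0.9), _saccade(3.0, 0.05, 2.5),
            _fixation(4.0, 0.2), _saccade(4.3, 0.05, 9.0),
            _fixation(5.0, 0.25), _saccade(5.4, 0.05, 8.0),
        ]
        assert attention_dynamics(_seq(events)) > 0


class TestComputeSegmentFeatures:
    def _meta(self):
        return SessionMeta(participant_id="P1", age=30, sex="M",
                           cycle_count=20, cycles_per_segment=20)

    def test_blink_rate_recovery(self, noiseless_profile):
        rec, truth = synthesize_segment(noiseless_profile, duration_s=100.0,
                                        seed=21, annotate_cycles=20)
        feats = compute_segment_features(
            rec, 1, self._meta(), detector=DetectorParams(blink_margin_samples=0))
        bf_true = truth.generating_features["BF"]
        n = bf_true * 100.0
        assert abs(feats["BF"] - bf_true) <= 3 * math.sqrt(n) / 100.0 + 2 / 100.0

    def test_break_content_excluded(self, noiseless_profile):
        rec, _ = synthesize_segment(noiseless_profile, duration_s=100.0,
                                    seed=22, annotate_cycles=20)
        feats_clean = compute_segment_features(
            rec, 1, self._meta(), detector=DetectorParams(blink_margin_samples=0))
        # graft a micro-break stuffed with artificial blinks after the segment
        fs = 360.0
        n_extra = int(25 * fs)
        t_extra = rec.timestamps[-1] + (np.arange(n_extra) + 1) / fs
        pupil_extra = np.full(n_extra, 4.0)
        pupil_extra[:: int(fs)] = 0.0  # blink every second
        rec2 = type(rec)(
            timestamps=np.concatenate([rec.timestamps, t_extra]),
            gaze_xy=np.vstack([rec.gaze_xy, np.zeros((n_extra, 2))]),
            pupil_mm=np.concatenate([rec.pupil_mm, pupil_extra]),
            geometry=rec.geometry,
            annotations=rec.annotations + [
                Interval("micro_break", float(t_extra[0]), float(t_extra[-1]) + 1 / fs)],
        )
        feats_break = compute_segment_features(
            rec2, 1, self._meta(), detector=DetectorParams(blink_margin_samples=0))
        assert feats_break["BF"] == pytest.approx(feats_clean["BF"], abs=1e-12)

    def test_no_cycles_errors(self, still_recording):
        with pytest.raises(Exception, match="no annotated cycles"):
            compute_segment_features(still_recording, 1, self._meta())

    def test_time_translation_invariance(self, noiseless_profile):
        rec0, _ = synthesize_segment(noiseless_profile, duration_s=40.0,
                                     seed=31, annotate_cycles=20, start_s=0.0)
        rec1, _ = synthesize_segment(noiseless_profile, duration_s=40.0,
                                     seed=31, annotate_cycles=20, start_s=500.0)
        det = DetectorParams(blink_margin_samples=0)
        f0 = compute_segment_features(rec0, 1, self._meta(), detector=det)
        f1 = compute_segment_features(rec1, 1, self._meta(), detector=det)
        for name in FEATURE_COLUMNS:
            a, b = f0[name], f1[name]
            if math.isnan(a) and math.isnan(b):
                continue
            assert a == pytest.approx(b, rel=1e-6, abs=1e-9), name


class TestRangeInvariants:
    @settings(max_examples=8, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 10_000), fatigue=st.floats(0.0, 1.0))
    def test_declared_ranges(self, seed, fatigue, noiseless_profile):
        rec, _ = synthesize_segment(noiseless_profile, fatigue_level=fatigue,
                                    duration_s=30.0, seed=seed, annotate_cycles=20)
        meta = SessionMeta(participant_id="P1", age=30, sex="M",
                           cycle_count=20, cycles_per_segment=20)
        feats = compute_segment_features(
            rec, 1, meta, detector=DetectorParams(blink_margin_samples=0))
        for name in ("BF", "SF", "FF", "LBF", "DBF", "BGF"):
            assert feats[name] >= 0
        for name in ("LBR", "BGR"):
            if not math.isnan(feats[name]):
                assert 0 <= feats[name] <= 1
        if not math.isnan(feats["PERCLOS"]):
            assert feats["PERCLOS"] >= 0
        if not math.isnan(feats["LFR"]):
            assert 0 <= feats["LFR"] <= 100
        if not math.isnan(feats["PDIR"]):
            assert feats["PDIR"] >= 0
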