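"""Micro-break session state machine and offline session simulator.

A session is 180 task cycles (~10 s each) split into 20-cycle segments.
After every segment comes a 5-s KSS pause; a 25-s micro-break follows
the pause when triggered.  Two exclusive trigger paths exist:

* **manual** — the user requests a break at any time; the break runs
  after the earliest upcoming KSS pause, and repeated requests within
  one segment collapse to a single break.  The model is never consulted.
* **automatic** — at each segment close the segment's oculometric
  features (pauses/breaks masked out) feed the trained classifier; a
  fatigued prediction schedules the break, an alert one does nothing.
  KSS ratings never enter the trigger.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from oculofatigue.errors import ConfigurationError, ModeError, ValidationError
from oculofatigue.fatigue_model import TrainedModel, predict_segment
from oculofatigue.io_gaze import SessionMeta
from oculofatigue.oculometrics import SegmentFeatures

CYCLE_S = 10.0
KSS_PAUSE_S = 5.0
MICRO_BREAK_S = 25.0


@dataclass
class Phase:
    kind: str          # cycle | kss_pause | micro_break
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class SessionState:
    """Cycle counter, pending requests and the growing timeline."""

    mode: str = "automatic"
    cycle_count: int = 180
    cycles_per_segment: int = 20
    current_cycle: int = 0
    pending_manual_request: bool = False
    kss_log: list[int] = field(default_factory=list)
    break_log: list[tuple[int, str]] = field(default_factory=list)
    timeline: list[Phase] = field(default_factory=list)
    complete: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "automatic"):
            raise ValidationError(f"invalid mode {self.mode!r}")
        if self.cycle_count % self.cycles_per_segment:
            raise ValidationError("cycle_count must be divisible by cycles_per_segment")

    @property
    def n_segments(self) -> int:
        return self.cycle_count // self.cycles_per_segment

    @property
    def current_segment(self) -> int:
        """1-based segment of the last started cycle (0 before the first)."""
        if self.current_cycle == 0:
            return 0
        return (self.current_cycle - 1) // self.cycles_per_segment + 1

    @property
    def clock_s(self) -> float:
        return self.timeline[-1].end_s if self.timeline else 0.0

    @property
    def segment_just_closed(self) -> bool:
        return (self.current_cycle > 0
                and self.current_cycle % self.cycles_per_segment == 0
                and bool(self.timeline)
                and self.timeline[-1].kind == "kss_pause")


def advance_cycle(state: SessionState) -> SessionState:
    """Run one task cycle; append the KSS pause when a segment closes.

    Advancing past the final cycle sets ``complete`` instead of raising.
    """
    if state.complete:
        return state
    if state.current_cycle >= state.cycle_count:
        state.complete = True
        return state
    state.current_cycle += 1
    state.timeline.append(Phase("cycle", state.clock_s, CYCLE_S))
    if state.current_cycle % state.cycles_per_segment == 0:
        state.timeline.append(Phase("kss_pause", state.clock_s, KSS_PAUSE_S))
        segment = state.current_segment
        if state.mode == "manual" and state.pending_manual_request:
            _schedule_break(state, segment, "manual")
            state.pending_manual_request = False
    if state.current_cycle >= state.cycle_count:
        state.complete = True
    return state


def _schedule_break(state: SessionState, segment: int, trigger: str) -> None:
    if state.break_log and state.break_log[-1][0] == segment:
        return  # at most one break per segment boundary
    state.timeline.append(Phase("micro_break", state.clock_s, MICRO_BREAK_S))
    state.break_log.append((segment, trigger))


def request_manual_break(state: SessionState) -> SessionState:
    """Flag a manual break wish; it fires after the earliest upcoming KSS pause."""
    if state.mode != "manual":
        raise ModeError("manual break requests are only valid in manual mode")
    if state.timeline and state.timeline[-1].kind == "kss_pause":
        # request during the pause itself: break follows immediately
        _schedule_break(state, state.current_segment, "manual")
        state.pending_manual_request = False
        return state
    state.pending_manual_request = True
    return state


def auto_trigger(
    state: SessionState,
    features: SegmentFeatures,
    model: TrainedModel,
) -> SessionState:
    """Consult the model at a segment close; schedule the break if fatigued."""
    if state.mode != "automatic":
        raise ModeError("auto_trigger is only valid in automatic mode")
    if model is None:
        raise ConfigurationError("automatic mode requires a trained model")
    if not state.segment_just_closed:
        raise ValidationError("auto_trigger must run immediately after a segment close")
    label, _post = predict_segment(model, features)
    if label == "fatigued":
        _schedule_break(state, state.current_segment, "automatic")
    return state


@dataclass
class SessionLog:
    """Full deterministic record of one simulated session."""

    mode: str
    timeline: list[Phase]
    break_log: list[tuple[int, str]]
    kss_log: list[int]
    predictions: list[dict]
    features_by_segment: dict[int, dict]

    @property
    def total_duration_s(self) -> float:
        return self.timeline[-1].end_s if self.timeline else 0.0

    def to_json(self, **meta) -> str:
        payload = {
            "mode": self.mode,
            "total_duration_s": self.total_duration_s,
            "timeline": [asdict(p) for p in self.timeline],
            "break_log": [list(b) for b in self.break_log],
            "kss_log": self.kss_log,
            "predictions": self.predictions,
            "features_by_segment": {
                str(k): v for k, v in self.features_by_segment.items()},
        }
        payload.update(meta)
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def run_session(
    segment_features: Callable[[int], SegmentFeatures],
    meta: SessionMeta,
    model: TrainedModel | None = None,
    manual_requests: dict[int, int] | None = None,
) -> SessionLog:
    """Drive the state machine over the whole session.

    ``segment_features`` maps a 1-based segment index to that segment's
    features (pause/break samples must already be masked out upstream —
    :func:`oculofatigue.oculometrics.compute_segment_features` does
    this).  ``manual_requests`` maps segment index -> number of clicks
    scripted within that segment.
    """
    state = SessionState(mode=meta.mode, cycle_count=meta.cycle_count,
                         cycles_per_segment=meta.cycles_per_segment)
    if meta.mode == "automatic" and model is None:
        raise ConfigurationError("automatic session needs a model")
    manual_requests = manual_requests or {}
    predictions: list[dict] = []
    features_by_segment: dict[int, dict] = {}

    while not state.complete:
        advance_cycle(state)
        seg = state.current_segment
        if (state.mode == "manual"
                and not state.pending_manual_request
                and seg in manual_requests
                and manual_requests[seg] > 0
                and state.current_cycle % state.cycles_per_segment != 0):
            for _ in range(manual_requests[seg]):   # clicks collapse to one
                request_manual_break(state)
            manual_requests = {k: v for k, v in manual_requests.items() if k != seg}
        if state.current_cycle % state.cycles_per_segment == 0:
            feats = segment_features(seg)
            features_by_segment[seg] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in feats.as_row().items()
            }
            if seg <= len(meta.kss_by_segment):
                state.kss_log.append(meta.kss_by_segment[seg - 1])
            if state.mode == "automatic":
                label, post = predict_segment(model, feats)
                predictions.append({"segment": seg, "label": label,
                                    "posterior": post})
                if label == "fatigued":
                    _schedule_break(state, seg, "automatic")
    return SessionLog(
        mode=state.mode,
        timeline=state.timeline,
        break_log=state.break_log,
        kss_log=state.kss_log,
        predictions=predictions,
        features_by_segment=features_by_segment,
    )
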