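"""Two-stage, risk-adaptive fall detection over a skeleton stream.

Stage 1 raises *potential fall* candidates through five cooperating
processes:

P1   subject detection — the key joints (head, shoulder centre, hip
     centre) must be tracked.
P2   initial assessment — computes speed, height and the fall-risk flag
     over a shared buffer; an outright high velocity (> ``velocity_high``)
     raises a candidate immediately.
P3   risk-adapted detection (high-risk subjects) — recomputes speed at
     every frame (no skip) against a lowered velocity threshold and
     monitors a raised near-floor threshold.
P4   normal detection (low-risk subjects) — near-floor head height with
     an intentional-descent recognizer, plus an acceleration test.
P5   confirmation — a candidate becomes a *confirmed fall* only if,
     within ``confirm_window`` after it, the head reaches and stays near
     the floor (no recovery above ``recovery_height``), the hip
     corroborates, the height trace shows a sustained drop rather than
     the small oscillation of walking/running, and the completed descent
     was not a deliberate (slow) floor transfer.

The intentional-descent recognizer classifies a descent as deliberate
(sitting/lying down) when the monotone height-decrease run lasts at
least ``slow_descent_seconds`` *and* the head's peak descent speed stays
below ``slow_descent_max_speed``; a fall always contains a rapid
collapse phase that violates the speed bound.  Deliberate descents are
sticky: no new candidate opens until the subject rises above
``recovery_height``.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .kinematics import StreamKinematics, compute_kinematics
from .risk import rolling_risk
from .types import KEY_JOINTS, SkeletonFrame, SkeletonStream

__all__ = [
    "EventKind",
    "Process",
    "Branch",
    "DetectionEvent",
    "FrameBuffer",
    "FallDetector",
    "detect_subject",
    "run_detector",
    "events_to_jsonl",
    "events_summary_rows",
]

log = logging.getLogger(__name__)


class EventKind(str, Enum):
    SUBJECT_DETECTED = "subject_detected"
    POTENTIAL_FALL = "potential_fall"
    CONFIRMED_FALL = "confirmed_fall"
    REJECTED_CANDIDATE = "rejected_candidate"


class Process(str, Enum):
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    P5 = "P5"


class Branch(str, Enum):
    WAIT = "wait"
    TO_P3 = "to_P3"
    TO_P4 = "to_P4"
    TO_P5 = "to_P5"


@dataclass
class DetectionEvent:
    kind: EventKind
    t_start: float
    t_end: float
    source_process: Process | None
    evidence: dict = field(default_factory=dict)
    candidate_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "t_start": round(self.t_start, 6),
            "t_end": round(self.t_end, 6),
            "source_process": self.source_process.value if self.source_process else None,
            "candidate_id": self.candidate_id,
            "evidence": self.evidence,
        }


class FrameBuffer:
    """Ring buffer of (frame, kinematic sample, risk factor sample)
    tuples spanning ``buffer_seconds``; oldest evicted first.  Shared by
    all processes in the streaming API."""

    def __init__(self, buffer_seconds: float, fps: float):
        self.capacity = max(2, int(round(buffer_seconds * fps)))
        self._items: deque = deque(maxlen=self.capacity)

    def push(self, frame: SkeletonFrame, kinematic=None, risk_factor=None) -> None:
        self._items.append((frame, kinematic, risk_factor))

    def __len__(self) -> int:
        return len(self._items)

    def frames(self) -> list[SkeletonFrame]:
        return [it[0] for it in self._items]

    def __getitem__(self, i: int):
        return self._items[i]


def detect_subject(frame: SkeletonFrame) -> bool:
    """Process 1: a person is in the scene iff the key joints are tracked."""
    return frame.tracked(*KEY_JOINTS)


def _round_evidence(ev: dict) -> dict:
    out = {}
    for k, v in ev.items():
        if isinstance(v, float):
            out[k] = round(v, 6)
        elif isinstance(v, dict):
            out[k] = _round_evidence(v)
        else:
            out[k] = v
    return out


class FallDetector:
    """Risk-adaptive detector bound to one stream via :meth:`prepare`."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.stream: SkeletonStream | None = None
        self.kin: StreamKinematics | None = None
        self.risk_high: np.ndarray | None = None
        self.process_log: list[tuple[int, str]] = []

    # ------------------------------------------------------------------
    def prepare(self, stream: SkeletonStream) -> "FallDetector":
        self.stream = stream
        self.kin = compute_kinematics(stream, self.config.kinematics)
        self.risk_high = rolling_risk(stream, self.config.risk)
        t = self.kin.timestamps
        hs = self.kin.smooth_heights["head"]
        cfg = self.config.detector
        # signed head descent speed (positive = going down) over a
        # multi-frame baseline — the robust channel the descent-run
        # classifier works on
        w = cfg.descent_window_frames
        ds = np.full(len(t), np.nan)
        if len(t) > w:
            ds[w:] = (hs[:-w] - hs[w:]) / (t[w:] - t[:-w])
        self._descent_speed = ds
        thr = cfg.descent_speed_threshold
        self._descending = np.where(np.isnan(ds), False, ds >= thr)
        self._rising = np.where(np.isnan(ds), False, ds <= -thr)
        self._down_state = False
        self._height_block = None
        self.process_log = []
        return self

    # ------------------------------------------------------------------
    # stage-1 processes
    def initial_assessment(self, i: int) -> Branch:
        """Process 2: branch on speed and the current fall-risk level."""
        kin = self.kin
        cfg = self.config.detector
        if not np.isfinite(kin.speed[i]):
            return Branch.WAIT
        if kin.speed[i] > cfg.velocity_high:
            return Branch.TO_P5
        if self.risk_high[i]:
            return Branch.TO_P3
        return Branch.TO_P4

    def _descent_run(
        self, i: int, forward_limit: int | None = None
    ) -> tuple[float, float, int, int]:
        """The monotone height-decrease run containing frame ``i``.

        Walks backward (and, when ``forward_limit`` is given, forward)
        through frames whose windowed head slope is descending, tolerating
        short flat stretches and stopping at any rising stretch.  Returns
        (duration s, peak descent speed m/s, start index, end index).
        """
        cfg = self.config.detector
        desc, rise = self._descending, self._rising
        t = self.kin.timestamps
        start = i
        j, gap = i, 0
        while j > 0:
            j -= 1
            if rise[j]:
                break
            if desc[j]:
                start, gap = j, 0
            else:
                gap += 1
                if gap > cfg.descent_grace:
                    break
        end = i
        if forward_limit is not None:
            k, gap = i, 0
            while k < forward_limit:
                k += 1
                if rise[k]:
                    break
                if desc[k]:
                    end, gap = k, 0
                else:
                    gap += 1
                    if gap > cfg.descent_grace:
                        break
        duration = float(t[end] - t[start])
        seg = self._descent_speed[start: end + 1]
        peak = float(np.nanmax(seg)) if np.isfinite(seg).any() else 0.0
        return duration, max(peak, 0.0), start, end

    def _is_deliberate_descent(
        self, i: int, forward_limit: int | None = None
    ) -> tuple[bool, dict]:
        cfg = self.config.detector
        duration, peak, start, end = self._descent_run(i, forward_limit)
        deliberate = (
            duration >= cfg.slow_descent_seconds
            and peak < cfg.slow_descent_max_speed
        )
        return deliberate, {
            "descent_duration": duration,
            "descent_peak_speed": peak,
            "descent_start_frame": int(start),
            "descent_end_frame": int(end),
        }

    def _height_rule_gate(self, i: int, h: float, threshold: float) -> dict | None:
        """Shared activity gate for the near-floor rules of P3 and P4.

        While the descent is still in progress its peak speed cannot be
        known, so the candidate is always raised and the completed
        descent is judged at confirmation time; a descent that has
        already come to rest is classified immediately.  Returns the
        trigger evidence, or None when the frame is gated."""
        if self._height_block is not None and h < self._height_block:
            return None
        ev: dict = {}
        if not self._descending[i]:
            deliberate, ev = self._is_deliberate_descent(i)
            if deliberate:
                self._enter_down_state(i, ev)
                return None
        return {"head_height": float(h), "threshold": threshold, **ev}

    def risk_adapted_detection(self, i: int) -> dict | None:
        """Process 3: finer-grained speed at a lowered threshold, plus a
        raised near-floor threshold, both gated by the shared
        intentional-descent recognizer."""
        cfg = self.config.detector
        kin = self.kin
        v_thr = cfg.velocity_high * cfg.risk_velocity_factor
        h_thr = cfg.near_floor_height * cfg.risk_floor_factor
        if np.isfinite(kin.fine_speed[i]) and kin.fine_speed[i] > v_thr:
            return {
                "rule": "sensitive_velocity",
                "fine_speed": float(kin.fine_speed[i]),
                "threshold": v_thr,
            }
        h = kin.smooth_heights["head"][i]
        if np.isfinite(h) and h < h_thr:
            ev = self._height_rule_gate(i, h, h_thr)
            if ev is not None:
                return {"rule": "raised_near_floor", **ev}
        return None

    def normal_detection(self, i: int) -> dict | None:
        """Process 4: near-floor height (unless the descent is a
        recognized deliberate activity) or high acceleration."""
        cfg = self.config.detector
        kin = self.kin
        h = kin.smooth_heights["head"][i]
        near_floor = np.isfinite(h) and h < cfg.near_floor_height
        high_accel = (
            np.isfinite(kin.acceleration[i])
            and kin.acceleration[i] > cfg.acceleration_high
        )
        if not (near_floor or high_accel):
            return None
        if near_floor:
            ev = self._height_rule_gate(i, float(h), cfg.near_floor_height)
            if ev is not None:
                return {"rule": "near_floor", **ev}
            # gated while down: the acceleration test is suppressed too
            return None
        if not self._descending[i]:
            deliberate, ev = self._is_deliberate_descent(i)
            if deliberate:
                return None
        return {
            "rule": "high_acceleration",
            "acceleration": float(kin.acceleration[i]),
            "threshold": cfg.acceleration_high,
        }

    # ------------------------------------------------------------------
    # stage 2
    def confirm_fall(self, i0: int, i1: int) -> tuple[EventKind, dict]:
        """Process 5: confirm or reject a candidate over frames
        [i0, i1]."""
        cfg = self.config.detector
        kin = self.kin
        t = kin.timestamps
        hs = kin.smooth_heights["head"]
        win = hs[i0: i1 + 1]
        ev: dict = {}

        finite = np.isfinite(win)
        below = finite & (win < cfg.near_floor_height)
        diffs = np.diff(win[finite]) if finite.sum() > 1 else np.array([])
        signs = np.sign(diffs[np.abs(diffs) > 1e-4])
        ev["height_sign_changes"] = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0

        if not below.any():
            ev["reason"] = "no_near_floor"
            ev["min_head_height"] = float(np.nanmin(win)) if finite.any() else None
            return EventKind.REJECTED_CANDIDATE, ev
        first_below = i0 + int(np.argmax(below))
        after = hs[first_below: i1 + 1]
        if np.nanmax(after) > cfg.recovery_height:
            ev["reason"] = "recovered"
            ev["max_height_after_floor"] = float(np.nanmax(after))
            return EventKind.REJECTED_CANDIDATE, ev

        hip = kin.smooth_heights.get("hip_center")
        tail = max(i1 - int(round(0.3 * self.stream.fps)), first_below)
        hip_end = float(np.nanmedian(hip[tail: i1 + 1])) if hip is not None else np.nan
        ev["hip_height_end"] = hip_end if np.isfinite(hip_end) else None
        if np.isfinite(hip_end) and hip_end >= cfg.recovery_height:
            ev["reason"] = "hip_not_down"
            return EventKind.REJECTED_CANDIDATE, ev

        lb = max(0, i0 - int(round(cfg.descent_lookback * self.stream.fps)))
        pre = hs[lb: first_below + 1]
        drop = float(np.nanmax(pre) - np.nanmin(after))
        ev["net_drop"] = drop
        if drop < cfg.fluctuation_amp:
            ev["reason"] = "oscillation_no_drop"
            return EventKind.REJECTED_CANDIDATE, ev

        # completed-descent recheck: a slow deliberate floor transfer is
        # not a fall even if it put the head near the floor
        deliberate, dev = self._is_deliberate_descent(first_below, forward_limit=i1)
        ev.update(dev)
        if deliberate:
            ev["reason"] = "deliberate_descent"
            self._enter_down_state(i1, dev)
            return EventKind.REJECTED_CANDIDATE, ev

        ev["reason"] = "sustained_drop_no_recovery"
        return EventKind.CONFIRMED_FALL, ev

    # ------------------------------------------------------------------
    def _enter_down_state(self, i: int, ev: dict) -> None:
        if not self._down_state:
            log.debug("deliberate descent recognized at frame %d: %s", i, ev)
        self._down_state = True

    def _stage1_trigger(self, i: int) -> tuple[Process, dict] | None:
        branch = self.initial_assessment(i)
        if branch is Branch.WAIT:
            return None
        if branch is Branch.TO_P5:
            self.process_log.append((i, "P2"))
            return Process.P2, {
                "rule": "high_velocity",
                "speed": float(self.kin.speed[i]),
                "threshold": self.config.detector.velocity_high,
            }
        if branch is Branch.TO_P3:
            self.process_log.append((i, "P3"))
            trig = self.risk_adapted_detection(i)
            return (Process.P3, trig) if trig else None
        self.process_log.append((i, "P4"))
        trig = self.normal_detection(i)
        return (Process.P4, trig) if trig else None

    def run(self) -> list[DetectionEvent]:
        """Drive the five processes over the prepared stream and return
        the time-ordered event sequence."""
        if self.kin is None:
            raise RuntimeError("call prepare(stream) first")
        cfg = self.config.detector
        kin = self.kin
        t = kin.timestamps
        n = len(t)
        hs = kin.smooth_heights["head"]
        fps = self.stream.fps

        events: list[DetectionEvent] = []
        self._down_state = False
        self._height_block = None
        open_cand: dict | None = None
        next_id = 0
        subject_seen = False

        for i in range(n):
            if not kin.subject[i]:
                continue
            if not subject_seen:
                subject_seen = True
                events.append(
                    DetectionEvent(
                        EventKind.SUBJECT_DETECTED, t[i], t[i], None,
                        {"frame_index": int(self.stream[i].frame_index)},
                    )
                )
            if self._down_state and np.isfinite(hs[i]) and hs[i] > cfg.recovery_height:
                self._down_state = False
            if self._height_block is not None and np.isfinite(hs[i]) and hs[i] >= self._height_block:
                self._height_block = None

            if open_cand is not None:
                # a new speed spike during an open window extends it
                if np.isfinite(kin.speed[i]) and kin.speed[i] > cfg.velocity_high:
                    open_cand["window_end"] = t[i] + cfg.confirm_window
                    open_cand["extensions"] += 1
                if t[i] >= open_cand["window_end"] or i == n - 1:
                    resolved = t[i] >= open_cand["window_end"]
                    kind, ev = self.confirm_fall(open_cand["i0"], i)
                    self.process_log.append((i, "P5"))
                    if not resolved:
                        ev["window_truncated"] = True
                        open_cand["event"].evidence["unresolved"] = not bool(
                            kind is EventKind.CONFIRMED_FALL
                        )
                    if open_cand["extensions"]:
                        ev["window_extensions"] = open_cand["extensions"]
                    events.append(
                        DetectionEvent(
                            kind, open_cand["t0"], t[i], Process.P5,
                            _round_evidence(ev), open_cand["id"],
                        )
                    )
                    if kind is EventKind.CONFIRMED_FALL:
                        # the subject is on the floor: no re-candidacy
                        # until they rise above recovery height
                        self._down_state = True
                    elif open_cand["event"].evidence.get("rule") in (
                        "near_floor", "raised_near_floor"
                    ):
                        # don't re-raise the same height trigger until the
                        # head rises back above it
                        self._height_block = open_cand["event"].evidence.get("threshold")
                    open_cand = None
                continue

            if self._down_state:
                continue
            trig = self._stage1_trigger(i)
            if trig is None:
                continue
            source, ev = trig
            cand = DetectionEvent(
                EventKind.POTENTIAL_FALL, t[i], t[i], source,
                _round_evidence(ev), next_id,
            )
            events.append(cand)
            open_cand = {
                "id": next_id,
                "i0": i,
                "t0": t[i],
                "window_end": t[i] + cfg.confirm_window,
                "extensions": 0,
                "event": cand,
            }
            next_id += 1

        if not subject_seen:
            log.info("no subject detected in stream; no events emitted")
        return events


def run_detector(
    stream: SkeletonStream, config: PipelineConfig | None = None
) -> list[DetectionEvent]:
    """Run the full two-stage algorithm on a stream.

    Deterministic given stream + config; events are time-ordered and
    every confirmed fall traces back to exactly one potential-fall
    candidate.
    """
    return FallDetector(config).prepare(stream).run()


def events_to_jsonl(events: list[DetectionEvent], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict(), sort_keys=True) + "\n")
    return path


def events_summary_rows(events: list[DetectionEvent]) -> list[dict]:
    """One flat row per event, for the summary CSV export."""
    return [
        {
            "kind": e.kind.value,
            "t_start": round(e.t_start, 6),
            "t_end": round(e.t_end, 6),
            "source_process": e.source_process.value if e.source_process else "",
            "candidate_id": "" if e.candidate_id is None else e.candidate_id,
            "reason": e.evidence.get("reason", e.evidence.get("rule", "")),
        }
        for e in events
    ]
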