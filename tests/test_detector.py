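"""Two-stage detection: processes, candidate lifecycle, end-to-end."""

import json

import numpy as np
import pytest

from fallsense.config import PipelineConfig, with_detector
from fallsense.detector import (
    Branch,
    EventKind,
    FallDetector,
    FrameBuffer,
    detect_subject,
    run_detector,
)
from fallsense.simulator import GAIT_PRESETS, MotionScript, Segment, simulate
from fallsense.types import FloorPlane, JointPosition, SkeletonFrame, SkeletonStream


def _kinds(events):
    return [e.kind for e in events]


def _count(events, kind):
    return sum(e.kind is kind for e in events)


def _stream(segments, gait="normal", seed=5, axis="x"):
    script = MotionScript(
        segments=tuple(segments), gait=GAIT_PRESETS[gait], seed=seed, axis=axis
    )
    return simulate(script)[0]


class TestSubjectDetection:
    FLOOR = FloorPlane(0, 1, 0, 0.91)

    def _frame(self, joints):
        return SkeletonFrame(0, 0.0, joints, self.FLOOR)

    def test_key_joints_tracked(self):
        joints = {
            "head": JointPosition(0, 0.6, 2),
            "shoulder_center": JointPosition(0, 0.4, 2),
            "hip_center": JointPosition(0, 0.0, 2),
        }
        assert detect_subject(self._frame(joints))

    def test_missing_head_not_detected(self):
        joints = {
            "head": JointPosition.untracked(),
            "shoulder_center": JointPosition(0, 0.4, 2),
            "hip_center": JointPosition(0, 0.0, 2),
        }
        assert not detect_subject(self._frame(joints))

    def test_empty_joint_map_not_detected(self):
        assert not detect_subject(self._frame({}))


class TestFrameBuffer:
    def test_capacity_and_eviction(self):
        buf = FrameBuffer(buffer_seconds=1.0, fps=30.0)
        floor = FloorPlane(0, 1, 0, 0.91)
        for i in range(40):
            buf.push(SkeletonFrame(i, i / 30, {}, floor))
        assert len(buf) == 30
        assert buf.frames()[0].frame_index == 10  # oldest evicted first


class TestBranching:
    def test_high_speed_routes_to_confirmation(self):
        stream = _stream([Segment("walk", 2.0), Segment("run", 2.0)])
        det = FallDetector().prepare(stream)
        i = int(np.nanargmax(det.kin.speed))
        assert det.kin.speed[i] > 2.0
        assert det.initial_assessment(i) is Branch.TO_P5

    def test_high_risk_routes_to_sensitive_path(self):
        stream = _stream([Segment("walk", 8.0)], gait="weak")
        det = FallDetector().prepare(stream)
        i = len(stream) - 10
        assert det.risk_high[i]
        assert det.initial_assessment(i) is Branch.TO_P3

    def test_low_risk_low_speed_routes_to_normal_path(self):
        stream = _stream([Segment("walk", 8.0)], gait="normal")
        det = FallDetector().prepare(stream)
        i = len(stream) - 10
        assert det.initial_assessment(i) is Branch.TO_P4

    def test_insufficient_buffer_waits(self):
        stream = _stream([Segment("stand", 2.0)])
        det = FallDetector().prepare(stream)
        assert det.initial_assessment(0) is Branch.WAIT

    def test_sensitive_path_lowers_velocity_threshold(self):
        """A stumble firing under 1.5 m/s alarms on the high-risk path
        but not through P4's velocity tests on the low-risk path."""
        stream = _stream([Segment("walk", 8.0)], gait="weak", seed=9)
        det = FallDetector().prepare(stream)
        i = len(stream) - 20
        # synthesize a moderate spike on the fine-grained channel
        det.kin.fine_speed[i] = 1.7
        trig = det.risk_adapted_detection(i)
        assert trig is not None and trig["rule"] == "sensitive_velocity"
        det2 = FallDetector().prepare(_stream([Segment("walk", 8.0)], seed=9))
        det2.kin.fine_speed[i] = 1.7
        assert det2.normal_detection(i) is None


class TestScenarios:
    def test_walk_fall_lie_confirms_exactly_one_fall(self, fall_stream, config):
        events = run_detector(fall_stream[0], config)
        assert _count(events, EventKind.CONFIRMED_FALL) == 1

    def test_fast_fall_confirmed(self):
        stream = _stream(
            [Segment("walk", 2.5), Segment("fall_forward", 1.3), Segment("lie_floor", 3.0)]
        )
        assert _count(run_detector(stream), EventKind.CONFIRMED_FALL) == 1

    def test_fall_from_chair_confirmed(self):
        stream = _stream([
            Segment("stand", 1.5),
            Segment("sit_chair", 2.5, {"transition": 2.0}),
            Segment("fall_from_chair", 1.2),
            Segment("lie_floor", 3.0),
        ])
        assert _count(run_detector(stream), EventKind.CONFIRMED_FALL) == 1

    def test_collapse_while_sitting_down_confirmed(self):
        stream = _stream([
            Segment("walk", 2.5),
            Segment("fall_while_sitting_down", 2.2),
            Segment("lie_floor", 3.0),
        ])
        assert _count(run_detector(stream), EventKind.CONFIRMED_FALL) == 1

    def test_slow_lying_down_not_confirmed(self, adl_stream, config):
        events = run_detector(adl_stream[0], config)
        assert _count(events, EventKind.CONFIRMED_FALL) == 0

    def test_slow_lying_down_high_risk_subject_not_confirmed(self):
        stream = _stream(
            [Segment("walk", 3.0), Segment("lie_floor", 7.0, {"transition": 3.8})],
            gait="weak",
        )
        assert _count(run_detector(stream), EventKind.CONFIRMED_FALL) == 0

    def test_running_speed_spike_rejected_by_height_pattern(self):
        stream = _stream([Segment("walk", 2.0), Segment("run", 3.0), Segment("walk", 2.0)])
        events = run_detector(stream)
        assert _count(events, EventKind.CONFIRMED_FALL) == 0
        rejected = [e for e in events if e.kind is EventKind.REJECTED_CANDIDATE]
        assert rejected and all(
            e.evidence["reason"] == "no_near_floor" for e in rejected
        )

    def test_sitting_on_chair_never_near_floor(self):
        stream = _stream([
            Segment("walk", 2.5), Segment("sit_chair", 5.0, {"transition": 2.0})
        ])
        events = run_detector(stream)
        assert _count(events, EventKind.CONFIRMED_FALL) == 0

    def test_picking_object_not_a_fall(self):
        stream = _stream([
            Segment("walk", 2.5), Segment("pick_object", 3.0), Segment("walk", 2.5)
        ])
        assert _count(run_detector(stream), EventKind.CONFIRMED_FALL) == 0

    def test_empty_stream_no_events(self):
        floor = FloorPlane(0, 1, 0, 0.91)
        frames = [SkeletonFrame(i, i / 30, {}, floor) for i in range(30)]
        events = run_detector(SkeletonStream(frames, metadata={"fps": 30}))
        assert events == []


class TestLifecycleInvariants:
    def test_confirmed_traces_to_candidate(self, fall_stream, config):
        events = run_detector(fall_stream[0], config)
        confirmed = [e for e in events if e.kind is EventKind.CONFIRMED_FALL]
        candidates = {e.candidate_id for e in events if e.kind is EventKind.POTENTIAL_FALL}
        assert confirmed
        for e in confirmed:
            assert e.candidate_id in candidates

    def test_confirmations_never_exceed_candidates(self, suite_results):
        _, events_by_seq = suite_results
        for events in events_by_seq.values():
            assert _count(events, EventKind.CONFIRMED_FALL) <= _count(
                events, EventKind.POTENTIAL_FALL
            )

    def test_events_time_ordered(self, suite_results):
        _, events_by_seq = suite_results
        for events in events_by_seq.values():
            starts = [e.t_start for e in events]
            assert starts == sorted(starts)

    def test_deterministic_event_log(self, fall_stream, config):
        e1 = run_detector(fall_stream[0], config)
        e2 = run_detector(fall_stream[0], config)
        s1 = "\n".join(json.dumps(e.to_dict(), sort_keys=True) for e in e1)
        s2 = "\n".join(json.dumps(e.to_dict(), sort_keys=True) for e in e2)
        assert s1 == s2

    def test_lower_velocity_threshold_never_fewer_candidates(self, fall_stream):
        stream = fall_stream[0]
        base = with_detector(PipelineConfig(), velocity_high=2.0)
        low = with_detector(PipelineConfig(), velocity_high=1.2)
        n_base = _count(run_detector(stream, base), EventKind.POTENTIAL_FALL)
        n_low = _count(run_detector(stream, low), EventKind.POTENTIAL_FALL)
        assert n_low >= n_base

    def test_all_three_branches_exercised_on_suite(self):
        procs = set()
        for segments, gait in [
            ([Segment("walk", 2.0), Segment("fall_forward", 1.5), Segment("lie_floor", 2.5)], "normal"),
            ([Segment("walk", 6.0)], "weak"),
            ([Segment("walk", 2.0), Segment("run", 2.0)], "normal"),
        ]:
            det = FallDetector().prepare(_stream(segments, gait=gait))
            det.run()
            procs |= {p for _, p in det.process_log}
        assert {"P2", "P3", "P4", "P5"} <= procs
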