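"""Domain types, on-disk formats and the accelerometer adapter."""

import math

import numpy as np
import pytest

from fallsense.io import (
    height_series_from_acceleration,
    read_accelerometer_csv,
    read_skeleton_csv,
    read_skeleton_jsonl,
    write_skeleton_csv,
    write_skeleton_jsonl,
)
from fallsense.simulator import GAIT_PRESETS, MotionScript, Segment, simulate
from fallsense.types import (
    AccelerationSeries,
    FloorPlane,
    FormatError,
    JointPosition,
    SkeletonFrame,
    SkeletonStream,
    TrackingState,
    ValidationError,
)


def _streams_equal(a: SkeletonStream, b: SkeletonStream, tol=1e-6) -> bool:
    if len(a) != len(b):
        return False
    for fa, fb in zip(a, b):
        if fa.frame_index != fb.frame_index or abs(fa.timestamp - fb.timestamp) > tol:
            return False
        for name in fa.joints:
            ja, jb = fa.joint(name), fb.joint(name)
            if ja.tracking_state != jb.tracking_state:
                return False
            if ja.usable and max(
                abs(ja.x - jb.x), abs(ja.y - jb.y), abs(ja.z - jb.z)
            ) > tol:
                return False
    return True


class TestTypes:
    def test_joint_requires_finite_coordinates_when_tracked(self):
        with pytest.raises(ValidationError):
            JointPosition(math.nan, 0.0, 1.0, TrackingState.TRACKED)
        # untracked joints may carry NaN placeholders
        assert not JointPosition.untracked().usable

    def test_floor_plane_rejects_degenerate_normal_and_negative_height(self):
        with pytest.raises(ValidationError):
            FloorPlane(0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValidationError):
            FloorPlane(0.0, 1.0, 0.0, -0.5)

    def test_stream_requires_increasing_timestamps(self):
        floor = FloorPlane(0, 1, 0, 0.91)
        j = {"head": JointPosition(0, 0.6, 2.0)}
        f0 = SkeletonFrame(0, 0.0, j, floor)
        f1 = SkeletonFrame(1, -0.1, j, floor)
        with pytest.raises(ValidationError):
            SkeletonStream([f0, f1])

    def test_stream_flags_frame_gaps(self):
        floor = FloorPlane(0, 1, 0, 0.91)
        j = {"head": JointPosition(0, 0.6, 2.0)}
        frames = [
            SkeletonFrame(i, t, j, floor)
            for i, t in enumerate([0.0, 1 / 30, 0.5, 0.5 + 1 / 30])
        ]
        stream = SkeletonStream(frames, metadata={"fps": 30})
        assert stream.gap_indices() == [2]

    def test_acceleration_series_length_mismatch(self):
        with pytest.raises(ValidationError):
            AccelerationSeries([0.0, 0.1], [9.8])


class TestSkeletonRoundTrip:
    @pytest.mark.parametrize("writer,reader", [
        (write_skeleton_csv, read_skeleton_csv),
        (write_skeleton_jsonl, read_skeleton_jsonl),
    ])
    def test_simulator_output_round_trips(self, tmp_path, writer, reader):
        script = MotionScript(
            segments=(Segment("walk", 1.0),), gait=GAIT_PRESETS["normal"], seed=3
        )
        stream, _ = simulate(script)
        path = writer(stream, tmp_path / "s.dat")
        assert _streams_equal(stream, reader(path))

    def test_many_seeded_streams_round_trip(self, tmp_path):
        for seed in range(20):
            script = MotionScript(
                segments=(Segment("stand", 0.3),), seed=seed
            )
            stream, _ = simulate(script)
            back = read_skeleton_csv(write_skeleton_csv(stream, tmp_path / "s.csv"))
            assert _streams_equal(stream, back)

    def test_empty_stream_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_skeleton_csv(SkeletonStream([]), tmp_path / "e.csv")

    def test_single_frame_stream_round_trips(self, tmp_path):
        floor = FloorPlane(0, 1, 0, 0.91)
        frame = SkeletonFrame(0, 0.0, {"head": JointPosition(0, 0.6, 2.0)}, floor)
        stream = SkeletonStream([frame])
        back = read_skeleton_csv(write_skeleton_csv(stream, tmp_path / "one.csv"))
        assert len(back) == 1
        assert back[0].joint("head").usable
        # joints absent from the file come back as not_tracked
        assert not back[0].joint("foot_l").usable

    def test_blank_cell_marks_joint_not_tracked(self, tmp_path):
        script = MotionScript(segments=(Segment("stand", 0.2),), seed=0)
        stream, _ = simulate(script)
        path = write_skeleton_csv(stream, tmp_path / "s.csv")
        text = path.read_text().splitlines()
        header = text[1].split(",")
        col = header.index("head_x")
        row = text[2].split(",")
        row[col] = ""
        text[2] = ",".join(row)
        path.write_text("\n".join(text) + "\n")
        back = read_skeleton_csv(path)
        assert back[0].joint("head").tracking_state is TrackingState.NOT_TRACKED
        assert back[1].joint("head").usable

    def test_missing_mandatory_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,floor_A,floor_B,floor_C,floor_D\n0,0,1,0,0.9\n")
        with pytest.raises(FormatError, match="t"):
            read_skeleton_csv(p)

    def test_decreasing_timestamps_rejected(self, tmp_path):
        script = MotionScript(segments=(Segment("stand", 0.2),), seed=0)
        stream, _ = simulate(script)
        path = write_skeleton_csv(stream, tmp_path / "s.csv")
        lines = path.read_text().splitlines()
        hdr = lines[1].split(",")
        t_col = hdr.index("t")
        row = lines[3].split(",")
        row[t_col] = "-5.0"
        lines[3] = ",".join(row)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError):
            read_skeleton_csv(path)


class TestAccelerometer:
    def test_toy_csv_reads_in_si_units(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,a_mag\n0,9.8\n0.1,9.8\n0.2,9.8\n")
        series = read_accelerometer_csv(p)
        assert len(series) == 3
        assert series.magnitude == [9.8, 9.8, 9.8]

    def test_g_units_converted(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,a_mag\n0,1.0\n0.1,2.0\n")
        series = read_accelerometer_csv(p, unit="g")
        assert series.magnitude == pytest.approx([9.81, 19.62])

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,a_mag\n")
        with pytest.raises(FormatError):
            read_accelerometer_csv(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,a_mag\n0,9.8\n0.1,oops\n")
        with pytest.raises(FormatError, match="row 1"):
            read_accelerometer_csv(p)


class TestHeightReconstruction:
    def test_constant_gravity_series_keeps_initial_height(self):
        series = AccelerationSeries([i * 0.1 for i in range(5)], [9.81] * 5)
        h = height_series_from_acceleration(1.4, series)
        assert h[0] == 1.4
        assert np.allclose(h, 1.4)

    def test_deviation_pulse_monotonically_lowers_height(self):
        # 3-sample pulse of +3 m/s^2 above gravity at dt = 0.1 s: each
        # pulse sample subtracts |a-g|*dt = 0.3 m in variation mode
        t = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        a = [9.81, 9.81, 12.81, 12.81, 12.81, 9.81]
        h = height_series_from_acceleration(1.5, AccelerationSeries(t, a))
        assert h.tolist() == pytest.approx([1.5, 1.5, 1.2, 0.9, 0.6, 0.6])
        assert all(x >= y for x, y in zip(h, h[1:]))

    def test_height_clipped_at_floor(self):
        t = [i * 0.1 for i in range(10)]
        a = [9.81] + [30.0] * 9
        h = height_series_from_acceleration(0.5, AccelerationSeries(t, a))
        assert h[-1] == 0.0
        assert (h >= 0).all()

    def test_double_integration_mode_descends_under_net_acceleration(self):
        t = [i * 0.1 for i in range(20)]
        a = [9.81 + 2.0] * 20
        h = height_series_from_acceleration(
            1.5, AccelerationSeries(t, a), mode="double_integration"
        )
        assert h[0] == 1.5
        assert h[-1] < h[1]

    def test_invalid_initial_height_rejected(self):
        series = AccelerationSeries([0.0, 0.1], [9.81, 9.81])
        with pytest.raises(ValueError):
            height_series_from_acceleration(0.0, series)
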