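"""Trajectory ingestion, displacement arithmetic, and repetition segmentation."""

import numpy as np
import pytest

from liftpattern.exceptions import (
    SegmentationError,
    TrajectoryParseError,
    ValidationError,
)
from liftpattern.synthetic import CurlSimConfig, simulate_curl
from liftpattern.trajectory import (
    MarkerTrajectory,
    RepetitionSegment,
    XmlFormatProfile,
    displacement,
    load_trajectory,
    max_displacement,
    segment_repetitions,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


KINOVEA_XML = """<?xml version="1.0"?>
<KinoveaVideoAnalysis>
  <Track name="bar">
    <TrackPointList>
      <TrackPoint X="0.0" Y="0.0" T="0.0"/>
      <TrackPoint X="1.5" Y="2.0" T="0.033"/>
      <TrackPoint X="3.0" Y="4.5" T="0.067"/>
      <TrackPoint X="4.0" Y="7.0" T="0.1"/>
      <TrackPoint X="4.5" Y="10.0" T="0.133"/>
    </TrackPointList>
  </Track>
</KinoveaVideoAnalysis>
"""


class TestLoadTrajectory:
    def test_csv_identity_and_linear_scaling(self, tmp_path):
        p = _write(tmp_path, "a.csv", "t,x,y\n0,0,0\n0.0333,1,2\n0.0667,2,4\n")
        traj = load_trajectory(p, scale=1.0)
        assert len(traj) == 3
        np.testing.assert_allclose(traj.x, [0, 1, 2])
        traj2 = load_trajectory(p, scale=2.0)
        np.testing.assert_allclose(traj2.x, [0, 2, 4])
        np.testing.assert_allclose(traj2.y, [0, 4, 8])

    def test_csv_without_time_column_derives_t_from_fs(self, tmp_path):
        p = _write(tmp_path, "b.csv", "x,y\n0,0\n1,1\n2,2\n")
        traj = load_trajectory(p, fs=30.0)
        np.testing.assert_allclose(traj.t, np.arange(3) / 30.0)

    def test_kinovea_xml_matches_hand_transcription(self, tmp_path):
        p = _write(tmp_path, "c.xml", KINOVEA_XML)
        traj = load_trajectory(p, format="kinovea_xml", scale=2.0)
        assert len(traj) == 5
        # file values times scale, rebased at the (0, 0) first sample
        np.testing.assert_allclose(traj.x, np.array([0.0, 1.5, 3.0, 4.0, 4.5]) * 2)
        np.testing.assert_allclose(traj.y, np.array([0.0, 2.0, 4.5, 7.0, 10.0]) * 2)
        np.testing.assert_allclose(traj.t, [0.0, 0.033, 0.067, 0.1, 0.133])

    def test_kinovea_custom_profile(self, tmp_path):
        xml = '<r><pt a="1" b="2"/><pt a="3" b="4"/></r>'
        p = _write(tmp_path, "d.xml", xml)
        prof = XmlFormatProfile(point_tag="pt", x_attr="a", y_attr="b")
        traj = load_trajectory(p, format="kinovea_xml", xml_profile=prof)
        np.testing.assert_allclose(traj.x, [0, 2])

    def test_rebased_origin(self, tmp_path):
        p = _write(tmp_path, "e.csv", "x,y\n5,7\n6,9\n")
        traj = load_trajectory(p)
        assert traj.x[0] == 0.0 and traj.y[0] == 0.0

    @pytest.mark.parametrize(
        "content,err",
        [
            ("x,y\n0,zero\n1,1\n", TrajectoryParseError),  # non-numeric
            ("a,b\n0,0\n1,1\n", TrajectoryParseError),  # missing columns
            ("t,x,y\n1,0,0\n0,1,1\n", ValidationError),  # non-monotone t
            ("t,x,y\n0,0,0\n", ValidationError),  # < 2 samples
        ],
    )
    def test_malformed_csv(self, tmp_path, content, err):
        p = _write(tmp_path, "bad.csv", content)
        with pytest.raises(err):
            load_trajectory(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_trajectory(tmp_path / "nope.csv")

    def test_rebase_idempotent(self, tmp_path):
        p = _write(tmp_path, "f.csv", "x,y\n3,1\n4,5\n7,2\n")
        traj = load_trajectory(p)
        again = traj.rebase()
        np.testing.assert_array_equal(traj.x, again.x)
        np.testing.assert_array_equal(traj.y, again.y)


class TestDisplacement:
    def setup_method(self):
        self.traj = MarkerTrajectory(
            t=np.arange(3) / 30, x=np.array([0.0, 3.0, 5.0]), y=np.array([0.0, 1.0, 4.0])
        )

    def test_direct_subtraction(self):
        assert displacement(self.traj, 0, 2) == (5.0, 4.0)

    def test_identity_case(self):
        assert displacement(self.traj, 1, 1) == (0.0, 0.0)

    def test_antisymmetry(self):
        dx, dy = displacement(self.traj, 0, 2)
        rdx, rdy = displacement(self.traj, 2, 0)
        assert (dx, dy) == (-rdx, -rdy)

    def test_quarter_circle_arc(self):
        # bar on a 30 cm forearm swinging from hanging to horizontal
        theta = np.linspace(-np.pi / 2, 0.0, 50)
        traj = MarkerTrajectory(
            t=np.linspace(0, 1, 50), x=30 * np.cos(theta), y=30 * np.sin(theta)
        ).rebase()
        dx, dy = displacement(traj, 0, 49)
        assert dx == pytest.approx(30.0)
        assert dy == pytest.approx(30.0)

    def test_index_out_of_range(self):
        with pytest.raises(ValidationError):
            displacement(self.traj, 0, 3)


class TestSegmentation:
    def test_single_monotone_rise(self):
        t = np.linspace(0, 2, 61)
        y = 1 - np.cos(np.pi * t)  # one period over 2 s: up then down
        traj = MarkerTrajectory(t=t, x=np.zeros_like(t), y=y)
        segs = segment_repetitions(traj, 1)
        assert len(segs) == 1
        s = segs[0]
        assert s.phase == "ascending"
        assert s.start_idx == 0
        # the rise covers the first half of the period
        assert abs(s.end_idx - 31) <= 2

    def test_three_periods_equal_lengths(self):
        t = np.linspace(0, 6, 181)
        y = 1 - np.cos(np.pi * t)
        traj = MarkerTrajectory(t=t, x=np.zeros_like(t), y=y)
        segs = segment_repetitions(traj, 3)
        lengths = [len(s) for s in segs]
        assert max(lengths) - min(lengths) <= 1
        # disjoint and ordered
        for a, b in zip(segs, segs[1:]):
            assert a.end_idx <= b.start_idx

    def test_noisy_synthetic_peaks_near_programmed_amplitude(self):
        cfg = CurlSimConfig(jitter_sd_cm=0.2, sway_sd_cm=0.0, seed=42)
        traj, gt = simulate_curl(cfg)
        segs = segment_repetitions(traj, 3)
        for s, prog in zip(segs, gt.dy_max):
            peak = (s.y - s.y[0]).max()
            assert abs(peak - prog) < 1.0

    def test_ascending_invariant(self, noiseless_curl):
        traj, _ = noiseless_curl
        for s in segment_repetitions(traj, 3):
            assert s.y[-1] >= s.y[0]

    def test_too_few_cycles_reports_count(self, noiseless_curl):
        traj, _ = noiseless_curl
        with pytest.raises(SegmentationError, match="3"):
            segment_repetitions(traj, 5)


class TestMaxDisplacement:
    def test_straight_vertical_rise(self):
        y = np.linspace(0, 56.8, 40)
        traj = MarkerTrajectory(t=np.linspace(0, 2, 40), x=np.zeros(40), y=y)
        seg = RepetitionSegment(0, 40, "ascending", traj)
        summ = max_displacement(seg)
        assert summ.dy_max == pytest.approx(56.8)
        assert summ.dx_max == 0.0

    def test_quarter_circle_radius_25(self):
        theta = np.linspace(-np.pi / 2, np.pi / 2, 201)  # grid hits theta = 0
        traj = MarkerTrajectory(
            t=np.linspace(0, 2, 201), x=25 * np.cos(theta), y=25 * np.sin(theta)
        ).rebase()
        seg = RepetitionSegment(0, 201, "ascending", traj)
        summ = max_displacement(seg)
        assert summ.dx_max == pytest.approx(25.0)
        assert summ.dy_max == pytest.approx(50.0)

    def test_generator_ground_truth(self):
        cfg = CurlSimConfig(
            jitter_sd_cm=0.0, sway_sd_cm=0.0, load_pct=50,
            dy_gain={0: 1.0, 50: 64.0 / 56.8}, dx_gain={0: 1.0, 50: 24.9 / 23.7},
        )
        traj, gt = simulate_curl(cfg)
        seg = segment_repetitions(traj, 3)[0]
        summ = max_displacement(seg, load_pct=50)
        step = gt.dy_max[0] * np.pi / (cfg.fs * cfg.cadence_s)  # one sample of arc speed
        assert abs(summ.dy_max - 64.0) <= step
        assert abs(summ.dx_max - 24.9) <= step

    def test_dy_max_bounds_net_rise(self, noiseless_curl):
        traj, _ = noiseless_curl
        for seg in segment_repetitions(traj, 3):
            assert max_displacement(seg).dy_max >= seg.y[-1] - seg.y[0]

    def test_descending_segment_rejected(self, noiseless_curl):
        traj, _ = noiseless_curl
        seg = RepetitionSegment(0, 10, "descending", traj)
        with pytest.raises(ValidationError):
            max_displacement(seg)
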