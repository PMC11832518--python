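"""Immobility detection, single-movement segmentation and classification."""

import numpy as np
import pytest

import ewmnkit as ek
from ewmnkit.linkage import direction_from_angles
from ewmnkit.segmentation import (
    Arena,
    Plane,
    SegmentationParams,
    _runs,
    classify_movement_type,
    detect_immobility,
    detect_snout_contact,
    keypoint_speeds,
    segment_single_movements,
)
from ewmnkit.simulate import GrammarSimConfig, _minjerk, simulate_warmup

from conftest import make_angles, render, run_pipeline


def static_series(spec, T, fps=50.0):
    kps, _ = render(np.zeros((T, 3)), np.zeros((T, 3)), spec, fps)
    return kps


class TestImmobility:
    def test_perfectly_static_trajectory_is_one_full_bout(self, spec):
        T = 300
        kps = static_series(spec, T)
        bouts = detect_immobility(kps, speed_threshold=1e-4, min_duration_s=1.0)
        assert len(bouts) == 1
        assert (bouts[0].start, bouts[0].end) == (0, T)
        assert bouts[0].duration_s == pytest.approx(T / 50.0)

    def test_scripted_600s_zero_velocity_epoch(self, spec):
        """A ten-minute zero-velocity epoch is recovered to within a frame."""
        fps = 10.0
        move = 200  # frames of motion either side
        still = int(600 * fps)
        T = move + still + move
        th = np.zeros((T, 3))
        t = np.arange(move) / move
        th[:move, 2] = 45 * np.sin(2 * np.pi * 3 * t)
        th[move + still :, 2] = 45 * np.sin(2 * np.pi * 3 * t)
        kps, _ = render(th, np.zeros((T, 3)), spec, fps)
        # noise-free input: disable smoothing so bout edges are exact up to
        # the central-difference stencil (one frame per side)
        bouts = detect_immobility(
            kps, speed_threshold=1e-3, min_duration_s=5.0, smooth_window_s=0.0
        )
        longest = max(bouts, key=lambda b: b.duration_s)
        assert abs(longest.duration_s - 600.0) <= 2.0 / fps + 1e-9

    def test_bout_count_matches_run_length_oracle(self, spec, rng):
        """Across thresholds, bouts equal a brute-force run-length scan."""
        T = 800
        fps = 50.0
        th = np.cumsum(rng.normal(0, 0.8, (T, 3)), axis=0)
        kps, _ = render(th, np.zeros((T, 3)), spec, fps)
        speeds = keypoint_speeds(kps)
        min_frames = 25
        for thr in (0.001, 0.005, 0.02, 0.1):
            quiet = np.all(speeds < thr, axis=1)
            expected = sum(1 for s, e in _runs(quiet) if e - s >= min_frames)
            bouts = detect_immobility(kps, thr, min_frames / fps)
            assert len(bouts) == expected

    def test_min_duration_below_two_frames_rejected(self, spec):
        kps = static_series(spec, 50)
        with pytest.raises(ValueError, match="2 frames"):
            detect_immobility(kps, 0.01, min_duration_s=0.01)


class TestWorkedExample:
    def test_single_horizontal_head_movement_45_right(self, spec):
        """The canonical worked example: one horizontal head movement from
        the midsagittal zero position ending 45 degrees to the right yields
        exactly one primitive of one 45-degree unit."""
        fps = 100.0
        pre, dur, post = int(2 * fps), int(0.5 * fps), int(2 * fps)
        T = pre + dur + post
        th = np.zeros((T, 3))
        th[pre : pre + dur, 2] = -45.0 * _minjerk(np.linspace(0, 1, dur))
        th[pre + dur :, 2] = -45.0
        kps, order = render(th, np.zeros((T, 3)), spec, fps)
        pose = ek.compute_segment_directions(kps, spec)
        rel = ek.to_body_relative(pose, order, spec)
        prims = segment_single_movements(rel, order, spec)
        assert len(prims) == 1
        p = prims[0]
        assert p.segment == "head"
        assert p.movement_type == "plane_horizontal"
        assert p.sign == "right"
        assert p.amplitude_deg == pytest.approx(45.0, abs=0.5)
        assert p.amplitude_units == 1

    def test_static_input_yields_empty_list(self, spec):
        kps = static_series(spec, 200)
        pose = ek.compute_segment_directions(kps, spec)
        order = ek.derive_heavy_light_order(ek.SupportState.constant(200), spec)
        rel = ek.to_body_relative(pose, order, spec)
        assert segment_single_movements(rel, order, spec) == []

    def test_subquantum_flicker_suppressed_and_logged(self, spec):
        fps = 50.0
        T = 400
        th = np.zeros((T, 3))
        dur = 25
        th[100 : 100 + dur, 2] = 5.0 * _minjerk(np.linspace(0, 1, dur))  # 5 deg blip
        th[100 + dur :, 2] = 5.0
        kps, order = render(th, np.zeros((T, 3)), spec, fps)
        pose = ek.compute_segment_directions(kps, spec)
        rel = ek.to_body_relative(pose, order, spec)
        log = []
        prims = segment_single_movements(rel, order, spec, discard_log=log)
        assert prims == []
        assert len(log) == 1 and log[0]["reason"] == "sub-amplitude"


class TestClassification:
    def params(self):
        return SegmentationParams()

    def test_horizontal_plane(self):
        th = np.linspace(0, 90, 50)
        ph = np.zeros(50)
        mtype, sign, amp, dist, mixed = classify_movement_type(th, ph, self.params())
        assert (mtype, sign) == ("plane_horizontal", "left")
        assert amp == pytest.approx(90.0)

    def test_vertical_plane_positive(self):
        th = np.zeros(50)
        ph = np.linspace(0, 45, 50)
        mtype, sign, amp, dist, mixed = classify_movement_type(th, ph, self.params())
        assert (mtype, sign) == ("plane_vertical", "up")
        assert amp == pytest.approx(45.0)

    def test_cone_about_vertical_axis(self):
        th = np.linspace(0, 120, 80)
        ph = np.full(80, 60.0)  # 30-degree half-angle about the vertical
        mtype, *_ = classify_movement_type(th, ph, self.params())
        assert mtype == "conical"

    def test_random_cones_recovered_against_generative_oracle(self, rng):
        """Arcs on random small circles classify as conical; the generating
        axis/half-angle are the oracle."""
        from scipy.spatial.transform import Rotation

        n_ok = 0
        for _ in range(100):
            # axis elevation >= 35 deg so the trace cannot also be read as a
            # horizontal plane movement inside the plane tolerance
            elev = np.radians(rng.uniform(35, 90))
            azim = rng.uniform(0, 2 * np.pi)
            axis = np.array(
                [np.cos(elev) * np.cos(azim), np.cos(elev) * np.sin(azim), np.sin(elev)]
            )
            half = np.radians(rng.uniform(20, 50))
            # ring of directions at angle `half` around axis
            ref = np.array([0.0, 0.0, 1.0])
            if abs(axis @ ref) > 0.95:
                ref = np.array([1.0, 0.0, 0.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            ang = np.linspace(0, rng.uniform(2.0, 5.0), 120)
            u = (
                np.cos(half) * axis[None]
                + np.sin(half) * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
            )
            from ewmnkit.linkage import angles_from_direction

            th, ph = angles_from_direction(u)
            th = np.degrees(np.unwrap(np.radians(th)))
            res = classify_movement_type(th, ph, self.params())
            if res and res[0] == "conical":
                n_ok += 1
        assert n_ok == 100

    def test_mixed_translation_flag(self):
        th = np.linspace(0, 60, 50)
        ph = np.zeros(50)
        mtype, sign, amp, dist, mixed = classify_movement_type(
            th, ph, self.params(), base_displacement=0.05, zero_dot=1.0
        )
        assert mtype == "plane_horizontal" and mixed

    def test_pure_translation_is_forward_transport(self):
        th = np.zeros(50)
        ph = np.zeros(50)
        res = classify_movement_type(th, ph, self.params(), base_displacement=0.03, zero_dot=1.0)
        assert res[0] == "forward_transport" and res[1] == "forward"
        assert res[3] == pytest.approx(0.03)


class TestTransportAttribution:
    def test_head_transport_attributed_to_head(self, spec):
        """A sub-chain translation (axial extension at the head's heavy
        joint) is attributed to the head, not to carried-along joints."""
        fps = 50.0
        T = 300
        ang = make_angles(np.zeros((T, 3)), np.zeros((T, 3)), spec, fps)
        order = ek.derive_heavy_light_order(ek.SupportState.constant(T), spec)
        ext = np.zeros((T, 3))
        dur = 30
        ext[100 : 100 + dur, 1] = 0.03 * _minjerk(np.linspace(0, 1, dur))
        ext[100 + dur :, 1] = 0.03
        kps = ek.forward_kinematics(np.zeros(3), ang, order, spec, extensions=ext)
        pose = ek.compute_segment_directions(kps, spec)
        rel = ek.to_body_relative(pose, order, spec)
        prims = segment_single_movements(rel, order, spec, kps=kps)
        assert len(prims) == 1
        p = prims[0]
        assert p.segment == "head" and p.movement_type == "forward_transport"
        assert p.sign == "forward"
        assert p.distance == pytest.approx(0.03, abs=1e-3)


class TestInvariants:
    def test_segmentation_idempotent_on_reconstruction(self, spec):
        """Re-segmenting the piecewise reconstruction of detected primitives
        returns the same primitives (symbols and amplitudes)."""
        res = simulate_warmup(GrammarSimConfig(stage=0.6, seed=7))
        prims = run_pipeline(res, spec)
        T = res.keypoints.n_frames
        th = np.zeros((T, 3))
        ph = np.zeros((T, 3))
        cur_t = np.zeros(3)
        cur_p = np.zeros(3)
        for p in sorted(prims, key=lambda q: q.start):
            if p.movement_type == "forward_transport":
                continue
            s = spec.segment_index(p.segment)
            ramp = np.linspace(0, 1, p.end - p.start)
            delta = p.amplitude_deg if p.sign in ("left", "up") else -p.amplitude_deg
            if p.movement_type == "plane_horizontal":
                th[p.start : p.end, s] = cur_t[s] + delta * ramp
                cur_t[s] += delta
                th[p.end :, s] = cur_t[s]
            else:
                ph[p.start : p.end, s] = cur_p[s] + delta * ramp
                cur_p[s] += delta
                ph[p.end :, s] = cur_p[s]
        angles = make_angles(th, ph, spec, res.keypoints.frame_rate)
        order = ek.derive_heavy_light_order(res.support, spec)
        redet = segment_single_movements(angles, order, spec)
        want = [p.symbol() for p in prims if p.movement_type != "forward_transport"]
        got = [p.symbol() for p in redet]
        assert want == got

    def test_amplitude_conservation_per_segment_and_plane(self, spec):
        """Signed primitive amplitudes sum to the net body-relative angular
        displacement within half a quantum per primitive."""
        res = simulate_warmup(GrammarSimConfig(stage=1.0, seed=11))
        prims = run_pipeline(res, spec)
        kps = res.keypoints
        pose = ek.compute_segment_directions(kps, spec)
        order = ek.derive_heavy_light_order(res.support, spec)
        rel = ek.to_body_relative(pose, order, spec)
        th = np.degrees(np.unwrap(np.radians(rel.theta_rel), axis=0))
        for s, name in enumerate(spec.segment_names):
            mine = [p for p in prims if p.segment == name and p.movement_type == "plane_horizontal"]
            signed = sum(p.amplitude_deg if p.sign == "left" else -p.amplitude_deg for p in mine)
            net = th[-1, s] - th[0, s]
            assert abs(signed - net) <= 22.5 * max(len(mine), 1) / 2 + 1.0


class TestSnoutContact:
    def arena(self):
        return Arena(planes=[Plane(point=(0, 0, 0), normal=(0, 0, 1))])

    def make_kps(self, spec, z):
        T = z.size
        pos = np.zeros((T, 1, 3))
        pos[:, 0, 2] = z
        return ek.KeypointSeries(
            times=np.arange(T) / 50.0,
            positions=pos,
            keypoint_names=["snout"],
            frame_rate=50.0,
        )

    def test_snout_on_floor_is_contact(self, spec):
        kps = self.make_kps(spec, np.zeros(10))
        c = detect_snout_contact(kps, self.arena(), threshold=0.01)
        assert c.all()

    def test_leaving_wall_flips_at_known_frame(self, spec):
        z = np.concatenate([np.zeros(100), np.linspace(0, 0.05, 100)])
        kps = self.make_kps(spec, z)
        c = detect_snout_contact(kps, self.arena(), threshold=0.01, min_dwell_s=0.1)
        flip = int(np.flatnonzero(~c)[0])
        expected = 100 + int(np.ceil(0.01 / (0.05 / 99)))
        assert abs(flip - expected) <= 5  # within the debounce window

    def test_zero_threshold_contact_only_at_exact_touch(self, spec):
        z = np.array([0.0, 0.001, 0.0, 0.002, 0.0] * 4)
        kps = self.make_kps(spec, z)
        c = detect_snout_contact(kps, self.arena(), threshold=0.0)
        assert (c == (z == 0.0)).all()

    def test_missing_snout_reports_unknown(self, spec):
        T = 10
        pos = np.zeros((T, 1, 3))
        kps = ek.KeypointSeries(
            times=np.arange(T) / 50.0,
            positions=pos,
            keypoint_names=["tail_base"],
            frame_rate=50.0,
        )
        with pytest.warns(UserWarning, match="unknown"):
            assert detect_snout_contact(kps, self.arena(), 0.01) is None

    def test_polyline_wall(self, spec):
        arena = Arena(polylines=[np.array([[0.0, -1.0], [0.0, 1.0]])])
        T = 4
        pos = np.zeros((T, 1, 2))
        pos[:, 0, 0] = [0.0, 0.005, 0.02, 0.5]
        kps = ek.KeypointSeries(
            times=np.arange(T) / 50.0,
            positions=pos,
            keypoint_names=["snout"],
            frame_rate=50.0,
        )
        c = detect_snout_contact(kps, arena, threshold=0.01)
        assert list(c) == [True, True, False, False]
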