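"""Marker blob pipeline, back-projection, tap signals and the 8 features."""

import numpy as np
import pytest

from pdmotor import synth, tapping
from pdmotor.io import CameraIntrinsics, KINECT_V2_INTRINSICS
from pdmotor.tapping import (CannotSegmentError, InsufficientSignalError,
                             MarkerTrack, TapSignal, UninformativeFrameError,
                             ZeroDynamicRangeError, backproject,
                             build_finger_signal, build_foot_signal,
                             detect_marker_blobs, extract_tap_features,
                             segment_trials, tap_features)


def _gaussian_spot(shape=(120, 160), center=(60.0, 80.0), sigma=4.0, peak=50000,
                   saturation=2.0):
    v, u = np.mgrid[0:shape[0], 0:shape[1]]
    g = np.exp(-0.5 * (((u - center[1]) ** 2 + (v - center[0]) ** 2) / sigma ** 2))
    return (peak * np.minimum(1.0, saturation * g)).astype(np.uint16)


def _cc_centroids_bruteforce(mask):
    """Flood-fill connected components (8-connectivity): [(centroid, area)]."""
    mask = mask.copy()
    h, w = mask.shape
    out = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0]:
                stack, pix = [(r0, c0)], []
                mask[r0, c0] = False
                while stack:
                    r, c = stack.pop()
                    pix.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                                mask[rr, cc] = False
                                stack.append((rr, cc))
                pix = np.array(pix, float)
                out.append(((pix[:, 1].mean(), pix[:, 0].mean()), len(pix)))
    return out


class TestBlobDetection:
    def test_single_spot_centroid(self):
        frame = _gaussian_spot()
        blobs = detect_marker_blobs(frame, size_range=(20, 500))
        assert len(blobs) == 1
        (u, v), area = blobs[0]
        assert abs(u - 80.0) < 0.5 and abs(v - 60.0) < 0.5
        assert 20 <= area <= 500

    def test_all_dark_frame(self):
        assert detect_marker_blobs(np.zeros((50, 50), np.uint16)) == []

    def test_two_spots_with_noise_specks(self, rng):
        frame = (_gaussian_spot(center=(40.0, 50.0)).astype(np.int64)
                 + _gaussian_spot(center=(80.0, 120.0)))
        frame = np.clip(frame, 0, 65535).astype(np.uint16)
        specks = rng.choice(120 * 160, 10, replace=False)
        flat = frame.reshape(-1)
        flat[specks] = np.maximum(flat[specks], 60000)
        blobs = detect_marker_blobs(frame.reshape(120, 160), size_range=(20, 500))
        assert len(blobs) == 2

    def test_saturated_frame_rejected(self):
        frame = np.full((50, 50), 60000, np.uint16)
        frame[0, 0] = 65535
        with pytest.raises(UninformativeFrameError):
            detect_marker_blobs(frame)

    def test_centroids_match_bruteforce_components(self, rng):
        """On binary-like frames the pipeline centroid equals the exact
        center of mass of each connected component."""
        frame = np.zeros((90, 110), np.uint16)
        for (r, c) in ((20, 30), (60, 80), (45, 15)):
            frame[r - 3:r + 4, c - 3:c + 4] = 50000  # 7x7 squares
        blobs = detect_marker_blobs(frame, size_range=(10, 200))
        cfg = tapping.BlobConfig()
        mask = frame > cfg.rel_threshold * frame.max()
        oracle = _cc_centroids_bruteforce(mask)
        assert len(blobs) == len(oracle) == 3
        got = sorted(b[0] for b in blobs)
        want = sorted(o[0] for o in oracle)
        for (u1, v1), (u2, v2) in zip(got, want):
            assert abs(u1 - u2) <= 0.5 and abs(v1 - v2) <= 0.5


class TestBackprojection:
    def test_principal_point_identity(self):
        depth = np.full((424, 512), 1000, np.uint16)
        p = backproject((256.0, 212.0), depth, KINECT_V2_INTRINSICS)
        assert np.allclose(p, [0, 0, 1.0])

    def test_unit_offset_closed_form(self):
        intr = CameraIntrinsics(fx=365, fy=365, cx=256, cy=212, depth_scale=0.001)
        depth = np.full((424, 720), 1000, np.uint16)
        p = backproject((256.0 + 365.0, 212.0), depth, intr)
        assert np.allclose(p, [1.0, 0.0, 1.0])

    def test_project_backproject_inverse(self, rng):
        intr = CameraIntrinsics(fx=380.0, fy=370.0, cx=250.0, cy=210.0,
                                depth_scale=1.0)
        pts = np.column_stack([rng.uniform(-0.3, 0.3, 40),
                               rng.uniform(-0.25, 0.25, 40),
                               rng.uniform(0.5, 2.0, 40)])
        uv = synth.project(pts, intr)
        for (u, v), p in zip(uv, pts):
            depth = np.zeros((424, 512))
            depth[int(round(v)), int(round(u))] = p[2]
            q = backproject((u, v), depth, intr)
            assert np.allclose(q, p, atol=1e-6)

    def test_invalid_depth_uses_neighborhood_median(self):
        depth = np.full((40, 40), 800, np.uint16)
        depth[20, 20] = 0
        p = backproject((20.0, 20.0), depth,
                        CameraIntrinsics(fx=300, fy=300, cx=20, cy=20))
        assert p is not None and p[2] == pytest.approx(0.8)
        assert backproject((5.0, 5.0), np.zeros((40, 40)),
                           CameraIntrinsics(fx=300, fy=300, cx=20, cy=20)) is None


def _track(t, positions):
    return MarkerTrack(timestamps=t, positions=np.asarray(positions, float))


class TestSignals:
    def test_static_points_zero_dynamic_range(self):
        t = np.arange(120) / 30
        a = _track(t, np.tile([0, 0, 0.8], (120, 1)))
        b = _track(t, np.tile([0.05, 0, 0.8], (120, 1)))
        with pytest.raises(ZeroDynamicRangeError):
            build_finger_signal(a, b)

    def test_distance_invariant_to_camera_translation(self):
        sig, _ = synth.generate_tap_signal(synth.TapProfile(), seed=0)
        raw = sig.d[:, None] * np.array([0.6, -0.8, 0.0])
        t = sig.t
        a = _track(t, np.tile([0, 0, 0.8], (len(t), 1)))
        b = _track(t, np.tile([0, 0, 0.8], (len(t), 1)) + raw + 0.02)
        shift = np.array([0.3, -0.1, 0.2])
        s1 = build_finger_signal(a, b)
        s2 = build_finger_signal(_track(t, a.positions + shift),
                                 _track(t, b.positions + shift))
        assert np.allclose(s1.d, s2.d, atol=1e-12)

    def test_short_overlap_rejected(self):
        t = np.arange(30) / 30
        a = _track(t, np.random.default_rng(0).normal(size=(30, 3)) + [0, 0, 1])
        with pytest.raises(InsufficientSignalError):
            build_finger_signal(a, a)

    def test_foot_signal_offset_invariance_and_rest(self):
        sig, _ = synth.generate_tap_signal(synth.TapProfile(kind="foot"), seed=1)
        pos = np.tile([0.0, 0.1, 0.9], (len(sig.t), 1))
        pos[:, 1] -= sig.d * 0.06  # lifting the toes decreases image-down Y
        tr = _track(sig.t, pos)
        s1 = build_foot_signal(tr)
        s2 = build_foot_signal(_track(sig.t, pos + np.array([0.2, 0.05, -0.1])))
        assert np.allclose(s1.d, s2.d, atol=1e-12)
        # peak ordering preserved after normalisation
        order1 = np.argsort(s1.d)[-5:]
        assert np.array_equal(order1, np.argsort(sig.d)[-5:])

    def test_motionless_foot_marker_rejected(self):
        t = np.arange(120) / 30
        with pytest.raises(ZeroDynamicRangeError):
            build_foot_signal(_track(t, np.tile([0, 0.1, 0.9], (120, 1))))


class TestTrialSegmentation:
    def test_generator_protocol_yields_ten_trials(self):
        sig, _ = synth.generate_tap_signal(
            synth.TapProfile(period_sd=0.04, amplitude_sd=0.01), seed=2)
        assert len(segment_trials(sig)) == 10

    def test_pure_tone_equal_trials(self):
        T, fs = 0.5, 30.0
        t = np.arange(0, 10 * T + 1 / fs / 2, 1 / fs)
        sig = TapSignal(t=t, d=0.5 * (1 - np.cos(2 * np.pi * t / T)), sample_rate=fs)
        trials = segment_trials(sig)
        assert len(trials) == 10
        durs = np.array([tr.duration for tr in trials])
        assert np.ptp(durs) <= 1 / fs + 1e-9

    def test_white_noise_cannot_segment(self, rng):
        t = np.arange(300) / 30
        sig = TapSignal(t=t, d=np.clip(0.1 * rng.random(300), 0, 1), sample_rate=30)
        with pytest.raises(CannotSegmentError):
            segment_trials(sig)


class TestTapFeatures:
    def test_pure_tone_analytics(self):
        T, fs = 0.5, 30.0
        t = np.arange(0, 10 * T + 1 / fs / 2, 1 / fs)
        sig = TapSignal(t=t, d=0.5 * (1 - np.cos(2 * np.pi * t / T)), sample_rate=fs)
        fv = tap_features(sig, segment_trials(sig))
        assert fv.meanTime == pytest.approx(T, abs=1 / fs)
        assert fv.varTime <= (1 / fs) ** 2
        assert fv.meanAmplitude == pytest.approx(1.0, abs=0.02)
        assert fv.periodicity == pytest.approx(1.0, abs=1e-2)
        assert fv.AxF == pytest.approx(1 / T, rel=0.02)

    def test_injected_tremor_bumps_are_counted(self):
        sig, truth = synth.generate_tap_signal(synth.TapProfile(tremor_bumps=3), seed=1)
        fv = extract_tap_features(sig)
        assert fv.tremors == 10 + len(truth.bump_times) == 13

    def test_tremors_at_least_trial_count(self):
        for seed in range(4):
            sig, _ = synth.generate_tap_signal(
                synth.TapProfile(period_sd=0.05, amplitude_sd=0.015,
                                 noise_sd=0.001), seed=seed)
            trials = segment_trials(sig)
            fv = tap_features(sig, trials)
            assert fv.tremors >= len(trials)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hesitations_increase_with_plateaus(self, seed):
        smooth, _ = synth.generate_tap_signal(synth.TapProfile(), seed=seed)
        hesit, _ = synth.generate_tap_signal(synth.TapProfile(hesitations=3), seed=seed)
        assert (extract_tap_features(hesit).hesitations
                > extract_tap_features(smooth).hesitations)

    def test_half_speed_replay_scaling(self):
        sig, _ = synth.generate_tap_signal(
            synth.TapProfile(period_sd=0.03, amplitude_sd=0.01), seed=5)
        slow = TapSignal(t=2 * sig.t, d=sig.d.copy(), kind=sig.kind,
                         sample_rate=sig.sample_rate / 2)
        f0 = extract_tap_features(sig)
        f1 = extract_tap_features(slow)
        assert f1.meanTime == pytest.approx(2 * f0.meanTime, rel=1e-6)
        assert f1.varTime == pytest.approx(4 * f0.varTime, rel=1e-6)
        assert f1.AxF == pytest.approx(f0.AxF / 2, rel=1e-6)
        assert f1.meanAmplitude == pytest.approx(f0.meanAmplitude, rel=1e-9)
        assert f1.periodicity == pytest.approx(f0.periodicity, abs=1e-6)


class TestEndToEnd:
    def test_frames_to_features_recovers_injected_values(self):
        """Render -> blob detect -> backproject -> signal -> features round
        trip recovers injected mean period and amplitude within 5%."""
        prof = synth.TapProfile(period_mean=0.4, amplitude_mean=0.08,
                                period_sd=0.03, amplitude_sd=0.006)
        pos, t, (sig_true, truth) = synth.finger_marker_trajectories(prof, seed=4)
        frames = synth.render_marker_frames(pos, t, seed=4, salt_fraction=0.0005)
        tracks = tapping.track_markers(frames, KINECT_V2_INTRINSICS, 2)
        # identity can swap (d1 is symmetric); trajectory recovery within 5 mm
        errs = [[np.sqrt(np.nanmean(np.linalg.norm(
            tracks[a].positions - pos[:, b, :], axis=1) ** 2)) for b in (0, 1)]
            for a in (0, 1)]
        assert min(errs[0][0] + errs[1][1], errs[0][1] + errs[1][0]) < 2 * 0.005
        fv = extract_tap_features(build_finger_signal(tracks[0], tracks[1]))
        assert fv.meanTime == pytest.approx(truth.durations.mean(), rel=0.05)
        assert fv.meanAmplitude == pytest.approx(truth.amplitudes.mean(), rel=0.05)

    def test_intensity_scaling_invariance(self):
        """Blob detection is invariant to uniform IR gain (threshold is
        relative to the frame maximum)."""
        frame = _gaussian_spot()
        b1 = detect_marker_blobs(frame, size_range=(20, 500))
        b2 = detect_marker_blobs((frame // 2).astype(np.uint16), size_range=(20, 500))
        assert b1[0][0] == pytest.approx(b2[0][0], abs=0.2)
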