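"""Threshold-crossing TOA extraction and beamforming azimuth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import hilbert

from uwbvitals.multiperson import (
    ArrayGeometry, NonConvergenceError, TOAConfig, cbf_azimuth,
    default_threshold, match_targets, steering_vector,
    toa_threshold_crossing)
from uwbvitals.preprocess import suppress_clutter
from uwbvitals.signal_model import (C, SceneConfig, TargetPlacement,
                                    TimingSpec, VitalSignProfile,
                                    simulate_array_echo, simulate_echo)


def brute_force_toas(r: np.ndarray, thd: float, guard: int) -> list[int]:
    """Independent oracle: bins whose power dominates their (symmetric)
    guard window and clears the threshold, in descending power order."""
    p = np.asarray(r, float) ** 2
    out = []
    for b in range(p.size):
        lo = max(b - guard, 0)
        hi = min(b + guard + 1, p.size)
        if p[b] >= thd and p[b] == p[lo:hi].max():
            out.append(b)
    out.sort(key=lambda b: -p[b])
    return out


def _pulse(n, center, width=8.0, amp=1.0):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-((x - center) / width) ** 2)


class TestToa:
    def test_all_zero_signal(self):
        cfg = TOAConfig(thd=0.5, n_left=10, n_right=10)
        assert toa_threshold_crossing(np.zeros(200), cfg) == []

    def test_two_clean_pulses_in_amplitude_order(self):
        r = _pulse(600, 100, amp=0.8) + _pulse(600, 400, amp=1.0)
        cfg = TOAConfig(thd=0.25, n_left=50, n_right=50)
        assert toa_threshold_crossing(r, cfg) == [400, 100]

    def test_sidelobe_inside_guard_suppressed(self):
        r = _pulse(400, 200, amp=1.0) + _pulse(400, 230, width=4.0, amp=0.5)
        cfg = TOAConfig(thd=0.04, n_left=50, n_right=50)
        assert toa_threshold_crossing(r, cfg) == [200]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(200, 1024))
            guard = int(rng.integers(8, 40))
            r = 0.05 * rng.normal(size=n)
            for _ in range(int(rng.integers(0, 5))):
                r += _pulse(n, rng.uniform(0, n - 1),
                            width=rng.uniform(3, 12),
                            amp=rng.uniform(0.3, 2.0))
            thd = float(np.median(r ** 2) * 6)
            cfg = TOAConfig(thd=thd, n_left=guard, n_right=guard,
                            max_iter=n)
            assert toa_threshold_crossing(r, cfg) == \
                brute_force_toas(r, thd, guard)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 2.0),
           st.floats(1.5, 6.0))
    def test_raising_threshold_never_adds_detections(self, seed, thd, mult):
        rng = np.random.default_rng(seed)
        r = rng.normal(size=300)
        lo = toa_threshold_crossing(
            r, TOAConfig(thd=thd, n_left=12, n_right=12, max_iter=300))
        hi = toa_threshold_crossing(
            r, TOAConfig(thd=thd * mult, n_left=12, n_right=12,
                         max_iter=300))
        assert len(hi) <= len(lo)
        assert set(hi) <= set(lo)

    def test_iteration_cap(self):
        r = np.ones(100) + 0.01 * np.arange(100)
        cfg = TOAConfig(thd=0.5, n_left=1, n_right=1, max_iter=3)
        with pytest.raises(NonConvergenceError):
            toa_threshold_crossing(r, cfg)

    def test_signal_shorter_than_guard(self):
        with pytest.raises(ValueError):
            toa_threshold_crossing(np.ones(10),
                                   TOAConfig(thd=1.0, n_left=6, n_right=6))

    def test_two_person_detection_study(self):
        """Two targets separated by more than the guard are both found in
        nearly every noisy trial."""
        timing = TimingSpec(n_seg=682, n_segments=1, frame_count=400)
        found = 0
        trials = 40
        for trial in range(trials):
            p1 = VitalSignProfile(d0=1.0, fr=0.25, fh=1.1)
            p2 = VitalSignProfile(d0=2.0, fr=0.35, fh=1.4)
            scene = SceneConfig(
                targets=[TargetPlacement(p1), TargetPlacement(p2)],
                awgn_sigma=0.1, trend_slope=1e-4,
                nonstat_clutter_sigma=1e-4, seed=100 + trial)
            echo, truth = simulate_echo(scene, timing=timing)
            post = suppress_clutter(echo)
            std = post.data.std(axis=0)
            cfg = TOAConfig(thd=default_threshold(std), n_left=33,
                            n_right=33)
            got = sorted(toa_threshold_crossing(std, cfg))
            bins = sorted(t.bin for t in truth)
            found += (len(got) == 2 and abs(got[0] - bins[0]) <= 3
                      and abs(got[1] - bins[1]) <= 3)
        assert found >= 0.95 * trials


class TestSteering:
    def test_zero_offsets_unity(self):
        geom = ArrayGeometry(offsets=np.zeros((4, 2)), wavelength=0.04)
        np.testing.assert_allclose(steering_vector(geom, 10.0, 30.0),
                                   np.ones(4))

    def test_vertical_look_direction_unity(self):
        geom = ArrayGeometry.planar_2x2()
        for phi in (0.0, 45.0, 200.0):
            np.testing.assert_allclose(steering_vector(geom, 90.0, phi),
                                       np.ones(4), atol=1e-12)

    def test_two_element_phase_arithmetic(self):
        lam = C / 7.29e9
        geom = ArrayGeometry(offsets=np.array([[0.0, 0.0], [lam / 2, 0.0]]),
                             wavelength=lam)
        theta, phi = 30.0, 40.0
        s = steering_vector(geom, theta, phi)
        expected = -2 * np.pi * 0.5 * np.cos(np.deg2rad(theta)) \
            * np.sin(np.deg2rad(phi))
        assert np.angle(s[1] / s[0]) == pytest.approx(
            np.angle(np.exp(1j * expected)))
        np.testing.assert_allclose(np.abs(s), 1.0)


class TestBeamforming:
    def test_identical_channels_flat_map(self):
        geom = ArrayGeometry(offsets=np.zeros((4, 2)), wavelength=0.04)
        chans = np.full(4, 1.0 + 0.5j)
        pmap, _ = cbf_azimuth(chans, geom, np.array([0.0]),
                              np.arange(-60, 61, 5.0))
        np.testing.assert_allclose(pmap, pmap.flat[0])

    def test_simulated_target_azimuth(self):
        geom = ArrayGeometry.planar_2x2()
        prof = VitalSignProfile(d0=1.5, fr=0.3, fh=1.2)
        scene = SceneConfig(targets=[TargetPlacement(prof,
                                                     azimuth_deg=20.0)],
                            awgn_sigma=0.05, seed=5)
        timing = TimingSpec(n_seg=682, n_segments=1, frame_count=300)
        echoes, truth = simulate_array_echo(scene, geom.offsets,
                                            timing=timing)
        b = truth[0].bin
        chans = np.array([hilbert(e.data.mean(axis=0))[b] for e in echoes])
        _, (_, phi) = cbf_azimuth(chans, geom, np.array([0.0]),
                                  np.arange(-60.0, 61.0, 1.0))
        assert abs(phi - 20.0) <= 1.0

    def test_channel_scaling(self):
        geom = ArrayGeometry.planar_2x2()
        rng = np.random.default_rng(8)
        chans = rng.normal(size=4) + 1j * rng.normal(size=4)
        grid_t, grid_p = np.array([0.0]), np.arange(-30, 31, 5.0)
        pmap, arg = cbf_azimuth(chans, geom, grid_t, grid_p)
        pmap2, arg2 = cbf_azimuth(3.0 * chans, geom, grid_t, grid_p)
        np.testing.assert_allclose(pmap2, 9.0 * pmap)
        assert arg == arg2

    def test_empty_grid_rejected(self):
        geom = ArrayGeometry.planar_2x2()
        with pytest.raises(ValueError):
            cbf_azimuth(np.ones(4), geom, np.array([]), np.array([0.0]))


class TestMatching:
    def test_single_pair(self):
        recs = match_targets([100], tf=4.29e-11, azimuths=[(102, 15.0)],
                             vitals={100: {"rr_bpm": 18.0, "hr_bpm": 72.0}})
        assert len(recs) == 1
        assert recs[0].azimuth_deg == 15.0
        assert recs[0].rr_bpm == 18.0
        assert recs[0].flags == ""

    def test_unmatched_toa_flagged_not_dropped(self):
        recs = match_targets([100, 500], tf=4.29e-11,
                             azimuths=[(102, 15.0)], gate_tolerance=30)
        assert len(recs) == 2
        far = [r for r in recs if r.toa_bin == 500][0]
        assert np.isnan(far.azimuth_deg)
        assert far.flags == "azimuth-unknown"

    def test_sorted_by_range(self):
        recs = match_targets([300, 100, 200], tf=4.29e-11)
        assert [r.toa_bin for r in recs] == [100, 200, 300]
        assert [r.person_id for r in recs] == [0, 1, 2]

    def test_empty(self):
        assert match_targets([], tf=4.29e-11) == []
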