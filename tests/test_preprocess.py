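"""Clutter-suppression chain: projections, filters, block smoothing."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from uwbvitals.preprocess import (
    FilterSpec, PreprocessConfig, SmoothingConfig, UnstableFilterError,
    apply_iir, design_butterworth, remove_linear_trend, remove_static,
    smooth_slow_time, suppress_clutter)
from uwbvitals.signal_model import (EchoMatrix, SceneConfig, StaticScatterer,
                                    TargetPlacement, TimingSpec,
                                    VitalSignProfile, simulate_echo)

TS = 0.0341
TF = 1.0 / 23.328e9


def _echo(data, ts=TS):
    return EchoMatrix(np.asarray(data, dtype=float), ts=ts, tf=TF, fc=7.29e9)


class TestRemoveStatic:
    @pytest.mark.parametrize("mode", ["per_bin", "grand"])
    def test_constant_matrix_vanishes(self, mode):
        out = remove_static(_echo(np.full((10, 6), 3.7)), mode)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_tone_unchanged(self):
        m = np.zeros((200, 4))
        # integer number of periods -> zero mean
        m[:, 2] = np.sin(2 * np.pi * np.arange(200) / 20)
        out = remove_static(_echo(m), "per_bin")
        np.testing.assert_allclose(out.data, m, atol=1e-10)

    def test_per_bin_column_sums_vanish(self):
        rng = np.random.default_rng(0)
        out = remove_static(_echo(rng.normal(size=(5, 4))), "per_bin")
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-12)

    def test_single_frame_per_bin_rejected(self):
        with pytest.raises(ValueError):
            remove_static(_echo(np.ones((1, 4))), "per_bin")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            remove_static(_echo(np.ones((4, 4))), "median")


class TestDetrend:
    def test_exact_line_vanishes(self):
        m = np.arange(30)[:, None] * 3.0 + 5.0
        out = remove_linear_trend(_echo(np.tile(m, (1, 3))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_output_orthogonal_to_trend_basis(self):
        mvec = np.sin(2 * np.pi * 0.3 * np.arange(100) * TS)
        out = remove_linear_trend(_echo(mvec[:, None]))
        col = out.data[:, 0]
        ramp = np.arange(100, dtype=float)
        assert abs(col @ ramp) < 1e-8 * np.linalg.norm(col) * np.linalg.norm(ramp)
        assert abs(col.sum()) < 1e-8 * np.linalg.norm(col) * 10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        e = _echo(rng.normal(size=(40, 5)))
        once = remove_linear_trend(e)
        twice = remove_linear_trend(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_matches_scipy_detrend(self):
        rng = np.random.default_rng(2)
        e = _echo(rng.normal(size=(64, 7)))
        ours = remove_linear_trend(e).data
        ref = sp_signal.detrend(e.data, axis=0, type="linear")
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            remove_linear_trend(_echo(np.ones((2, 3))))


class TestButterworth:
    @pytest.mark.parametrize("cutoff,kind", [(0.1036, "lowpass"),
                                             (0.0212, "highpass")])
    def test_half_power_at_cutoff(self, cutoff, kind):
        spec = design_butterworth(5, cutoff, kind)
        h = spec.response(np.array([cutoff]))[0]
        assert h ** 2 == pytest.approx(0.5, abs=1e-6)

    def test_passband_edges(self):
        lp = design_butterworth(5, 0.1036, "lowpass")
        hp = design_butterworth(5, 0.0212, "highpass")
        assert lp.response(np.array([1e-9]))[0] == pytest.approx(1.0, abs=1e-9)
        assert hp.response(np.array([0.9999]))[0] == pytest.approx(1.0,
                                                                   abs=1e-3)

    def test_monotone_rolloff(self):
        spec = design_butterworth(5, 0.1036, "lowpass")
        h = spec.response(np.array([0.1036, 0.2072, 0.4]))
        assert h[1] < h[0] and h[2] < h[1]

    @pytest.mark.parametrize("cutoff", [0.0, 1.0, 1.5, -0.2])
    def test_invalid_cutoff(self, cutoff):
        with pytest.raises(ValueError):
            design_butterworth(5, cutoff, "lowpass")


class TestApplyIir:
    def test_impulse_response_energy_finite(self):
        spec = design_butterworth(5, 0.1036, "lowpass")
        m = np.zeros((400, 1))
        m[0, 0] = 1.0
        out = apply_iir(_echo(m), spec)
        ref = sp_signal.lfilter(spec.b, spec.a, m[:, 0])
        np.testing.assert_allclose(out.data[:, 0], ref)
        assert np.sum(out.data ** 2) < np.inf
        assert np.sum(np.abs(out.data[-20:])) < 1e-6

    def test_dc_rejected_by_highpass(self):
        spec = design_butterworth(5, 0.0212, "highpass")
        m = np.ones((4000, 1))
        out = apply_iir(_echo(m), spec)
        assert np.max(np.abs(out.data[-100:])) < 0.01

    def test_cascade_keeps_in_band_tone(self):
        t = np.arange(6000) * TS
        in_band = np.sin(2 * np.pi * 1.0 * t)     # 1 Hz: inside passband
        dc = 2.0 * np.ones_like(t)                 # at DC
        e = _echo((in_band + dc)[:, None])
        out = apply_iir(apply_iir(e, design_butterworth(5, 0.0212, "highpass")),
                        design_butterworth(5, 0.1036, "lowpass"))
        spec = np.abs(np.fft.rfft(out.data[1000:, 0]))
        freqs = np.fft.rfftfreq(out.data[1000:, 0].size, TS)
        tone = spec[np.argmin(np.abs(freqs - 1.0))]
        dc_mag = spec[0]
        assert tone > 0.1 * in_band.size / 4      # tone survives
        assert dc_mag < tone * 0.1                 # DC down > 20 dB

    def test_unstable_spec_rejected(self):
        bad = FilterSpec(order=1, cutoff=0.5, kind="lowpass",
                         b=np.array([1.0]), a=np.array([1.0, -1.5]))
        with pytest.raises(UnstableFilterError):
            apply_iir(_echo(np.ones((10, 1))), bad)


class TestSmoothing:
    def test_identity_block(self):
        rng = np.random.default_rng(3)
        e = _echo(rng.normal(size=(12, 3)))
        out = smooth_slow_time(e, SmoothingConfig(block=1))
        np.testing.assert_allclose(out.data, e.data)

    def test_block_means(self):
        m = np.arange(14 * 2, dtype=float).reshape(14, 2)
        out = smooth_slow_time(_echo(m), SmoothingConfig(block=7))
        assert out.data.shape == (2, 2)
        np.testing.assert_allclose(out.data[0], m[:7].mean(axis=0))
        np.testing.assert_allclose(out.data[1], m[7:].mean(axis=0))
        assert out.ts == pytest.approx(7 * TS)

    def test_noise_variance_reduced_sevenfold(self):
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(200):
            col = rng.normal(size=(70, 1))
            out = smooth_slow_time(_echo(col), SmoothingConfig(block=7))
            ratios.append(out.data.var() / col.var())
        # E[ratio] = 1/7; 3 sigma of the trial mean
        assert np.mean(ratios) == pytest.approx(1 / 7, abs=3 * np.std(ratios)
                                                / np.sqrt(len(ratios)))

    def test_block_longer_than_record(self):
        with pytest.raises(ValueError):
            smooth_slow_time(_echo(np.ones((5, 2))), SmoothingConfig(block=7))


class TestChain:
    def test_linearity(self):
        rng = np.random.default_rng(5)
        x = _echo(rng.normal(size=(120, 8)))
        y = _echo(rng.normal(size=(120, 8)))
        a, b = 2.3, -0.7
        combo = _echo(a * x.data + b * y.data)
        lhs = suppress_clutter(combo).data
        rhs = (a * suppress_clutter(x).data + b * suppress_clutter(y).data)
        scale = np.max(np.abs(lhs))
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-9 * scale)

    def test_statics_only_scene_annihilated(self):
        timing = TimingSpec(n_seg=256, n_segments=1, frame_count=700)
        tf = timing.tf(__import__("uwbvitals.signal_model",
                                  fromlist=["PulseSpec"]).PulseSpec())
        scene = SceneConfig(statics=[StaticScatterer(tau=100 * tf, a=1.0),
                                     StaticScatterer(tau=180 * tf, a=0.5)])
        echo, _ = simulate_echo(scene, timing=timing)
        post = suppress_clutter(echo)
        settled = post.data[10:]
        assert np.sum(settled ** 2) < 1e-4 * np.sum(echo.data ** 2)

    def test_vital_peak_preserved(self):
        # n_seg=682 keeps the frame interval (and hence the filter
        # passband) at the radar's 0.0341 s operating point
        timing = TimingSpec(n_seg=682, n_segments=1, frame_count=1024)
        prof = VitalSignProfile(d0=0.5, ar=0.004, ah=0.0003, fr=0.35, fh=1.3)
        scene = SceneConfig(targets=[TargetPlacement(prof)], awgn_sigma=0.05,
                            seed=6)
        echo, truth = simulate_echo(scene, timing=timing)
        post = suppress_clutter(echo)
        series = post.data[post.transient_frames:,
                           int(post.data.std(axis=0).argmax())]
        mag = np.abs(np.fft.rfft(series - series.mean()))
        freqs = np.fft.rfftfreq(series.size, post.ts)
        band = (freqs > 0.1) & (freqs < 0.7)
        f_peak = freqs[band][np.argmax(mag[band])]
        assert abs(f_peak - 0.35) <= freqs[1]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="cutoff"):
            PreprocessConfig(cutoff_hp=1.5)
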