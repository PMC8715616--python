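import numpy as np
import pytest

from mixclock import (
    SyntheticMixingConfig,
    compute_trace,
    expected_sd_trace,
    generate_mixing_video,
    ground_truth_mixing_time,
    mixing_time,
    render_frames,
    segment_reactor,
    simulate_concentration,
    simulate_ph_trace,
)
from mixclock.errors import ParameterError
from mixclock.synthetic import row_concentration

SMALL = dict(frame_w=40, frame_h=100, duration_s=40.0, t_add_s=5.0, fps=1.0)


class TestConcentrationField:
    def test_zero_before_addition(self):
        cfg = SyntheticMixingConfig(**SMALL)
        times, fields = simulate_concentration(cfg)
        pre = times < cfg.t_add_s
        assert pre.any() and np.all(fields[pre] == 0.0)

    def test_uniform_gradient_sd_decays_with_single_rate(self):
        # gradient=1: every row shares one rate, so the spatial SD of the
        # field is SD(t_add) * exp(-(t - t_add)/tau) exactly
        cfg = SyntheticMixingConfig(tau_s=6.0, gradient=1.0, **SMALL)
        times, rows = row_concentration(cfg)
        after = times >= cfg.t_add_s
        dt = times[after] - cfg.t_add_s
        sd = rows[after].std(axis=1)
        assert np.allclose(sd, sd[0] * np.exp(-dt / cfg.tau_s), rtol=1e-10)

    def test_fixed_point_is_uniform_column_mean(self):
        cfg = SyntheticMixingConfig(tau_s=2.0, **SMALL)
        _, rows = row_concentration(cfg, times=np.array([0.0, 1e6]))
        assert np.allclose(rows[-1], cfg.c_mean, atol=1e-12)

    def test_pulse_occupies_top_rows_only(self):
        cfg = SyntheticMixingConfig(**SMALL)
        _, rows = row_concentration(cfg, times=np.array([0.0, cfg.t_add_s]))
        at_add = rows[-1]
        assert np.all(at_add[: cfg.n_top_rows] == 1.0)
        assert np.all(at_add[cfg.n_top_rows :] == 0.0)

    def test_bottom_mixes_last_when_gradient_below_one(self):
        cfg = SyntheticMixingConfig(gradient=0.4, tau_s=6.0, **SMALL)
        _, rows = row_concentration(cfg, times=np.array([0.0, 20.0]))
        # deviation from the fixed point grows toward the bottom rows
        dev = np.abs(rows[-1] - cfg.c_mean)
        assert dev[-1] > dev[cfg.n_top_rows]

    @pytest.mark.parametrize(
        "bad",
        [dict(tau_s=0), dict(gradient=0), dict(gradient=1.5), dict(noise_sd=-1),
         dict(t_add_s=50.0)],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ParameterError):
            SyntheticMixingConfig(**{**SMALL, **bad})


class TestRendering:
    def test_noiseless_undyed_column_equals_clear_rgb(self):
        cfg = SyntheticMixingConfig(noise_sd=0.0, **SMALL)
        seq = generate_mixing_video(cfg)
        roi = cfg.column_roi
        pre = seq.frames[0, roi.y0 : roi.y1, roi.x0 : roi.x1]
        assert np.all(pre == np.array(cfg.clear_rgb, dtype=np.uint8))

    def test_same_seed_is_bit_identical(self):
        cfg = SyntheticMixingConfig(noise_sd=2.0, seed=42, **SMALL)
        a = generate_mixing_video(cfg)
        b = generate_mixing_video(cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_different_seed_differs(self):
        a = generate_mixing_video(
            SyntheticMixingConfig(noise_sd=2.0, seed=1, **SMALL)
        )
        b = generate_mixing_video(
            SyntheticMixingConfig(noise_sd=2.0, seed=2, **SMALL)
        )
        assert not np.array_equal(a.frames, b.frames)

    def test_background_pixels_constant_across_frames(self):
        cfg = SyntheticMixingConfig(noise_sd=3.0, **SMALL)
        seq = generate_mixing_video(cfg)
        roi = cfg.column_roi
        bg = np.ones(seq.frame_shape, dtype=bool)
        bg[roi.y0 : roi.y1, roi.x0 : roi.x1] = False
        assert np.all(seq.frames[:, bg] == seq.frames[0, bg])

    def test_field_shape_mismatch_rejected(self):
        cfg = SyntheticMixingConfig(**SMALL)
        with pytest.raises(ParameterError):
            render_frames(np.zeros((3, 5, 5)), cfg)


class TestGroundTruth:
    def test_closed_form_without_quantization(self):
        # continuous intensities, gradient=1: SD(t) = SD0 exp(-dt/8);
        # in-band of the 5%-of-range band at dt ~ 8 ln 20 ~ 23.97 -> 24 s
        cfg = SyntheticMixingConfig(tau_s=8.0, duration_s=60.0, fps=1.0)
        assert ground_truth_mixing_time(cfg, quantize=False) == 24.0

    def test_quantized_truth_matches_rendered_pipeline_exactly(self):
        cfg = SyntheticMixingConfig(tau_s=8.0, duration_s=60.0)
        seq = generate_mixing_video(cfg)
        mask = segment_reactor(seq, "reference_diff", threshold=10)
        trace = compute_trace(seq, mask)
        model = expected_sd_trace(cfg)
        assert np.abs(trace.values - model.values).max() < 0.5
        res = mixing_time(trace, cfg.t_add_s, band_mode="relative_range")
        assert res.t_mix_s == ground_truth_mixing_time(cfg)

    def test_wide_tolerance_mixes_almost_immediately(self):
        # as tolerance -> 1 the band swallows the whole range; only the peak
        # sample itself (the range maximum) can sit outside it
        cfg = SyntheticMixingConfig(tau_s=8.0, duration_s=60.0)
        t99 = ground_truth_mixing_time(cfg, tolerance=0.99, quantize=False)
        assert t99 <= 1.0 / cfg.fps

    def test_slow_bottom_prolongs_mixing(self):
        base = dict(tau_s=6.0, duration_s=120.0, frame_w=40, frame_h=100)
        t_uniform = ground_truth_mixing_time(SyntheticMixingConfig(**base))
        t_slow = ground_truth_mixing_time(
            SyntheticMixingConfig(gradient=0.5, **base)
        )
        assert t_slow >= t_uniform

    def test_degenerate_final_band_falls_back_with_warning(self):
        # noiseless quantized tail rounds to a uniform column -> final SD 0
        cfg = SyntheticMixingConfig(tau_s=4.0, duration_s=60.0)
        with pytest.warns(UserWarning, match="relative_range"):
            t = ground_truth_mixing_time(cfg, band_mode="relative_final")
        assert t == ground_truth_mixing_time(cfg, band_mode="relative_range")


class TestPhTrace:
    def test_endpoints(self):
        tr = simulate_ph_trace(ph0=7.0, ph_inf=9.0, tau_s=8.0, t_add_s=6.0)
        assert tr.values[tr.times_s < 6.0] == pytest.approx(7.0)
        i_add = np.searchsorted(tr.times_s, 6.0)
        assert tr.values[i_add] == pytest.approx(7.0)
        assert tr.values[-1] == pytest.approx(9.0, abs=1e-4)

    def test_mixing_time_matches_closed_form(self):
        tr = simulate_ph_trace(ph0=7.0, ph_inf=9.0, tau_s=8.0, t_add_s=6.0)
        res = mixing_time(tr, 6.0)
        assert res.t_mix_s == pytest.approx(12.0)

    def test_same_seed_identical(self):
        a = simulate_ph_trace(noise_sd=0.05, seed=7)
        b = simulate_ph_trace(noise_sd=0.05, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ph_trace(tau_s=0.0)
        with pytest.raises(ParameterError):
            simulate_ph_trace(interval_s=-3.0)


class TestPipelineRecovery:
    def test_tau_recovered_across_grid_and_noise(self):
        # headline property: the imaging chain reproduces the analytic
        # mixing time of the generated video within 2 sampling intervals
        for tau in (4.0, 8.0):
            for noise in (0.0, 2.0):
                cfg = SyntheticMixingConfig(
                    tau_s=tau, noise_sd=noise, seed=11,
                    duration_s=5 + 4 * tau + 25,
                )
                seq = generate_mixing_video(cfg)
                mask = segment_reactor(seq, "reference_diff", threshold=10)
                res = mixing_time(
                    compute_trace(seq, mask), cfg.t_add_s,
                    band_mode="relative_range",
                )
                truth = ground_truth_mixing_time(cfg)
                assert res.converged
                assert abs(res.t_mix_s - truth) <= 2.0

    def test_estimated_mixing_time_increases_with_tau(self):
        estimates = []
        for tau in (4.0, 8.0, 16.0):
            cfg = SyntheticMixingConfig(
                tau_s=tau, noise_sd=1.0, seed=5, duration_s=5 + 4 * tau + 25
            )
            seq = generate_mixing_video(cfg)
            mask = segment_reactor(seq, "reference_diff", threshold=10)
            res = mixing_time(
                compute_trace(seq, mask), cfg.t_add_s, band_mode="relative_range"
            )
            estimates.append(res.t_mix_s)
        assert estimates == sorted(estimates)
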