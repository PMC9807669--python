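"""Baseline, per-sweep SNR, gated averaging, zero-phase filtering."""

import numpy as np
import pytest

from vepscope import (
    SweepSet,
    average_sweeps,
    baseline,
    butterworth_filter,
    sweep_snr,
    vep_template,
)

FS = 50_000.0
ONSET = 0.2


def make_sweeps(traces, fs=FS, onset=ONSET):
    return SweepSet(np.atleast_2d(traces), fs, onset)


class TestBaseline:
    def test_constant_trace(self):
        trace = np.full(40_000, 5.0)
        assert baseline(trace, FS, ONSET) == 5.0

    def test_zero_mean_noise_converges_to_zero(self):
        rng = np.random.default_rng(3)
        sd = 1.0
        n_window = int(0.1 * FS)
        trace = rng.normal(0.0, sd, 40_000)
        assert abs(baseline(trace, FS, ONSET)) < 3 * sd / np.sqrt(n_window)

    def test_linear_ramp_gives_midpoint(self):
        # ramp 0..1 over the whole record; closed-form mean of the
        # arithmetic sequence over the window equals its midpoint value
        n = 40_000
        trace = np.linspace(0.0, 1.0, n, endpoint=False)
        i0, i1 = int((ONSET - 0.1) * FS), int(ONSET * FS)
        expected = (trace[i0] + trace[i1 - 1]) / 2
        assert baseline(trace, FS, ONSET) == pytest.approx(expected, rel=1e-12)

    def test_window_outside_record_rejected(self):
        with pytest.raises(ValueError):
            baseline(np.zeros(100), FS, onset_s=0.001, baseline_window_s=0.1)


class TestSweepSNR:
    def test_stationary_noise_snr_near_one(self):
        rng = np.random.default_rng(11)
        snrs = [
            sweep_snr(rng.normal(0, 10.0, 40_000), FS, ONSET) for _ in range(50)
        ]
        assert np.mean(snrs) == pytest.approx(1.0, abs=0.02)

    def test_noiseless_response_returns_inf(self):
        t = np.arange(40_000) / FS - ONSET
        trace = vep_template(t, scale=100.0)
        assert sweep_snr(trace, FS, ONSET) == np.inf

    def test_signal_plus_noise_rms_additivity(self):
        # deterministic component of response-window RMS 10, noise RMS 5
        # everywhere -> SNR ~ sqrt(125)/5 = sqrt(5)
        rng = np.random.default_rng(5)
        t = np.arange(40_000) / FS - ONSET
        resp_window = (t >= 0) & (t < 0.4)
        signal = np.where(resp_window, 10.0 * np.sqrt(2) * np.sin(2 * np.pi * 40 * t), 0.0)
        snrs = [
            sweep_snr(signal + rng.normal(0, 5.0, t.size), FS, ONSET)
            for _ in range(200)
        ]
        assert np.mean(snrs) == pytest.approx(np.sqrt(5.0), rel=0.02)


class TestAverageSweeps:
    def test_identical_sweeps_average_exactly(self):
        trace = np.sin(np.linspace(0, 20, 40_000)) * 10
        sweeps = make_sweeps(np.tile(trace, (5, 1)))
        avg = average_sweeps(sweeps, snr_threshold=0.0)
        np.testing.assert_allclose(avg.trace, trace, rtol=1e-12, atol=1e-15)
        assert avg.n_included == 5 and avg.n_excluded == 0

    def test_zero_threshold_includes_all(self):
        rng = np.random.default_rng(2)
        sweeps = make_sweeps(rng.normal(0, 1, (8, 40_000)))
        avg = average_sweeps(sweeps, snr_threshold=0.0)
        assert avg.n_included == 8

    def test_constructed_subthreshold_sweeps_excluded_exactly(self):
        """15 signal-bearing sweeps (SNR > 1 by construction) plus 5
        response-attenuated sweeps (SNR < 1) -> n_included == 15."""
        rng = np.random.default_rng(9)
        t = np.arange(40_000) / FS - ONSET
        resp = (t >= 0) & (t < 0.4)
        traces = []
        for k in range(20):
            noise = rng.normal(0, 5.0, t.size)
            if k < 15:
                trace = noise + np.where(resp, vep_template(t, scale=200.0), 0.0)
            else:
                trace = np.where(resp, 0.3 * noise, noise)  # response window damped
            traces.append(trace)
        traces = np.asarray(traces)
        # brute-force check of the construction with the same formula
        snrs = np.array([sweep_snr(tr, FS, ONSET) for tr in traces])
        assert np.all(snrs[:15] > 1.0) and np.all(snrs[15:] < 1.0)
        avg = average_sweeps(make_sweeps(traces), snr_threshold=1.0)
        assert avg.n_included == 15 and avg.n_excluded == 5

    def test_empty_sweepset_rejected(self):
        with pytest.raises(ValueError):
            average_sweeps(make_sweeps(np.zeros((0, 40_000))))

    def test_all_excluded_is_flagged_not_raised(self):
        rng = np.random.default_rng(4)
        t = np.arange(40_000) / FS - ONSET
        resp = (t >= 0) & (t < 0.4)
        traces = np.array(
            [np.where(resp, 0.2 * rng.normal(0, 5, t.size), rng.normal(0, 5, t.size))
             for _ in range(4)]
        )
        avg = average_sweeps(make_sweeps(traces), snr_threshold=1.0)
        assert not avg.valid
        assert avg.n_included == 0 and avg.n_excluded == 4

    def test_averaging_linearity_without_threshold(self):
        rng = np.random.default_rng(6)
        traces = rng.normal(0, 3, (6, 40_000))
        a = 2.5
        avg1 = average_sweeps(make_sweeps(traces), snr_threshold=0.0)
        avg2 = average_sweeps(make_sweeps(a * traces), snr_threshold=0.0)
        np.testing.assert_allclose(avg2.trace, a * avg1.trace, rtol=1e-9, atol=1e-12)

    def test_inclusion_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        t = np.arange(40_000) / FS - ONSET
        traces = np.array(
            [rng.normal(0, 5, t.size) + vep_template(t, scale=s) for s in np.linspace(0, 80, 10)]
        )
        counts = [
            average_sweeps(make_sweeps(traces), snr_threshold=thr).n_included
            for thr in (0.0, 0.9, 1.0, 1.1, 1.5, 3.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestButterworthFilter:
    def test_dc_unchanged_by_lowpass(self):
        trace = np.full(10_000, 7.5)
        out = butterworth_filter(trace, FS, "lowpass", 4, 200.0)
        np.testing.assert_allclose(out, trace, rtol=1e-9)

    def test_stopband_sinusoid_attenuated_per_analytic_response(self):
        # 1 kHz through 4-pole 200 Hz lowpass, applied forward-backward:
        # |H|^2 = 1 / (1 + (f/fc)^(2*4)) per pass, squared for two passes
        t = np.arange(50_000) / FS
        trace = np.sin(2 * np.pi * 1000.0 * t)
        out = butterworth_filter(trace, FS, "lowpass", 4, 200.0)
        single_pass = 1.0 / np.sqrt(1.0 + (1000.0 / 200.0) ** 8)
        bound = single_pass**2
        mid = out[10_000:40_000]  # avoid edge transients
        assert np.max(np.abs(mid)) <= bound * 1.05

    def test_passband_preserved_by_hardware_style_bandpass(self):
        # 50 Hz through the single-pole 10 Hz - 3 kHz bandpass: analytic
        # two-pass magnitude ~0.96, so amplitude preserved within 5%
        t = np.arange(100_000) / FS
        trace = np.sin(2 * np.pi * 50.0 * t)
        out = butterworth_filter(trace, FS, "bandpass", 1, (10.0, 3000.0))
        mid = out[30_000:70_000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, abs=0.05)

    def test_stopband_energy_never_increased(self):
        rng = np.random.default_rng(10)
        trace = rng.normal(0, 1, 50_000)
        out = butterworth_filter(trace, FS, "lowpass", 4, 200.0)
        # total energy must drop for broadband input through a lowpass
        assert np.sum(out**2) < np.sum(trace**2)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_filter(np.zeros(100), 1000.0, "lowpass", 4, 500.0)

    def test_invalid_order_and_kind_rejected(self):
        with pytest.raises(ValueError):
            butterworth_filter(np.zeros(100), FS, "lowpass", 0, 200.0)
        with pytest.raises(ValueError):
            butterworth_filter(np.zeros(100), FS, "notch", 2, 200.0)

    def test_output_length_matches_input(self):
        trace = np.random.default_rng(0).normal(size=12_345)
        out = butterworth_filter(trace, FS, "bandpass", 1, (10.0, 3000.0))
        assert out.shape == trace.shape
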