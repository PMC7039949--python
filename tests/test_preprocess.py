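import numpy as np
import pytest

from eabrkit.preprocess import (
    EvokedTrace,
    ExponentialFitError,
    FilterSettings,
    WindowError,
    alternating_polarity_average,
    bandpass,
    effective_sample_interval_us,
    epoch_average,
    interleave_upsample,
    native_sample_interval_us,
    preprocess_condition,
    remove_onset_artifact,
    subtract_exponential_trend,
)
from eabrkit.quantify import find_wave
from eabrkit.stimulus import Polarity, PulseShape
from eabrkit.synthdata import (
    ArtifactModel,
    Condition,
    ExpTail,
    GenParams,
    GroundTruth,
    HARDWARE_DELAYS_US,
    SweepSet,
    simulate_sweepset,
)

from conftest import make_condition

FS = 48828.125
DT_US = 20.48


def trace_from(samples, dt_us=DT_US / 4, t0_ms=5.0, **kw):
    return EvokedTrace(
        samples_uv=np.asarray(samples, float),
        sample_interval_us=dt_us,
        t0_us=t0_ms * 1000.0,
        **kw,
    )


def test_sampling_arithmetic():
    assert native_sample_interval_us(FS) == pytest.approx(20.48)
    assert native_sample_interval_us(48828.0) == pytest.approx(20.48, rel=1e-4)
    assert effective_sample_interval_us(FS) == pytest.approx(5.12)


class TestEpochAverage:
    def _sweepset(self, sweeps):
        return SweepSet(
            sweeps_uv=np.asarray(sweeps, float),
            sampling_rate_hz=FS,
            delay_tag_us=0.0,
            condition=make_condition(),
            t0_index=244,  # 5 ms pre-onset
        )

    def test_identical_sweeps_average_to_any_sweep(self):
        row = np.sin(np.arange(500) / 10.0)
        ss = self._sweepset(np.tile(row, (5, 1)))
        avg = epoch_average(ss)
        t_ms = (np.arange(500) - 244) * DT_US / 1000.0
        base = row[(t_ms >= -5.0) & (t_ms <= -1.0)].mean()
        np.testing.assert_allclose(avg.samples_uv, row - base, atol=1e-12)

    def test_constant_offset_removed(self):
        row = np.zeros(500)
        ss = self._sweepset(np.stack([row + 3.7, row + 3.7]))
        avg = epoch_average(ss)
        np.testing.assert_allclose(avg.samples_uv, 0.0, atol=1e-12)

    def test_sqrt_n_noise_reduction(self):
        rng = np.random.default_rng(0)
        sweeps = rng.standard_normal((400, 500))
        avg = epoch_average(self._sweepset(sweeps))
        assert avg.samples_uv.std() == pytest.approx(1 / 20.0, rel=0.10)

    def test_post_onset_baseline_rejected(self):
        ss = self._sweepset(np.zeros((2, 500)))
        with pytest.raises(WindowError):
            epoch_average(ss, baseline_window_ms=(-1.0, 1.0))

    def test_provenance_recorded(self):
        avg = epoch_average(self._sweepset(np.zeros((2, 500))))
        assert avg.provenance[0]["step"] == "epoch_average"
        assert avg.provenance[0]["n_sweeps"] == 2


class TestRemoveOnsetArtifact:
    def test_linear_segment_unchanged(self):
        t = np.arange(2000)
        trace = trace_from(0.01 * t)
        out = remove_onset_artifact(trace, (0.0, 0.3))
        np.testing.assert_allclose(out.samples_uv, trace.samples_uv, atol=1e-9)

    def test_spike_removed_outside_untouched(self):
        trace = trace_from(np.zeros(2000))
        idx = trace.window_indices((0.05, 0.25))
        trace.samples_uv[idx] = 50.0
        out = remove_onset_artifact(trace, (0.0, 0.3))
        assert np.abs(out.samples_uv[idx]).max() < 1e-9
        outside = np.ones(len(trace), bool)
        outside[trace.window_indices((-0.1, 0.4))] = False
        np.testing.assert_array_equal(out.samples_uv[outside],
                                      trace.samples_uv[outside])

    def test_simulated_artifact_residual_below_1pct(self, quiet_params):
        cond = make_condition(charge_nc=1.0)  # subthreshold: artifact only
        ss = simulate_sweepset(quiet_params, cond)
        trace = epoch_average(ss)
        peak = np.abs(trace.samples_uv).max()
        out = remove_onset_artifact(trace, (0.0, 0.3))
        win = out.window_indices((0.0, 0.3))
        assert np.abs(out.samples_uv[win]).max() < 0.01 * peak

    def test_window_outside_trace_raises(self):
        trace = trace_from(np.zeros(100), t0_ms=0.0)
        with pytest.raises(WindowError):
            remove_onset_artifact(trace, (50.0, 60.0))


class TestSubtractExponentialTrend:
    def test_pure_exponential_removed(self):
        trace = trace_from(np.zeros(4000))
        t = trace.time_ms
        a, tau, c = 40.0, 1.3, 2.0
        trace.samples_uv[:] = np.where(t > 0, a * np.exp(-t / tau) + c, 0.0)
        out = subtract_exponential_trend(trace, [(0.3, 2.7), (3.2, 11.0)])
        for win in [(0.3, 2.7), (3.2, 11.0)]:
            idx = out.window_indices(win)
            assert np.abs(out.samples_uv[idx]).max() < 1e-6 * a

    def test_wave_on_exponential_preserved(self):
        trace = trace_from(np.zeros(4000))
        t = trace.time_ms
        trace.samples_uv[:] = np.where(t > 0, 30.0 * np.exp(-t / 1.0), 0.0)
        sigma = 0.175
        tc = 1.05 + sigma
        u = (t - tc) / sigma
        wave = -u * np.exp(-0.5 * u * u) / (2 * np.exp(-0.5)) * 2.0  # 2 uV p2t
        trace.samples_uv += wave
        out = subtract_exponential_trend(trace, [(0.3, 2.7)])
        m = find_wave(out, "II")
        assert m.amplitude_uv == pytest.approx(2.0, rel=0.05)

    def test_fit_failure_names_window(self):
        trace = trace_from(np.full(4000, np.nan))
        with pytest.raises(ExponentialFitError) as err:
            subtract_exponential_trend(trace, [(0.3, 2.7)])
        assert err.value.window_ms == (0.3, 2.7)


class TestBandpass:
    def _sine_gain_db(self, freq_hz, settings=FilterSettings()):
        fs = 195312.5
        t = np.arange(int(fs * 0.5)) / fs
        x = np.sin(2 * np.pi * freq_hz * t)
        trace = EvokedTrace(x, 1e6 / fs, t0_us=0.0)
        y = bandpass(trace, settings).samples_uv
        mid = slice(len(x) // 4, 3 * len(x) // 4)  # avoid edges
        return 20 * np.log10(np.std(y[mid]) / np.std(x[mid]))

    def test_dc_rejected(self):
        trace = EvokedTrace(np.ones(5000), DT_US / 4, t0_us=0.0)
        out = bandpass(trace)
        mid = slice(1000, 4000)
        assert np.abs(out.samples_uv[mid]).max() < 1e-6

    def test_1khz_passband_unity(self):
        assert abs(self._sine_gain_db(1000.0)) < 0.5

    def test_10hz_attenuated_30db(self):
        assert self._sine_gain_db(10.0) < -30.0

    def test_causal_mode_recorded(self):
        trace = EvokedTrace(np.random.default_rng(0).standard_normal(4000),
                            DT_US / 4, t0_us=0.0)
        out = bandpass(trace, FilterSettings(zero_phase=False))
        assert out.provenance[-1]["application"] == "causal"

    def test_cutoff_above_nyquist_rejected(self):
        trace = EvokedTrace(np.zeros(100), 1e6 / 4000.0, t0_us=0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(trace, FilterSettings(high_cut_hz=3000.0))


class TestInterleaveUpsample:
    def _delayed_traces(self, fn, n=600, hardware=True):
        """Four delay-tagged traces sampling fn(t_us rel. onset)."""
        params = GenParams(noise_sd_uv=0.0, hardware_delay_grid=hardware)
        cond = make_condition()
        traces = []
        for tag in HARDWARE_DELAYS_US:
            shift = tag if hardware else (tag / 5.0) * DT_US / 4
            t_us = (np.arange(n) - 244) * DT_US - shift
            traces.append(
                EvokedTrace(fn(t_us), DT_US, t0_us=244 * DT_US,
                            condition=cond, delay_tag_us=tag)
            )
        return traces

    def test_effective_interval(self):
        traces = self._delayed_traces(lambda t: np.zeros_like(t))
        merged = interleave_upsample(traces)
        assert merged.sample_interval_us == pytest.approx(5.12)

    def test_constant_traces_give_constant_4x(self):
        traces = self._delayed_traces(lambda t: np.full_like(t, 2.5))
        merged = interleave_upsample(traces)
        assert len(merged) == 4 * 600
        np.testing.assert_allclose(merged.samples_uv, 2.5)

    def test_bandlimited_signal_matches_dense_reference(self):
        def fn(t_us):
            t = t_us / 1e6
            return (np.sin(2 * np.pi * 700 * t) + 0.5 *
                    np.sin(2 * np.pi * 2300 * t + 1.0))

        merged = interleave_upsample(self._delayed_traces(fn, hardware=True))
        dense = fn(merged.time_ms * 1000.0)
        err = np.sqrt(np.mean((merged.samples_uv - dense) ** 2))
        assert err < 0.02 * np.sqrt(np.mean(dense**2))

    def test_ideal_grid_is_exact(self):
        def fn(t_us):
            return np.sin(2 * np.pi * 700 * t_us / 1e6)

        merged = interleave_upsample(self._delayed_traces(fn, hardware=False))
        dense = fn(merged.time_ms * 1000.0)
        np.testing.assert_allclose(merged.samples_uv, dense, atol=1e-9)

    def test_missing_tag_rejected(self):
        traces = self._delayed_traces(lambda t: np.zeros_like(t))
        with pytest.raises(ValueError, match="delay tags"):
            interleave_upsample([traces[0], traces[0], traces[2], traces[3]])

    def test_wrong_count_rejected(self):
        traces = self._delayed_traces(lambda t: np.zeros_like(t))
        with pytest.raises(ValueError):
            interleave_upsample(traces[:3])


class TestAlternatingPolarityAverage:
    def test_antisymmetric_artifact_cancels_exactly(self):
        art = np.zeros(1000)
        art[200:230] = 100.0
        wave = np.exp(-((np.arange(1000) - 500.0) ** 2) / 200.0)
        a = trace_from(art + wave)
        c = trace_from(-art + wave)
        avg = alternating_polarity_average(a, c)
        np.testing.assert_allclose(avg.samples_uv, wave, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = trace_from(np.zeros(2000))
        b = trace_from(np.zeros(2000), dt_us=DT_US)
        with pytest.raises(ValueError, match="grid"):
            alternating_polarity_average(a, b)

    def test_same_polarity_rejected(self):
        cond = make_condition()
        a = trace_from(np.zeros(1000), condition=cond)
        b = trace_from(np.zeros(1000), condition=cond)
        with pytest.raises(ValueError, match="polarity"):
            alternating_polarity_average(a, b)


class TestFullChainRecovery:
    @pytest.mark.parametrize("gap_us", [10.0, 2900.0])
    @pytest.mark.parametrize("shape", list(PulseShape))
    def test_zero_noise_recovery(self, shape, gap_us):
        """Whole cleaning chain on noise-free data: wave-II amplitude
        within 5% and latency within one effective sample."""
        params = GenParams(noise_sd_uv=0.0, n_sweeps=2)
        cond = make_condition(shape=shape, charge_nc=5.8, interphase_gap_us=gap_us)
        groups = [
            simulate_sweepset(params, cond, d) for d in HARDWARE_DELAYS_US
        ]
        trace = preprocess_condition(groups)
        gt = GroundTruth(params=params, levels_nc=(5.8,))
        m = find_wave(trace, "II")
        assert m.present
        assert m.amplitude_uv == pytest.approx(
            gt.true_amplitude_uv(cond, "II"), rel=0.05
        )
        assert abs(m.peak_latency_ms - gt.true_latency_ms(cond, "II")) * 1000 <= 5.12

    def test_no_energy_injected_outside_artifact_windows(self):
        params = GenParams(noise_sd_uv=0.0, n_sweeps=2)
        cond = make_condition(charge_nc=5.8)
        groups = [simulate_sweepset(params, cond, d) for d in HARDWARE_DELAYS_US]
        raw = interleave_upsample([epoch_average(s) for s in groups])
        clean = preprocess_condition(groups)
        idx = clean.window_indices((0.5, 9.0))
        rms_before = np.sqrt(np.mean(raw.samples_uv[idx] ** 2))
        rms_after = np.sqrt(np.mean(clean.samples_uv[idx] ** 2))
        assert rms_after <= rms_before * 1.02

    def test_provenance_is_ordered_and_complete(self):
        params = GenParams(noise_sd_uv=0.0, n_sweeps=2)
        cond = make_condition(charge_nc=4.0)
        groups = [simulate_sweepset(params, cond, d) for d in HARDWARE_DELAYS_US]
        trace = preprocess_condition(groups)
        steps = [p["step"] for p in trace.provenance]
        assert steps == [
            "epoch_average",
            "interleave_upsample",
            "remove_onset_artifact",
            "bandpass",
        ]
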