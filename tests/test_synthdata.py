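import numpy as np
import pytest

from eabrkit.preprocess import epoch_average, interleave_upsample
from eabrkit.quantify import find_wave
from eabrkit.stimulus import Polarity, PulseShape
from eabrkit.synthdata import (
    ArtifactModel,
    Condition,
    DelayTagError,
    ExpTail,
    GenParams,
    GroundTruth,
    GrowthModel,
    HARDWARE_DELAYS_US,
    SweepSet,
    clean_trace,
    simulate_study,
    simulate_sweepset,
)

from conftest import make_condition


class TestSimulateSweepset:
    def test_default_n_sweeps_is_400(self):
        params = GenParams(noise_sd_uv=0.0)
        assert params.n_sweeps == 400
        ss = simulate_sweepset(params, make_condition())
        assert ss.n_sweeps == 400

    def test_below_threshold_artifact_only(self, quiet_params):
        cond = make_condition(charge_nc=1.0)  # below every true threshold
        ss = simulate_sweepset(quiet_params, cond)
        art, _ = clean_trace(quiet_params, cond, include_waves=False)
        np.testing.assert_array_equal(ss.sweeps_uv[0], art)

    def test_polarity_flip_negates_artifact_not_waves(self, quiet_params):
        charge = 6.0
        a = make_condition(polarity=Polarity.ANODIC_FIRST, charge_nc=charge)
        c = make_condition(polarity=Polarity.CATHODIC_FIRST, charge_nc=charge)
        sa = simulate_sweepset(quiet_params, a).sweeps_uv[0]
        sc = simulate_sweepset(quiet_params, c).sweeps_uv[0]
        art_a, _ = clean_trace(quiet_params, a, include_waves=False)
        art_c, _ = clean_trace(quiet_params, c, include_waves=False)
        np.testing.assert_allclose(art_a, -art_c, atol=1e-12)
        # wave component (sweep minus artifact) identical across polarity
        np.testing.assert_allclose(sa - art_a, sc - art_c, atol=1e-12)

    def test_delay_tag_validation(self, quiet_params):
        with pytest.raises(DelayTagError):
            simulate_sweepset(quiet_params, make_condition(), delay_tag_us=7.0)

    def test_delay_shifts_signal(self, quiet_params):
        cond = make_condition(charge_nc=6.0)
        t0 = simulate_sweepset(quiet_params, cond, 0.0).sweeps_uv[0]
        t15 = simulate_sweepset(quiet_params, cond, 15.0).sweeps_uv[0]
        assert not np.allclose(t0, t15)

    def test_exp_tail_only_for_long_gap(self, quiet_params):
        short = make_condition(charge_nc=1.0, interphase_gap_us=10.0)
        long_ = make_condition(charge_nc=1.0, interphase_gap_us=2900.0)
        s_short = simulate_sweepset(quiet_params, short).sweeps_uv[0]
        s_long = simulate_sweepset(quiet_params, long_).sweeps_uv[0]
        # 1.5 ms after onset: short-gap artifact is over, long-gap tail is not
        dt = quiet_params.sample_interval_us
        i = int(round(5e3 / dt)) + int(round(1.5e3 / dt))
        assert s_short[i] == 0.0
        assert abs(s_long[i]) > 1.0

    def test_facial_nerve_flag(self):
        params = GenParams(noise_sd_uv=0.0, n_sweeps=1, facial_nerve_onset_nc=5.0)
        low = simulate_sweepset(params, make_condition(charge_nc=4.0))
        high = simulate_sweepset(params, make_condition(charge_nc=5.5))
        assert not low.above_facial_nerve
        assert high.above_facial_nerve


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        params = GenParams(n_sweeps=10, seed=42)
        cond = make_condition(charge_nc=4.0)
        a = simulate_sweepset(params, cond, 5.0)
        b = simulate_sweepset(params, cond, 5.0)
        np.testing.assert_array_equal(a.sweeps_uv, b.sweeps_uv)

    def test_different_seed_differs(self):
        params = GenParams(n_sweeps=10)
        cond = make_condition(charge_nc=4.0)
        a = simulate_sweepset(params, cond, seed=1)
        b = simulate_sweepset(params, cond, seed=2)
        assert not np.allclose(a.sweeps_uv, b.sweeps_uv)

    def test_sweep_substreams_stable_under_n_sweeps(self):
        """Per-sweep keying: the first sweeps do not depend on n_sweeps."""
        cond = make_condition(charge_nc=4.0)
        a = simulate_sweepset(GenParams(n_sweeps=5, seed=3), cond)
        b = simulate_sweepset(GenParams(n_sweeps=10, seed=3), cond)
        np.testing.assert_array_equal(a.sweeps_uv, b.sweeps_uv[:5])

    def test_study_deterministic(self):
        kw = dict(
            params=GenParams(n_sweeps=3, seed=9),
            shapes=[PulseShape.REC],
            polarities=[Polarity.ANODIC_FIRST],
            levels_nc=[2.2, 4.8],
        )
        s1 = simulate_study(**kw)
        s2 = simulate_study(**kw)
        for a, b in zip(s1.sweepsets, s2.sweepsets):
            np.testing.assert_array_equal(a.sweeps_uv, b.sweeps_uv)


class TestStatisticalProperties:
    def test_averaging_reduces_noise_sqrt_n(self):
        """400-sweep average noise sd ~= per-sweep sd / 20 (tol 10%)."""
        params = GenParams(n_sweeps=400, noise_sd_uv=2.0, seed=11)
        cond = make_condition(charge_nc=1.0)  # subthreshold: artifact only
        ss = simulate_sweepset(params, cond)
        clean, t0 = clean_trace(params, cond)
        resid = ss.sweeps_uv.mean(axis=0) - clean
        # use the pre-onset region (pure noise)
        sd = resid[: t0 - 10].std()
        assert sd == pytest.approx(2.0 / np.sqrt(400), rel=0.10)

    def test_artifact_antisymmetry_cancels_in_polarity_mean(self):
        params = GenParams(n_sweeps=100, noise_sd_uv=0.5, seed=13)
        charge = 1.0  # subthreshold, artifact only
        a = simulate_sweepset(
            params, make_condition(polarity=Polarity.ANODIC_FIRST, charge_nc=charge)
        )
        c = simulate_sweepset(
            params, make_condition(polarity=Polarity.CATHODIC_FIRST, charge_nc=charge)
        )
        combined = 0.5 * (a.sweeps_uv.mean(axis=0) + c.sweeps_uv.mean(axis=0))
        dt = params.sample_interval_us
        t0 = a.t0_index
        art_win = combined[t0 : t0 + int(round(100.0 / dt)) + 1]
        art_peak = np.abs(a.sweeps_uv.mean(axis=0)[t0:]).max()
        noise_floor = 0.5 / np.sqrt(100) / np.sqrt(2)
        assert np.abs(art_win).max() < 5 * noise_floor
        assert np.abs(art_win).max() < 0.01 * art_peak


class TestWaveRecoveryNoiseFree:
    @pytest.mark.parametrize("shape", list(PulseShape))
    def test_find_wave_recovers_truth_without_artifact(self, shape):
        """No noise, no artifact: amplitude within 1%, latency within one
        effective sample (5.12 us)."""
        params = GenParams(
            noise_sd_uv=0.0,
            n_sweeps=1,
            artifact_model=ArtifactModel(peak_uv_per_ua=0.0, exp_tail=None),
        )
        cond = make_condition(shape=shape, charge_nc=5.8)
        traces = [
            epoch_average(simulate_sweepset(params, cond, d))
            for d in HARDWARE_DELAYS_US
        ]
        merged = interleave_upsample(traces)
        gt = GroundTruth(params=params, levels_nc=(5.8,))
        m = find_wave(merged, "II")
        true_amp = gt.true_amplitude_uv(cond, "II")
        true_lat = gt.true_latency_ms(cond, "II")
        assert m.present
        assert m.amplitude_uv == pytest.approx(true_amp, rel=0.01)
        assert abs(m.peak_latency_ms - true_lat) * 1000 <= 5.12


class TestGroundTruth:
    def test_threshold_is_first_supra_criterion_level(self):
        params = GenParams()
        levels = (1.6, 2.2, 2.8, 3.4, 4.0, 4.8, 5.8, 7.0)
        gt = GroundTruth(params=params, levels_nc=levels)
        # REC true zero-crossing at 3.85 nC -> first tested level above
        # criterion is 4.0
        assert gt.true_threshold_nc(PulseShape.REC) == 4.0
        assert gt.true_threshold_nc(PulseShape.RAMP_UP) == 2.2
        assert gt.true_threshold_nc(PulseShape.RAMP_LONG) == 2.8
        assert gt.true_threshold_nc(PulseShape.RAMP_DOWN) == 3.4

    def test_roundtrip_dict(self):
        gt = GroundTruth(params=GenParams(seed=5), levels_nc=(1.0, 2.0))
        gt2 = GroundTruth.from_dict(gt.to_dict())
        assert gt2.params.seed == 5
        assert gt2.levels_nc == (1.0, 2.0)
        assert gt2.true_threshold_nc(PulseShape.REC) == gt.true_threshold_nc(
            PulseShape.REC
        )

    def test_growth_model_validation(self):
        with pytest.raises(ValueError):
            GrowthModel(threshold_nc=2.0, slope_uv_per_nc=-1.0)
        with pytest.raises(ValueError):
            GrowthModel(threshold_nc=2.0, slope_uv_per_nc=1.0,
                        saturation_slope_uv_per_nc=0.5)

    def test_saturating_growth(self):
        g = GrowthModel(threshold_nc=2.0, slope_uv_per_nc=2.0, knee_nc=5.0,
                        saturation_slope_uv_per_nc=-0.5)
        assert g.amplitude_uv(1.0) == 0.0
        assert g.amplitude_uv(4.0) == pytest.approx(4.0)
        assert g.amplitude_uv(7.0) == pytest.approx(6.0 - 1.0)
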