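import numpy as np
import pytest

from lumirhythm import (
    LuminescenceTrace,
    ParameterError,
    PreprocessConfig,
    TraceLengthError,
    average_replicates,
    boxcar_gain,
    detrend_moving_average,
    fit_fixed_period,
    fit_sinusoid,
    get_preset,
    preprocess_trace,
    simulate_plate,
    smooth_moving_average,
)
from lumirhythm.preprocess import window_samples

from conftest import clean_params
from lumirhythm import simulate_trace


class TestConfig:
    def test_windows_become_odd_sample_counts(self):
        assert window_samples(24.0, 0.2) == 121
        assert window_samples(2.0, 0.2) == 11
        assert window_samples(2.2, 0.2) == 11

    def test_detrend_must_exceed_smooth(self):
        with pytest.raises(ParameterError):
            PreprocessConfig(detrend_window_h=1.0, smooth_window_h=2.0)

    def test_unknown_edge_policy(self):
        with pytest.raises(ParameterError):
            PreprocessConfig(edge_policy="pad")


class TestDetrend:
    def test_annihilates_affine_baseline(self, time_72h):
        y = 3.0 + 0.7 * time_72h
        tr = LuminescenceTrace("w", time_72h, y)
        out = detrend_moving_average(tr)
        assert np.max(np.abs(out.signal)) < 1e-9
        assert out.steps_applied == ("detrend_movavg",)

    def test_trim_drops_half_window(self, make_sine):
        out = detrend_moving_average(make_sine())
        # 121-sample window at 0.2 h: 60 samples (12 h) trimmed per side
        assert out.time_h[0] == pytest.approx(12.0)
        assert out.time_h[-1] == pytest.approx(60.0)
        assert out.n == 361 - 120

    def test_shrink_keeps_full_length(self, make_sine):
        cfg = PreprocessConfig(edge_policy="shrink")
        out = detrend_moving_average(make_sine(), cfg)
        assert out.n == 361

    def test_full_period_window_passes_sinusoid_with_dirichlet_gain(
        self, make_sine
    ):
        # The 121-sample (24.0 h span) boxcar of a 24 h sinusoid is
        # −sin/121 (Dirichlet kernel), so detrending returns
        # (1 + 1/121)·input on the retained region — the exact discrete
        # analogue of "a full-period mean annihilates the sinusoid".
        tr = make_sine(period=24.0, amplitude=1.0)
        out = detrend_moving_average(tr)
        keep = slice(60, 361 - 60)
        expected = tr.signal[keep] * (1.0 + 1.0 / 121.0)
        np.testing.assert_allclose(out.signal, expected, atol=1e-9)

    def test_decaying_baseline_plus_sinusoid_recovers_period(self, time_72h):
        y = 100 * np.exp(-time_72h / 48) + 10 * np.sin(
            2 * np.pi * time_72h / 24
        )
        tr = LuminescenceTrace("w", time_72h, y)
        fit = fit_sinusoid(detrend_moving_average(tr))
        assert abs(fit.period_h - 24.0) < 0.2

    def test_residual_baseline_matches_direct_convolution_oracle(
        self, time_72h
    ):
        y = 100 * np.exp(-time_72h / 48) + 10 * np.sin(
            2 * np.pi * time_72h / 24
        )
        tr = LuminescenceTrace("w", time_72h, y)
        out = detrend_moving_average(tr)
        # independent oracle: direct windowed means by explicit slicing
        h = 60
        oracle = np.array(
            [y[i - h : i + h + 1].mean() for i in range(h, 361 - h)]
        )
        np.testing.assert_allclose(out.signal, y[h : 361 - h] - oracle,
                                   atol=1e-9)

    def test_too_short_trace_raises(self):
        t = np.arange(0.0, 40.0, 0.2)
        tr = LuminescenceTrace("w", t, np.sin(t))
        with pytest.raises(TraceLengthError, match="48"):
            detrend_moving_average(tr)

    def test_irregular_sampling_rejected(self):
        t = np.concatenate([np.arange(0, 50, 0.2), [50.5, 51.5]])
        tr = LuminescenceTrace("w", t, np.ones_like(t))
        with pytest.raises(ParameterError, match="regular"):
            detrend_moving_average(tr)


class TestSmooth:
    def test_constant_trace_unchanged(self, time_72h):
        tr = LuminescenceTrace("w", time_72h, np.full(361, 42.0))
        out = smooth_moving_average(tr)
        np.testing.assert_allclose(out.signal, 42.0, atol=1e-12)
        assert out.steps_applied == ("smooth_movavg",)

    def test_window_under_three_samples_rejected(self, make_sine):
        cfg = PreprocessConfig(smooth_window_h=0.3)
        with pytest.raises(ParameterError, match="3 samples"):
            smooth_moving_average(make_sine(), cfg)

    def test_noise_variance_shrinks_by_window_size(self):
        rng = np.random.default_rng(42)
        n, w = 10_000, 11
        t = np.arange(n) * 0.2
        y = rng.normal(0.0, 1.0, n)
        out = smooth_moving_average(
            LuminescenceTrace("w", t, y),
            PreprocessConfig(smooth_window_h=2.0),
        )
        ratio = out.signal.var() / y.var()
        assert abs(ratio - 1.0 / w) < 0.15 / w

    @pytest.mark.parametrize("window_h,period", [(2.0, 24.0), (4.0, 24.0),
                                                 (2.0, 16.0)])
    def test_sinusoid_attenuation_matches_sinc_closed_form(
        self, make_sine, window_h, period
    ):
        tr = make_sine(period=period, amplitude=1.0)
        cfg = PreprocessConfig(smooth_window_h=window_h)
        out = smooth_moving_average(tr, cfg)
        _, amp, _, _ = fit_fixed_period(out, period)
        x = np.pi * window_h / period
        sinc = abs(np.sin(x) / x)
        assert abs(amp - sinc) / sinc < 0.01


class TestAverageReplicates:
    def test_identical_traces_average_to_themselves(self, make_sine):
        from lumirhythm import PlateRecording

        trs = tuple(make_sine(well=f"A{i}") for i in range(3))
        plate = PlateRecording(trs, {f"A{i}": "c" for i in range(3)})
        mean = average_replicates(plate, "c")
        assert mean.well_id == "c:mean"
        np.testing.assert_allclose(mean.signal, trs[0].signal, atol=1e-12)

    def test_unknown_condition_lists_available(self, make_sine):
        from lumirhythm import ConditionNotFoundError, PlateRecording

        plate = PlateRecording((make_sine(),), {"W1": "NIH3T3"})
        with pytest.raises(ConditionNotFoundError, match="NIH3T3"):
            average_replicates(plate, "LLC")

    def test_synchronized_wells_preserve_amplitude(self):
        plate = simulate_plate(get_preset("NIH3T3", n_wells=3, seed=11))
        mean_fit = fit_sinusoid(
            preprocess_trace(average_replicates(plate, "NIH3T3"))
        )
        single_fit = fit_sinusoid(preprocess_trace(plate.traces[0]))
        assert abs(mean_fit.amplitude - single_fit.amplitude) < (
            0.10 * single_fit.amplitude
        )

    def test_unsynchronized_ensemble_average_flattens(self):
        plate = simulate_plate(get_preset("unsync", n_wells=24, seed=5))
        mean_fit = fit_sinusoid(
            preprocess_trace(average_replicates(plate, "unsync"))
        )
        single = fit_sinusoid(
            preprocess_trace(simulate_trace(clean_params(amplitude0=50.0)))
        )
        assert mean_fit.amplitude < 0.30 * single.amplitude


class TestFilterTheory:
    def test_boxcar_gain_limits(self):
        assert boxcar_gain(24.0, 0.1, 0.2) == 1.0  # single-sample window
        # long window of an exact period: small negative Dirichlet leakage
        assert boxcar_gain(24.0, 24.0, 0.2) == pytest.approx(-1 / 121)

    def test_zero_crossing_spacing_preserved(self, make_sine):
        tr = make_sine(period=24.0)
        out = preprocess_trace(tr)

        def crossings(trc):
            s = trc.signal
            idx = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
            return trc.time_h[idx]

        a, b = crossings(tr), crossings(out)
        common = [x for x in a if b.size and (np.abs(b - x).min() < 0.2)]
        assert len(common) == len(b)
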