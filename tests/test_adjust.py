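"""Edge handling, baseline correction, dB conversion, channel averaging."""

import numpy as np
import pytest

from wavelet_tf import (
    BaselineSpec,
    EpochedData,
    TFResult,
    average_channels,
    baseline_correct,
    build_bank_range,
    chop_edges,
    cwt_single,
    pad_edges,
    to_db,
)
from wavelet_tf.errors import (
    DegenerateBaselineError,
    DomainError,
    InvalidParameterError,
    UnsupportedMeasureError,
)


def _result(values, fs=500.0, t0=-500.0, measure="amplitude", **kw):
    n_ch, n_f, n_t = values.shape
    return TFResult(
        values=values,
        measure=measure,
        frequencies=10.0 + np.arange(n_f),
        time_ms=t0 + np.arange(n_t) * 1000.0 / fs,
        channel_labels=[f"C{i}" for i in range(n_ch)],
        **kw,
    )


def _random_result(rng, n_ch=3, n_f=5, n_t=501):
    return _result(rng.random((n_ch, n_f, n_t)) + 0.5)


class TestChop:
    def test_chop_arithmetic_minus500_1500(self, rng):
        res = _result(rng.random((2, 3, 1001)))
        out = chop_edges(res, 300)
        assert out.time_ms[0] == pytest.approx(-200.0)
        assert out.time_ms[-1] == pytest.approx(1200.0)
        assert out.time_ms[-1] - out.time_ms[0] == pytest.approx(1400.0)
        assert out.chopped_ms == pytest.approx(300.0)
        assert np.array_equal(out.values, res.values[:, :, 150:851])

    def test_chop_zero_is_identity(self, rng):
        res = _random_result(rng)
        out = chop_edges(res, 0)
        assert np.array_equal(out.values, res.values)
        assert np.array_equal(out.time_ms, res.time_ms)

    def test_over_chop_rejected(self, rng):
        res = _result(rng.random((1, 2, 501)), t0=0.0)  # 1000 ms long
        with pytest.raises(InvalidParameterError):
            chop_edges(res, 600)


class TestPad:
    def _epochs(self, data, fs=500.0):
        n = data.shape[-1]
        return EpochedData(
            data=data,
            sampling_rate=fs,
            time_ms=(np.arange(n) - n // 2) * 1000.0 / fs,
            channel_labels=[f"C{i}" for i in range(data.shape[1])],
        )

    def test_pad_zero_is_identity(self, rng):
        ep = self._epochs(rng.standard_normal((2, 2, 301)))
        out = pad_edges(ep, 0)
        assert np.array_equal(out.data, ep.data)

    def test_ms_to_sample_conversion(self, rng):
        ep = self._epochs(rng.standard_normal((1, 1, 301)))
        out = pad_edges(ep, 200, "zero")
        assert out.n_samples == 301 + 2 * 100
        assert out.padded_ms == pytest.approx(200.0)
        assert np.all(out.data[0, 0, :100] == 0)
        dt = np.diff(out.time_ms)
        assert np.allclose(dt, 2.0)

    def test_mirror_pad_is_continuous_at_edges(self, rng):
        ep = self._epochs(rng.standard_normal((1, 1, 301)))
        out = pad_edges(ep, 50, "mirror")
        # reflection: sample just outside equals sample just inside
        assert out.data[0, 0, 24] == ep.data[0, 0, 1]
        assert out.data[0, 0, -25] == ep.data[0, 0, -2]

    def test_negative_padding_rejected(self, rng):
        ep = self._epochs(rng.standard_normal((1, 1, 301)))
        with pytest.raises(InvalidParameterError):
            pad_edges(ep, -10)

    def test_pad_transform_chop_restores_axis_and_reduces_edge_error(self):
        """Mirror padding reduces edge distortion versus the unpadded CWT.

        Oracle: the same sinusoid transformed on an extended signal, with the
        extension cut away, gives the distortion-free interior reference.
        """
        fs, f0 = 250.0, 10.0
        bank = build_bank_range(10, 20, 5, 7, fs)
        n = 501
        t_full = np.arange(-400, n + 400) / fs
        full = np.cos(2 * np.pi * f0 * t_full)
        s = full[400 : 400 + n]
        ref = cwt_single(full, bank)[:, 400 : 400 + n]  # distortion-free
        plain = cwt_single(s, bank)
        ep = EpochedData(
            data=s.reshape(1, 1, -1),
            sampling_rate=fs,
            time_ms=np.arange(n) * 1000.0 / fs,
            channel_labels=["C0"],
        )
        pad_ms = 200.0
        padded = pad_edges(ep, pad_ms, "mirror")
        npad = int(pad_ms * fs / 1000)
        padded_cwt = cwt_single(padded.data[0, 0], bank)[:, npad:-npad]
        assert padded_cwt.shape == plain.shape
        # compare worst-case edge error at the lowest frequency
        edge = 30
        err_plain = np.abs(np.abs(plain[0]) - np.abs(ref[0]))[:edge].max()
        err_padded = np.abs(np.abs(padded_cwt[0]) - np.abs(ref[0]))[:edge].max()
        assert err_padded < err_plain


class TestBaseline:
    def test_subtractive_zeroes_window_mean(self, rng):
        res = _random_result(rng)
        spec = BaselineSpec("subtractive", (-400, -100))
        out = baseline_correct(res, spec)
        i0 = np.argmin(np.abs(out.time_ms + 400))
        i1 = np.argmin(np.abs(out.time_ms + 100))
        m = out.values[:, :, i0 : i1 + 1].mean(axis=-1)
        assert np.max(np.abs(m)) <= 1e-12

    def test_divisive_of_flat_surface_is_one(self):
        res = _result(np.full((2, 3, 501), 4.2))
        out = baseline_correct(res, BaselineSpec("divisive", (-400, 0)))
        assert np.allclose(out.values, 1.0, atol=1e-14)

    def test_subtractive_normalized_of_flat_surface_is_zero(self):
        res = _result(np.full((2, 3, 501), 4.2))
        out = baseline_correct(res, BaselineSpec("subtractive_normalized", (-400, 0)))
        assert np.allclose(out.values, 0.0, atol=1e-14)

    def test_default_window_is_full_prestimulus(self, rng):
        res = _random_result(rng)
        out = baseline_correct(res, BaselineSpec("subtractive"))
        pre = res.time_ms <= 0
        assert np.max(np.abs(out.values[:, :, pre].mean(axis=-1))) <= 1e-12

    def test_subtractive_idempotent(self, rng):
        res = _random_result(rng)
        spec = BaselineSpec("subtractive", (-300, 0))
        once = baseline_correct(res, spec)
        twice = baseline_correct(once, spec)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_commutes_with_channel_average(self, rng):
        res = _random_result(rng)
        spec = BaselineSpec("subtractive", (-300, 0))
        a = average_channels(baseline_correct(res, spec), ["C0", "C2"])
        b = baseline_correct(average_channels(res, ["C0", "C2"]), spec)
        assert np.max(np.abs(a.values - b.values)) <= 1e-12

    def test_divisive_invariant_subtractive_equivariant_under_rescaling(self, rng):
        res = _random_result(rng)
        scaled = res.copy_with(values=res.values * 3.7)
        div = BaselineSpec("divisive", (-300, 0))
        sub = BaselineSpec("subtractive", (-300, 0))
        assert np.allclose(
            baseline_correct(res, div).values,
            baseline_correct(scaled, div).values,
            atol=1e-12,
        )
        assert np.allclose(
            baseline_correct(res, sub).values * 3.7,
            baseline_correct(scaled, sub).values,
            atol=1e-10,
        )

    def test_per_frequency_baselines_are_independent(self, rng):
        res = _random_result(rng)
        out = baseline_correct(res, BaselineSpec("subtractive", (-300, 0)))
        # correcting a single-frequency slice alone gives the same row
        one = res.copy_with(
            values=res.values[:, 1:2, :], frequencies=res.frequencies[1:2]
        )
        out_one = baseline_correct(one, BaselineSpec("subtractive", (-300, 0)))
        assert np.allclose(out.values[:, 1:2, :], out_one.values, atol=1e-14)

    def test_zero_baseline_rejected_for_divisive(self):
        values = np.ones((1, 1, 501))
        values[0, 0, :100] = 0.0
        res = _result(values)
        with pytest.raises(DegenerateBaselineError):
            baseline_correct(res, BaselineSpec("divisive", (-500, -400)))

    def test_complex_measure_rejected(self, rng):
        res = _result(
            rng.random((1, 2, 501)) + 1j * rng.random((1, 2, 501)), measure="complex"
        )
        with pytest.raises(UnsupportedMeasureError):
            baseline_correct(res, BaselineSpec("subtractive"))

    def test_bad_window_order_rejected(self):
        with pytest.raises(InvalidParameterError):
            BaselineSpec("subtractive", (100, -100))


class TestDb:
    def test_power_one_maps_to_zero_db(self):
        res = _result(np.ones((1, 1, 501)), measure="power")
        assert np.allclose(to_db(res).values, 0.0)

    def test_amplitude_ten_maps_to_twenty_db(self):
        res = _result(np.full((1, 1, 501), 10.0))
        assert np.allclose(to_db(res).values, 20.0)

    def test_amplitude_and_power_conventions_agree(self, rng):
        a = rng.random((2, 3, 101)) + 0.1
        amp = _result(a)
        pwr = _result(a**2, measure="power")
        assert np.allclose(to_db(amp).values, to_db(pwr).values, atol=1e-12)

    def test_nonpositive_values_rejected_with_advice(self, rng):
        res = _random_result(rng)
        corrected = baseline_correct(res, BaselineSpec("subtractive"))
        with pytest.raises(DomainError, match="divisive"):
            to_db(corrected)


class TestAverageChannels:
    def test_single_channel_subset_is_identity(self, rng):
        res = _random_result(rng)
        out = average_channels(res, ["C1"])
        assert np.array_equal(out.values[0], res.values[1])
        assert out.channel_labels == ["C1"]

    def test_opposite_channels_cancel(self):
        v = np.random.default_rng(0).standard_normal((1, 2, 101))
        values = np.concatenate([v, -v], axis=0)
        res = _result(values, measure="power", baseline=BaselineSpec("subtractive"))
        out = average_channels(res, ["C0", "C1"])
        assert np.allclose(out.values, 0.0, atol=1e-15)

    def test_matches_elementwise_mean_oracle(self, rng):
        res = _random_result(rng, n_ch=5)
        subset = ["C0", "C2", "C3"]
        out = average_channels(res, subset)
        brute = (res.values[0] + res.values[2] + res.values[3]) / 3.0
        assert np.allclose(out.values[0], brute, atol=1e-14)
        assert out.channel_labels == ["avg(C0+C2+C3)"]

    def test_unknown_label_named_in_error(self, rng):
        res = _random_result(rng)
        with pytest.raises(InvalidParameterError, match="Cz"):
            average_channels(res, ["C0", "Cz"])
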