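"""CWT and trial averaging: oracles, linearity, induced vs evoked."""

import numpy as np
import pytest

from wavelet_tf import (
    BurstSpec,
    EpochedData,
    SyntheticSpec,
    build_bank_range,
    cwt_single,
    generate,
    remove_dc,
    transform_evoked,
    transform_total_induced,
)
from wavelet_tf.errors import InvalidParameterError, SignalTooShortError


def _epochs_from_array(data, fs=250.0):
    n_s = data.shape[-1]
    t = (np.arange(n_s) - n_s // 2) * 1000.0 / fs
    return EpochedData(
        data=data,
        sampling_rate=fs,
        time_ms=t,
        channel_labels=[f"C{i}" for i in range(data.shape[1])],
    )


class TestRemoveDC:
    def test_constant_trace_becomes_zero(self):
        ep = _epochs_from_array(np.full((1, 1, 100), 5.0))
        assert np.allclose(remove_dc(ep).data, 0.0)

    def test_zero_mean_sinusoid_unchanged(self):
        n = 200
        s = np.sin(2 * np.pi * np.arange(n) / 20)  # integer number of periods
        ep = _epochs_from_array(s.reshape(1, 1, -1))
        assert np.allclose(remove_dc(ep).data[0, 0], s, atol=1e-12)

    def test_offset_removed_per_trace(self):
        n = 200
        s = np.sin(2 * np.pi * np.arange(n) / 20)
        ep = _epochs_from_array(np.stack([[s + 3.0], [s - 1.5]]))
        out = remove_dc(ep)
        assert np.allclose(out.data[0, 0], s, atol=1e-12)
        assert np.allclose(out.data[1, 0], s, atol=1e-12)
        assert np.allclose(out.data.mean(axis=-1), 0.0, atol=1e-12)


class TestCwtSingle:
    def test_zero_trace_gives_zero_coefficients(self, small_bank):
        c = cwt_single(np.zeros(600), small_bank)
        assert c.shape == (len(small_bank.wavelets), 600)
        assert np.all(c == 0)

    def test_linearity(self, small_bank, rng):
        s = rng.standard_normal(600)
        assert np.allclose(
            cwt_single(2 * s, small_bank), 2 * cwt_single(s, small_bank), atol=1e-12
        )

    def test_too_short_trace_names_offending_frequency(self, small_bank):
        with pytest.raises(SignalTooShortError, match="10"):
            cwt_single(np.zeros(50), small_bank)

    def test_unit_sinusoid_flat_across_time_and_frequency(self, small_bank):
        """Amplitude normalization: interior modulus ~1 at each bank frequency."""
        fs = small_bank.spec.sampling_rate
        t = np.arange(1000) / fs
        h = small_bank.max_half_length
        peaks = []
        for i, f in enumerate(small_bank.spec.frequencies):
            c = cwt_single(np.cos(2 * np.pi * f * t), small_bank)
            interior = np.abs(c[i])[h:-h]
            assert interior.std() / interior.mean() < 1e-3  # flat over time
            peaks.append(interior.max())
        peaks = np.array(peaks)
        assert np.all(np.abs(peaks - 1.0) < 0.01)  # ~1 uV, flat over frequency

    def test_fft_convolution_matches_direct_convolution(self, rng):
        """Independent time-domain oracle: direct np.convolve per frequency."""
        bank = build_bank_range(20, 60, 20, 7, 200.0)
        gains = [2.0 / np.sum(np.abs(w)) for w in bank.wavelets]
        h = bank.max_half_length
        for _ in range(10):
            s = rng.standard_normal(500)
            fast = cwt_single(s, bank)
            for i, (w, g) in enumerate(zip(bank.wavelets, gains)):
                direct = g * np.convolve(s, w, mode="same")
                num = np.abs(fast[i, h:-h] - direct[h:-h]).max()
                assert num / np.abs(direct[h:-h]).max() <= 1e-8


class TestAveraging:
    def test_single_trial_subset_equals_that_trial(self, tiny_epochs, small_bank):
        full = transform_total_induced(tiny_epochs, small_bank, trial_subset=[2])
        one = EpochedData(
            data=tiny_epochs.data[2:3],
            sampling_rate=tiny_epochs.sampling_rate,
            time_ms=tiny_epochs.time_ms,
            channel_labels=tiny_epochs.channel_labels,
        )
        alone = transform_total_induced(one, small_bank)
        assert np.allclose(full.values, alone.values, atol=1e-14)
        assert full.n_trials_averaged == 1

    def test_identical_trials_average_to_single_trial(self, small_bank):
        rng = np.random.default_rng(0)
        trial = rng.standard_normal((1, 2, 500))
        ep = _epochs_from_array(np.repeat(trial, 4, axis=0))
        avg = transform_total_induced(ep, small_bank)
        single = transform_total_induced(
            _epochs_from_array(trial), small_bank
        )
        assert np.allclose(avg.values, single.values, atol=1e-12)

    def test_identical_trials_evoked_equals_induced(self, small_bank):
        rng = np.random.default_rng(3)
        trial = rng.standard_normal((1, 2, 500))
        ep = _epochs_from_array(np.repeat(trial, 6, axis=0))
        ind = transform_total_induced(ep, small_bank)
        evo = transform_evoked(ep, small_bank)
        assert np.max(np.abs(ind.values - evo.values)) <= 1e-12

    def test_single_trial_evoked_equals_induced(self, small_bank, rng):
        ep = _epochs_from_array(rng.standard_normal((1, 2, 500)))
        ind = transform_total_induced(ep, small_bank)
        evo = transform_evoked(ep, small_bank)
        assert np.allclose(ind.values, evo.values, atol=1e-12)

    def test_phase_jitter_attenuates_evoked_not_induced(self):
        """Non-phase-locked activity averages out of the ERP (~1/sqrt N)."""
        spec = SyntheticSpec(
            n_trials=100,
            n_channels=1,
            sampling_rate=250.0,
            epoch_window_ms=(-400.0, 1000.0),
            bursts=(BurstSpec(20.0, 300.0, 200.0, 1.0, phase_policy="jittered"),),
            noise_sd=0.0,
            seed=7,
        )
        ep = generate(spec)
        bank = build_bank_range(10, 30, 1, 7, 250.0)
        ind = transform_total_induced(ep, bank)
        evo = transform_evoked(ep, bank)
        fi = int(np.argmin(np.abs(bank.frequencies - 20)))
        ti = int(np.argmin(np.abs(ep.time_ms - 300)))
        assert evo.values[0, fi, ti] <= 0.3 * ind.values[0, fi, ti]

    def test_measure_power_is_amplitude_squared(self, tiny_epochs, small_bank):
        # holds exactly for a single trial (same complex coefficients)
        amp = transform_total_induced(tiny_epochs, small_bank, "amplitude", [0])
        pwr = transform_total_induced(tiny_epochs, small_bank, "power", [0])
        assert np.allclose(pwr.values, amp.values**2, rtol=1e-10, atol=1e-14)

    def test_complex_measure_retains_phase(self, tiny_epochs, small_bank):
        cplx = transform_total_induced(tiny_epochs, small_bank, "complex", [0])
        amp = transform_total_induced(tiny_epochs, small_bank, "amplitude", [0])
        assert np.iscomplexobj(cplx.values)
        assert np.allclose(np.abs(cplx.values), amp.values, atol=1e-12)

    def test_sem_matches_direct_formula(self, tiny_epochs, small_bank):
        res = transform_total_induced(tiny_epochs, small_bank, compute_sem=True)
        per_trial = np.stack(
            [
                np.abs(
                    np.stack(
                        [
                            cwt_single(
                                tiny_epochs.data[t, c]
                                - tiny_epochs.data[t, c].mean(),
                                small_bank,
                            )
                            for c in range(tiny_epochs.n_channels)
                        ]
                    )
                )
                for t in range(tiny_epochs.n_trials)
            ]
        )
        sem = per_trial.std(axis=0, ddof=1) / np.sqrt(tiny_epochs.n_trials)
        assert np.allclose(res.sem, sem, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("subset", [[], [99]])
    def test_bad_trial_subset_rejected(self, tiny_epochs, small_bank, subset):
        with pytest.raises(InvalidParameterError):
            transform_total_induced(tiny_epochs, small_bank, trial_subset=subset)

    def test_bad_measure_rejected(self, tiny_epochs, small_bank):
        with pytest.raises(InvalidParameterError):
            transform_total_induced(tiny_epochs, small_bank, measure="phase")
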