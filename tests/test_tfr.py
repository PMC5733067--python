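"""Analytic signals and source-space ERSP / ITC."""

import numpy as np
import pytest

from sourcetf.containers import SensorEpochs
from sourcetf.inverse import build_inverse
from sourcetf.tfr import (
    BandWindow,
    SourceTFTimecourse,
    analytic_epochs,
    default_band_windows,
    source_ersp,
    source_itc,
    window_average,
)

from oracles import naive_source_ersp, naive_source_itc


def _sine_epochs(freq=10.0, amp=4.0, srate=256.0, n_trials=3, n_ch=2, phases=None):
    if phases is not None:
        n_trials = len(phases)
    n_samp = int(4 * srate)
    t0 = int(srate)
    t = (np.arange(n_samp) - t0) / srate
    data = np.zeros((n_ch, n_samp, n_trials))
    rng = np.random.default_rng(0)
    for k in range(n_trials):
        ph = phases[k] if phases is not None else rng.uniform(0, 2 * np.pi)
        for c in range(n_ch):
            data[c, :, k] = amp * np.cos(2 * np.pi * freq * t + ph)
    return SensorEpochs(
        data=data,
        srate=srate,
        t0_index=t0,
        channel_names=[f"c{i}" for i in range(n_ch)],
    )


class TestAnalyticEpochs:
    def test_modulus_recovers_sinusoid_amplitude(self):
        ep = _sine_epochs(amp=4.0)
        ana = analytic_epochs(ep, (8.0, 12.0))
        core = ana.data[:, 192:-192, :]  # 0.75 s away from the edges
        np.testing.assert_allclose(np.abs(core), 4.0, rtol=0.02)

    def test_modulus_invariant_to_phase_shift(self):
        a = analytic_epochs(_sine_epochs(phases=[0.0]), (8.0, 12.0))
        b = analytic_epochs(_sine_epochs(phases=[1.3]), (8.0, 12.0))
        core = slice(192, -192)  # away from the reflection-padded edges
        np.testing.assert_allclose(
            np.abs(a.data[:, core, 0]), np.abs(b.data[:, core, 0]), rtol=0.02
        )

    def test_phase_derivative_matches_frequency(self):
        ep = _sine_epochs(freq=10.0)
        ana = analytic_epochs(ep, (8.0, 12.0))
        phase = np.unwrap(np.angle(ana.data[0, :, 0]))
        inst_freq = np.diff(phase[128:-128]) / (2 * np.pi) * ep.srate
        np.testing.assert_allclose(inst_freq, 10.0, rtol=0.01)

    def test_band_too_narrow_rejected(self):
        ep = _sine_epochs()
        with pytest.raises(ValueError, match="too narrow"):
            analytic_epochs(ep, (10.0, 10.3))

    def test_band_outside_nyquist_rejected(self):
        ep = _sine_epochs(srate=256.0)
        with pytest.raises(ValueError, match="band"):
            analytic_epochs(ep, (100.0, 140.0))


class TestWindowAverage:
    def _tc(self, values, srate=512.0, t0=512):
        return SourceTFTimecourse(
            values=values, srate=srate, t0_index=t0, measure="ERSP", n_trials=1,
            band=(9.0, 13.0),
        )

    def test_constant_timecourse_returns_constant(self):
        tc = self._tc(np.full((3, 2048), 2.5))
        np.testing.assert_allclose(window_average(tc, (0.530, 0.750)), 2.5)

    def test_alpha_window_sample_count_half_open(self):
        # values = sample index, so the mean identifies exactly which samples
        vals = np.tile(np.arange(2048.0), (1, 1))
        tc = self._tc(vals)
        got = window_average(tc, (0.530, 0.750))[0]
        lo = 512 + int(np.ceil(0.530 * 512))  # first sample with t >= 0.530
        samples = np.arange(lo, 512 + int(np.ceil(0.750 * 512)))
        assert len(samples) == 112  # floor((0.750-0.530)*512)
        assert got == pytest.approx(samples.mean())

    def test_empty_window_rejected(self):
        tc = self._tc(np.zeros((2, 2048)))
        with pytest.raises(ValueError, match="no samples"):
            window_average(tc, (10.0, 10.1))

    def test_default_table_has_six_cells(self):
        bands = default_band_windows()
        assert len(bands) == 6
        assert sum(b.measure == "ERSP" for b in bands) == 3
        assert sum(b.measure == "ITC" for b in bands) == 3

    def test_malformed_band_rejected(self):
        with pytest.raises(ValueError):
            BandWindow("bad", 13.0, 9.0, 0.0, 100.0, "ERSP")


class TestSourceErsp:
    def test_stationary_input_gives_near_zero_ersp(self, inverse_op):
        rng = np.random.default_rng(1)
        n_ch = inverse_op.n_channels
        data = rng.normal(0, 5.0, size=(n_ch, 512, 40))
        ep = SensorEpochs(
            data=data, srate=128.0, t0_index=128,
            channel_names=[f"E{i + 1:03d}" for i in range(n_ch)],
        )
        ana = analytic_epochs(ep, (8.0, 12.0))
        tc = source_ersp(ana, inverse_op, baseline_window=(-0.85, -0.05))
        post = window_average(tc, (0.5, 1.5))
        base = window_average(tc, (-0.85, -0.05))
        # additive baseline removes stationary power: the residual is small
        # relative to the per-voxel mean power it was subtracted from
        from sourcetf.inverse import apply_inverse, source_power_map

        mean_power = source_power_map(
            inverse_op, apply_inverse(inverse_op, ana.data)
        ).mean(axis=(1, 2))
        assert np.abs(base).max() < 1e-10 * mean_power.max()
        assert np.all(np.abs(post) < 0.3 * mean_power)

    def test_no_trials_rejected(self, inverse_op):
        ep = _sine_epochs(n_ch=inverse_op.n_channels)
        ana = analytic_epochs(ep, (8.0, 12.0))
        ana.data = ana.data[:, :, :0]
        with pytest.raises(ValueError, match="trials"):
            source_ersp(ana, inverse_op)


class TestSourceItc:
    def test_duplicated_trials_give_itc_one(self, inverse_op):
        ep = _sine_epochs(n_ch=inverse_op.n_channels, n_trials=1)
        ep.data = np.repeat(ep.data, 8, axis=2)  # identical trials
        ana = analytic_epochs(ep, (8.0, 12.0))
        tc = source_itc(ana, inverse_op)
        valid = ~np.isnan(tc.values)
        np.testing.assert_allclose(tc.values[valid], 1.0, atol=1e-8)

    def test_itc_bounded_in_unit_interval(self, inverse_op):
        rng = np.random.default_rng(2)
        n_ch = inverse_op.n_channels
        data = rng.normal(size=(n_ch, 256, 12))
        ep = SensorEpochs(
            data=data, srate=128.0, t0_index=64,
            channel_names=[f"E{i + 1:03d}" for i in range(n_ch)],
        )
        tc = source_itc(analytic_epochs(ep, (8.0, 12.0)), inverse_op)
        valid = ~np.isnan(tc.values)
        assert np.all(tc.values[valid] >= 0) and np.all(tc.values[valid] <= 1 + 1e-12)

    def test_uniform_phases_give_chance_level(self, inverse_op):
        n = 300
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 2 * np.pi, n)
        ep = _sine_epochs(n_ch=inverse_op.n_channels, n_trials=n, phases=phases)
        tc = source_itc(analytic_epochs(ep, (8.0, 12.0)), inverse_op)
        chance = np.sqrt(np.pi) / (2 * np.sqrt(n))
        se = np.sqrt((4 - np.pi) / (4 * n))
        mid = tc.values[:, 200:-200]
        assert np.nanmedian(mid) == pytest.approx(chance, abs=3 * se)

    def test_all_zero_voxels_flagged_not_zero(self, inverse_op):
        ep = _sine_epochs(n_ch=inverse_op.n_channels, n_trials=2)
        ep.data[:] = 0.0
        tc = source_itc(analytic_epochs(ep, (8.0, 12.0)), inverse_op)
        assert np.isnan(tc.values).all()
        assert tc.undefined_mask.all()

    def test_orientation_rules_agree_on_strong_source(self, tiny_leadfield):
        op = build_inverse(tiny_leadfield, snr=3.0)
        ep = _sine_epochs(n_ch=8, n_trials=20)
        ana = analytic_epochs(ep, (8.0, 12.0))
        a = source_itc(ana, op, orientation_rule="dominant-svd")
        b = source_itc(ana, op, orientation_rule="max-power-component")
        core = slice(128, -128)
        np.testing.assert_allclose(
            a.values[:, core], b.values[:, core], atol=0.05
        )


class TestOracleEquivalence:
    """Vectorized ERSP/ITC vs the literal per-trial per-voxel transcription."""

    @pytest.fixture(scope="class")
    def instance(self, tiny_leadfield):
        op = build_inverse(tiny_leadfield, snr=3.0)
        rng = np.random.default_rng(7)
        data = rng.normal(0, 3.0, size=(8, 128, 10))  # 10 trials
        ep = SensorEpochs(
            data=data, srate=64.0, t0_index=64,
            channel_names=list(tiny_leadfield.montage.channel_names),
        )
        ana = analytic_epochs(ep, (8.0, 12.0))
        return op, ana

    def test_ersp_matches_literal_loop(self, instance):
        op, ana = instance
        tc = source_ersp(ana, op, baseline_window=(-0.9, -0.1))
        naive = naive_source_ersp(
            ana.data, op.transfer, op.s_blocks, tc.times, (-0.9, -0.1)
        )
        np.testing.assert_allclose(tc.values, naive, rtol=1e-10, atol=1e-10)

    def test_itc_matches_literal_loop(self, instance):
        op, ana = instance
        from sourcetf.tfr import _orientations

        tc = source_itc(ana, op)
        u = _orientations(ana, op, "dominant-svd", None, 16)
        naive = naive_source_itc(ana.data, op.transfer, u)
        np.testing.assert_allclose(tc.values, naive, rtol=1e-10, atol=1e-10)
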