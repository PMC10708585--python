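import numpy as np
import pytest

from lampspec import (
    ChannelBand,
    IlluminationMatrix,
    NoiseModel,
    QECurve,
    ReflectanceSpectrum,
    TemperaturePerturbation,
    assemble_system,
    build_illumination_matrix,
    channel_sensitivity,
    make_grid,
    perturb_illumination,
    simulate_signals,
)
from lampspec.detector import ChannelSensitivity
from lampspec.forward_model import read_signals_csv, write_signals_csv


def tiny_system():
    """2 temperatures x 2 wavelengths, 1 channel, hand-set values."""
    grid = make_grid(500, 600, 100)
    illum = IlluminationMatrix(
        grid=grid,
        temperatures=np.array([2500.0, 3000.0]),
        values=np.array([[1.0, 2.0], [3.0, 4.0]]),
        transmissivity=np.ones(2),
    )
    sens = ChannelSensitivity(
        band=ChannelBand(500, 600, closed_high=True), grid=grid, values=np.ones(2)
    )
    return grid, assemble_system(illum, [sens])


class TestAssembleSystem:
    def test_unit_sensitivity_reproduces_illumination(self, illumination, default_grid):
        ones = ChannelSensitivity(
            band=ChannelBand(400, 700, closed_high=True),
            grid=default_grid,
            values=np.ones(default_grid.n),
        )
        system = assemble_system(illumination, [ones])
        np.testing.assert_array_equal(system.values, illumination.values)

    def test_hand_example(self):
        _, system = tiny_system()
        np.testing.assert_array_equal(system.values, [[1.0, 2.0], [3.0, 4.0]])

    def test_channel_major_block_layout(self, illumination, default_grid, qe):
        bands = [ChannelBand(400, 500), ChannelBand(500, 700, closed_high=True)]
        sens = [channel_sensitivity(qe, b, default_grid) for b in bands]
        system = assemble_system(illumination, sens)
        m = illumination.m
        assert system.values.shape == (2 * m, default_grid.n)
        np.testing.assert_allclose(
            system.values[:m], illumination.values * sens[0].values[None, :]
        )
        np.testing.assert_allclose(
            system.values[m:], illumination.values * sens[1].values[None, :]
        )

    def test_wavelength_invisible_to_all_channels_gives_zero_column(
        self, illumination, default_grid, qe
    ):
        sens = [channel_sensitivity(qe, ChannelBand(400, 500), default_grid)]
        system = assemble_system(illumination, sens)
        outside = default_grid.points >= 500
        assert np.all(system.values[:, outside] == 0)

    def test_grid_mismatch_rejected(self, illumination, qe):
        other = make_grid(400, 700, 20)
        sens = channel_sensitivity(qe, ChannelBand(400, 700, closed_high=True), other)
        with pytest.raises(ValueError, match="grid"):
            assemble_system(illumination, [sens])


class TestSimulateSignals:
    def test_noiseless_hand_example(self):
        grid, system = tiny_system()
        r = ReflectanceSpectrum(grid=grid, values=np.array([1.0, 0.5]))
        signals = simulate_signals(system, r)
        np.testing.assert_allclose(signals.values, [2.0, 5.0])

    def test_zero_reflectance_gives_zero_signals_per_signal_noise(self):
        grid, system = tiny_system()
        r = ReflectanceSpectrum(grid=grid, values=np.zeros(2))
        signals = simulate_signals(system, r, NoiseModel(snr=100, seed=0))
        np.testing.assert_array_equal(signals.values, 0.0)

    def test_noiseless_linearity(self, default_system, default_grid, rng):
        r1 = rng.uniform(0, 0.5, default_grid.n)
        r2 = rng.uniform(0, 0.5, default_grid.n)
        s1 = simulate_signals(default_system, ReflectanceSpectrum(default_grid, r1)).values
        s2 = simulate_signals(default_system, ReflectanceSpectrum(default_grid, r2)).values
        s12 = simulate_signals(default_system, ReflectanceSpectrum(default_grid, r1 + r2)).values
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-12)

    @pytest.mark.parametrize("c", [0.2, 1.0])
    def test_flat_spectrum_conservation(self, default_system, default_grid, c):
        flat = ReflectanceSpectrum(default_grid, np.full(default_grid.n, c))
        signals = simulate_signals(default_system, flat)
        np.testing.assert_allclose(signals.values, c * default_system.values.sum(axis=1), rtol=1e-12)

    def test_seeded_reproducibility(self, default_system, panel):
        a = simulate_signals(default_system, panel[0], NoiseModel(snr=100, seed=7))
        b = simulate_signals(default_system, panel[0], NoiseModel(snr=100, seed=7))
        np.testing.assert_array_equal(a.values, b.values)

    def test_empirical_snr_per_signal(self, default_system, panel):
        """Sample sd over 1e4 noisy replicates matches signal/snr within 3 SE."""
        n_rep, snr = 10_000, 100.0
        clean = default_system.values @ panel[0].values
        rng = np.random.default_rng(42)
        noisy = clean[None, :] + rng.normal(0, 1, (n_rep, len(clean))) * clean[None, :] / snr
        sample_sd = noisy.std(axis=0, ddof=1)
        se = (clean / snr) / np.sqrt(2 * (n_rep - 1))
        assert np.all(np.abs(sample_sd - clean / snr) < 3.5 * se + 1e-15)
        # and the package path reproduces the per-signal draw distribution
        sig = simulate_signals(default_system, panel[0], NoiseModel(snr=snr, seed=3))
        assert np.all(np.abs(sig.values - clean) < 6 * clean / snr)

    def test_global_mean_convention(self, default_system, panel):
        noise = NoiseModel(snr=100, convention="global-mean", seed=5)
        clean = default_system.values @ panel[0].values
        n_rep = 5_000
        rng = np.random.default_rng(11)
        sd = clean.mean() / 100
        draws = clean[None, :] + rng.normal(0, sd, (n_rep, len(clean)))
        assert (draws - clean[None, :]).std(ddof=1) == pytest.approx(sd, rel=0.05)
        sig = simulate_signals(default_system, panel[0], noise)
        assert np.all(np.isfinite(sig.values))

    def test_invalid_noise_model(self):
        with pytest.raises(ValueError):
            NoiseModel(snr=0)
        with pytest.raises(ValueError):
            NoiseModel(snr=100, convention="bogus")


class TestPerturbIllumination:
    def test_sd_zero_is_identity(self, illumination):
        out = perturb_illumination(illumination, TemperaturePerturbation(sd=0.0, seed=1))
        assert out is illumination

    def test_fixed_seed_is_bit_identical(self, illumination):
        a = perturb_illumination(illumination, TemperaturePerturbation(sd=10.0, seed=9))
        b = perturb_illumination(illumination, TemperaturePerturbation(sd=10.0, seed=9))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.temperatures, b.temperatures)

    def test_rows_rebuilt_from_perturbed_temperatures(self, illumination, default_grid):
        pert = perturb_illumination(illumination, TemperaturePerturbation(sd=10.0, seed=2))
        rebuilt = build_illumination_matrix(default_grid, pert.temperatures)
        np.testing.assert_allclose(pert.values, rebuilt.values, rtol=1e-14)
        # the nominal matrix is untouched and the perturbed rows differ
        assert not np.array_equal(pert.temperatures, illumination.temperatures)
        assert np.all(pert.values != illumination.values)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            TemperaturePerturbation(sd=-1.0)


class TestSignalsCsv:
    def test_round_trip(self, default_system, panel, tmp_path):
        signals = simulate_signals(default_system, panel[3], NoiseModel(snr=100, seed=0))
        path = tmp_path / "signals.csv"
        write_signals_csv(signals, path)
        back = read_signals_csv(path)
        assert back.p == signals.p
        np.testing.assert_allclose(back.temperatures, signals.temperatures)
        np.testing.assert_allclose(back.values, signals.values, rtol=1e-12)
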