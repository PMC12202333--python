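import numpy as np
import pytest
import pywt

from eegfatigue.data import CHANNELS, Epoch
from eegfatigue.entropy import (EntropyConfig, approximate_entropy,
                                build_feature_table, coarse_grain,
                                entropy_feature_names, extract_features,
                                fuzzy_entropy, kolmogorov_entropy,
                                kolmogorov_r0, permutation_entropy,
                                relative_band_power, sample_entropy,
                                spectral_entropy, symbolic_transfer_entropy,
                                wavelet_log_energy,
                                wavelet_packet_energy_entropy)
from oracles import (naive_approximate_entropy, naive_fuzzy_entropy,
                     naive_permutation_entropy, naive_sample_entropy,
                     naive_symbolic_transfer_entropy)

FS = 200.0


def _sine(freq, n=200, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestOracleEquivalence:
    """Vectorized estimators against naive double-loop references."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_approximate_entropy_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert approximate_entropy(x) == pytest.approx(
            naive_approximate_entropy(x), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_sample_entropy_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert sample_entropy(x) == pytest.approx(
            naive_sample_entropy(x), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_fuzzy_entropy_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert fuzzy_entropy(x) == pytest.approx(
            naive_fuzzy_entropy(x), abs=1e-10)

    def test_permutation_entropy_matches_pattern_histogram(self):
        x = np.random.default_rng(2).standard_normal(500)
        assert permutation_entropy(x) == pytest.approx(
            naive_permutation_entropy(x), abs=1e-12)

    def test_transfer_entropy_matches_joint_histogram(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        assert symbolic_transfer_entropy(x, y) == pytest.approx(
            naive_symbolic_transfer_entropy(x, y), abs=1e-12)

    def test_transfer_entropy_longer_history(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(300)
        y = np.roll(x, 1) + 0.1 * rng.standard_normal(300)
        assert symbolic_transfer_entropy(x, y, k=2) == pytest.approx(
            naive_symbolic_transfer_entropy(x, y, k=2), abs=1e-12)


class TestRegularityLimits:
    @pytest.mark.parametrize("fn", [approximate_entropy, sample_entropy,
                                    fuzzy_entropy])
    def test_constant_sequence_has_zero_entropy(self, fn):
        assert fn(np.full(100, 2.5)) == 0.0

    @pytest.mark.parametrize("fn", [approximate_entropy, sample_entropy,
                                    fuzzy_entropy])
    def test_noise_less_regular_than_sine(self, fn, rng):
        noise = rng.standard_normal(300)
        assert fn(noise) > fn(_sine(5.0, n=300))

    def test_fuzzy_entropy_is_continuous_in_input(self, rng):
        x = rng.standard_normal(200)
        eps = 1e-6 * rng.standard_normal(200)
        assert abs(fuzzy_entropy(x) - fuzzy_entropy(x + eps)) < 1e-3

    def test_estimators_reject_too_short_input(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0))


class TestKolmogorov:
    def test_r0_is_mean_absolute_deviation(self):
        assert kolmogorov_r0(np.array([1.0, 2.0, 3.0, 4.0])) == 1.0

    def test_periodic_signal_near_zero(self):
        x = _sine(7.0, n=2000)
        assert kolmogorov_entropy(x) <= 0.05

    def test_noise_exceeds_sine(self, rng):
        assert kolmogorov_entropy(rng.standard_normal(400)) > \
            kolmogorov_entropy(_sine(7.0, n=400))

    def test_constant_signal_is_zero(self):
        assert kolmogorov_entropy(np.full(100, 1.0)) == 0.0


class TestPermutation:
    def test_monotone_sequence_has_zero_entropy(self):
        assert permutation_entropy(np.arange(200.0)) == 0.0

    def test_iid_noise_approaches_one(self):
        x = np.random.default_rng(5).uniform(size=10_000)
        assert permutation_entropy(x) > 0.97

    def test_coarse_graining_is_window_means(self):
        np.testing.assert_allclose(
            coarse_grain(np.array([1.0, 3.0, 2.0, 4.0, 9.0]), 2),
            [2.0, 3.0])

    def test_too_short_input_reports_requirement(self):
        with pytest.raises(ValueError, match="at least"):
            permutation_entropy(np.arange(10.0))


class TestSpectral:
    def test_single_tone_concentrated(self):
        assert spectral_entropy(_sine(10.0, n=1000), FS) <= 0.2

    def test_white_noise_flat(self):
        x = np.random.default_rng(6).standard_normal(1000)
        assert spectral_entropy(x, FS) >= 0.9

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            v = spectral_entropy(rng.standard_normal(200), FS)
            assert 0.0 <= v <= 1.0

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros(200), FS)


class TestTransferEntropy:
    def test_shifted_copy_gives_directed_flow(self, rng):
        x = rng.standard_normal(2000)
        y = np.roll(x, 1)          # x leads y by one sample
        forward = symbolic_transfer_entropy(x, y)
        backward = symbolic_transfer_entropy(y, x)
        assert forward > 10 * backward
        assert forward > 0.5       # near-deterministic symbol copy

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert symbolic_transfer_entropy(x, y) < 0.01

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            symbolic_transfer_entropy(np.arange(10.0), np.arange(9.0))


class TestWaveletEntropies:
    def test_wle_has_levels_plus_one_components(self, rng):
        assert wavelet_log_energy(rng.standard_normal(200)).shape == (3,)

    def test_wle_scaling_identity(self, rng):
        x = rng.standard_normal(200)
        coeffs = pywt.wavedec(x, "db3", level=2)
        base = wavelet_log_energy(x)
        scaled = wavelet_log_energy(10.0 * x)
        expected = base + np.array([len(c) for c in coeffs]) * np.log(100.0)
        np.testing.assert_allclose(scaled, expected, rtol=1e-9)

    def test_wle_matches_per_leaf_coefficient_sums(self, rng):
        x = rng.standard_normal(200)
        coeffs = pywt.wavedec(x, "db3", level=2)
        expected = [np.sum(np.log(c ** 2)) for c in coeffs]
        np.testing.assert_allclose(wavelet_log_energy(x), expected, rtol=1e-9)

    def test_wpe_single_leaf_concentration_near_zero(self):
        # a pure deepest-approximation signal: energy in one packet
        wp = pywt.WaveletPacket(data=np.zeros(256), wavelet="db3", maxlevel=2)
        wp["aa"] = np.ones(len(wp["aa"].data))
        x = wp.reconstruct(update=False)
        assert wavelet_packet_energy_entropy(x) < 0.2

    def test_wpe_uniform_four_leaves_is_two_bits(self):
        wp = pywt.WaveletPacket(data=np.zeros(256), wavelet="db3", maxlevel=2)
        rng = np.random.default_rng(8)
        for node in wp.get_level(2, order="natural"):
            data = rng.standard_normal(len(node.data))
            wp[node.path] = data / np.linalg.norm(data)
        x = wp.reconstruct(update=False)
        assert wavelet_packet_energy_entropy(x) == pytest.approx(2.0, abs=0.05)

    def test_wpe_matches_leaf_energy_oracle(self, rng):
        x = rng.standard_normal(300)
        wp = pywt.WaveletPacket(data=x, wavelet="db3", maxlevel=2)
        e = np.array([np.sum(n.data ** 2)
                      for n in wp.get_level(2, order="natural")])
        p = e / e.sum()
        expected = -(p * np.log2(p)).sum()
        assert wavelet_packet_energy_entropy(x) == pytest.approx(expected,
                                                                 abs=1e-9)


class TestRelativeBandPower:
    def test_theta_tone_concentrates_in_theta(self):
        rbp = relative_band_power(_sine(6.0, n=1000), FS)
        assert rbp[1] >= 0.9

    def test_fractions_bounded(self, rng):
        rbp = relative_band_power(rng.standard_normal(400), FS)
        assert np.all(rbp >= 0.0) and np.all(rbp <= 1.0)
        assert rbp.sum() <= 1.0 + 1e-12

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            relative_band_power(np.zeros(100), FS)


class TestFeatureAssembly:
    def _epoch(self, rng, fs=200):
        return Epoch(1, "normal", fs, rng.standard_normal((2, fs)), 0)

    def test_default_extraction_yields_22_named_features(self, rng):
        values = extract_features(self._epoch(rng))
        assert list(values) == entropy_feature_names()
        assert len(values) == 22
        assert all(np.isfinite(v) for v in values.values())

    def test_channel_swap_swaps_suffixes_not_values(self, rng):
        epoch = self._epoch(rng)
        swapped = Epoch(1, "normal", epoch.fs, epoch.samples[::-1].copy(), 0)
        a = extract_features(epoch)
        b = extract_features(swapped)
        for name in ("AE", "FE", "KE", "PE", "SE", "SPE", "WPE", "STE"):
            assert a[f"{name}_FP1"] == b[f"{name}_FP2"]
            assert a[f"{name}_FP2"] == b[f"{name}_FP1"]

    def test_rbp_columns_appended_on_request(self, rng):
        values = extract_features(self._epoch(rng), include_rbp=True)
        assert len(values) == 22 + 8
        assert "RBP_theta_FP2" in values

    def test_feature_table_shape_and_metadata(self, feature_table):
        # 4 subjects x 2 states x 10 one-second epochs
        assert len(feature_table) == 80
        entropy_cols = [c for c in feature_table.feature_names
                        if not c.startswith("RBP_")]
        assert len(entropy_cols) == 22
        assert set(feature_table.df["label"]) == {0, 1}
        assert feature_table.X.shape == (80, 30)

    def test_all_features_finite_on_pipeline_epochs(self, feature_table):
        assert np.all(np.isfinite(feature_table.X))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EntropyConfig(m_aef=0)
        with pytest.raises(ValueError):
            EntropyConfig(r_factor=-1.0)


class TestDiscrimination:
    """Fatigue direction of the feature means on the synthetic cohort."""

    @pytest.mark.parametrize("feature,direction", [
        ("SE_FP1", "lower"), ("FE_FP1", "lower"), ("SPE_FP1", "lower"),
        ("SE_FP2", "lower"), ("FE_FP2", "lower"), ("SPE_FP2", "lower"),
        ("RBP_theta_FP1", "higher"), ("RBP_theta_FP2", "higher"),
    ])
    def test_fatigue_shifts_feature_mean(self, feature_table, feature,
                                         direction):
        means = feature_table.df.groupby("state")[feature].mean()
        if direction == "lower":
            assert means["fatigue"] < means["normal"]
        else:
            assert means["fatigue"] > means["normal"]
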