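import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegpref import (BandSet, aw_index, build_feature_table, choice_index,
                     default_bands, differential_entropy, effort_index, hjorth,
                     read_feature_table, relative_band_power, valence,
                     welch_psd, write_feature_table)
from eegpref.errors import DomainError, ParameterError, UndefinedFeatureError
from eegpref.features import PSDResult, band_integral

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestWelchPSD:
    def test_white_noise_satisfies_parseval(self, rng):
        x = rng.standard_normal(256 * 30)
        psd = welch_psd(x, 256.0)
        total = np.trapezoid(psd.power, psd.freqs)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_tone_peak_location(self):
        t = np.arange(2048) / 256.0
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), 256.0)
        peak = psd.freqs[np.argmax(psd.power)]
        df = psd.freqs[1] - psd.freqs[0]
        assert abs(peak - 10.0) <= df

    def test_zero_signal_zero_density(self):
        psd = welch_psd(np.zeros(1000), 256.0)
        np.testing.assert_array_equal(psd.power, 0.0)

    def test_window_shrinks_to_short_segment(self):
        x = np.random.default_rng(0).standard_normal(100)
        psd = welch_psd(x, 256.0, win_sec=1.0)  # window 256 > 100 samples
        assert len(psd.freqs) == 100 // 2 + 1


class TestRelativeBandPower:
    def test_rows_sum_to_one(self, rng):
        x = rng.standard_normal((5, 3, 512))
        shares = relative_band_power(welch_psd(x, 256.0), default_bands())
        np.testing.assert_allclose(shares.sum(axis=-1), 1.0, atol=1e-9)

    def test_alpha_tone_dominates_alpha_share(self):
        t = np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        shares = relative_band_power(welch_psd(x, 256.0), default_bands())
        assert shares[2] > 0.9  # alpha is the third band

    def test_flat_density_gives_bandwidth_shares(self):
        freqs = np.linspace(0.0, 40.0, 401)
        psd = PSDResult(freqs=freqs, power=np.ones((1, 401)))
        shares = relative_band_power(psd, default_bands())
        np.testing.assert_allclose(
            shares[0], np.array([3.5, 4.0, 5.0, 17.0]) / 29.5, atol=1e-9)

    def test_zero_power_is_undefined(self):
        psd = PSDResult(freqs=np.linspace(0, 128, 100), power=np.zeros((1, 100)))
        with pytest.raises(UndefinedFeatureError):
            relative_band_power(psd, default_bands())


class TestAsymmetryIndices:
    @pytest.mark.parametrize("fn,args,expected", [
        (aw_index, (3.0, 1.0), 0.5),
        (aw_index, (2.0, 2.0), 0.0),
        (aw_index, (1.0, 3.0), -0.5),
        (effort_index, (2.0, 2.0), 0.0),
        (effort_index, (6.0, 2.0), 0.5),
        (choice_index, (np.e ** 2, np.e), 1.0 / 3.0),
        (choice_index, (5.0, 5.0), 0.0),
        (valence, (8.0, 4.0, 6.0, 3.0), 0.0),
        (valence, (8.0, 4.0, 3.0, 3.0), 1.0),
    ])
    def test_known_values(self, fn, args, expected):
        assert fn(*args) == pytest.approx(expected)

    def test_nonpositive_power_is_domain_error(self):
        with pytest.raises(DomainError):
            effort_index(0.0, 1.0)
        with pytest.raises(DomainError):
            aw_index(-1.0, 2.0)
        with pytest.raises(DomainError):
            valence(1.0, 0.0, 1.0, 1.0)

    def test_choice_log_cancellation_is_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            choice_index(np.e, 1.0 / np.e)

    @settings(derandomize=True, max_examples=100)
    @given(a=positive, b=positive)
    def test_aw_bounded_and_antisymmetric(self, a, b):
        v = aw_index(a, b)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(-aw_index(b, a))

    @settings(derandomize=True, max_examples=100)
    @given(a=positive, b=positive)
    def test_choice_antisymmetric_under_swap(self, a, b):
        den = np.log(a) + np.log(b)
        if abs(den) < 1e-6:
            return
        assert choice_index(a, b) == pytest.approx(-choice_index(b, a))

    def test_valence_sign_flips_under_channel_swap(self):
        assert valence(8, 4, 3, 3) == -valence(3, 3, 8, 4)


class TestDifferentialEntropy:
    def test_unit_gaussian_closed_form(self, rng):
        x = rng.standard_normal(4096)
        x = (x - x.mean()) / x.std()
        assert differential_entropy(x, 256.0) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=0.01)

    def test_variance_scaling_adds_half_log(self, rng):
        x = rng.standard_normal(4096)
        assert differential_entropy(2 * x, 256.0) - differential_entropy(
            x, 256.0) == pytest.approx(np.log(2), abs=1e-9)

    def test_gaussian_variance_two(self, rng):
        x = rng.normal(0, np.sqrt(2), 4096)
        assert differential_entropy(x, 256.0) == pytest.approx(
            0.5 * np.log(4 * np.pi * np.e), abs=0.05)

    def test_monotone_in_band_variance(self, rng):
        x = rng.standard_normal(2048)
        lo = differential_entropy(x, 256.0, band=(8.0, 13.0))
        hi = differential_entropy(3 * x, 256.0, band=(8.0, 13.0))
        assert hi > lo

    def test_base_two_conversion(self, rng):
        x = rng.standard_normal(1024)
        nats = differential_entropy(x, 256.0)
        bits = differential_entropy(x, 256.0, base=2)
        assert bits == pytest.approx(nats / np.log(2))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            differential_entropy(np.ones(128), 256.0)


class TestHjorth:
    def test_tone_mobility_and_complexity(self):
        t = np.arange(4 * 256) / 256.0
        act, mob, comp = hjorth(np.sin(2 * np.pi * 2 * t), 256.0)
        assert act == pytest.approx(0.5, rel=0.01)
        assert mob == pytest.approx(2 * np.pi * 2, rel=0.01)
        assert comp == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("freq", [1, 5, 10, 20, 30])
    def test_complexity_near_one_for_pure_tones(self, freq):
        t = np.arange(4 * 256) / 256.0
        _, _, comp = hjorth(np.sin(2 * np.pi * freq * t), 256.0)
        assert comp == pytest.approx(1.0, rel=0.02)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(1000)
        act, mob, comp = hjorth(x, 256.0)
        act3, mob3, comp3 = hjorth(3 * x, 256.0)
        assert act3 == pytest.approx(9 * act)
        assert mob3 == pytest.approx(mob)
        assert comp3 == pytest.approx(comp)

    def test_constant_signal_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            hjorth(np.full(100, 2.0), 256.0)


class TestBandSet:
    def test_default_band_edges(self):
        bands = default_bands()
        assert bands.names == ("delta", "theta", "alpha", "beta")
        assert bands.edges("delta") == (0.5, 4.0)
        assert bands.edges("beta") == (13.0, 30.0)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ParameterError):
            BandSet((("a", 1.0, 5.0), ("b", 4.0, 8.0)))

    def test_band_integral_matches_trapezoid_on_grid(self):
        freqs = np.linspace(0, 128, 257)
        power = np.ones(257)
        assert band_integral(PSDResult(freqs, power), 8.0, 13.0) == pytest.approx(5.0)


class TestBuildFeatureTable:
    def test_psd_table_has_channel_by_band_columns(self, small_segments):
        ft = build_feature_table(small_segments, "psd")
        assert ft.values.shape == (small_segments.n_segments, 88)
        assert ft.feature_names[0] == "psd:FP1:delta"
        assert np.isfinite(ft.values).all()

    def test_de_on_occipital_region(self, small_segments, montage):
        ft = build_feature_table(small_segments, "de",
                                 channels=montage.regions["occipital"])
        assert ft.values.shape[1] == 8  # 2 channels x 4 bands

    def test_hjorth_has_three_measures_per_cell(self, small_segments):
        ft = build_feature_table(small_segments, "hjorth", channels=["Cz"])
        assert ft.values.shape[1] == 12  # 3 measures x 4 bands
        assert "hjorth_mobility:Cz:alpha" in ft.feature_names

    def test_choice_16_channels_uses_8_pairs(self, small_segments, montage):
        pairs = [p for p in montage.lr_pairs if p != ("TP9", "TP10")]
        chans = [c for p in pairs for c in p]
        assert len(set(chans)) == 16
        ft = build_feature_table(small_segments, "asymmetry", channels=chans,
                                 indices=["choice"])
        assert ft.values.shape[1] == 32  # 8 pairs x 4 bands

    def test_asymmetry_defaults_include_all_indices(self, small_segments):
        ft = build_feature_table(small_segments, "asymmetry")
        fams = {n.split(":")[0] for n in ft.feature_names}
        assert fams == {"aw", "effort", "valence", "choice"}

    def test_unknown_family_and_empty_selection_rejected(self, small_segments):
        with pytest.raises(ParameterError):
            build_feature_table(small_segments, "wavelet")
        with pytest.raises(ParameterError):
            build_feature_table(small_segments, "psd", channels=[])

    def test_csv_round_trip(self, small_segments, tmp_path):
        ft = build_feature_table(small_segments, "psd", channels=["O1", "O2"])
        write_feature_table(ft, tmp_path / "ft.csv")
        back = read_feature_table(tmp_path / "ft.csv")
        np.testing.assert_allclose(back.values, ft.values, rtol=1e-12)
        assert back.feature_names == ft.feature_names
        np.testing.assert_array_equal(back.labels, ft.labels)
        assert back.meta == ft.meta
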