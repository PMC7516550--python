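import math

import numpy as np
import pytest

import ceemdboost as cb
from ceemdboost.features import (
    _change_quantiles,
    entropy_features,
    parse_feature_name,
)

import oracles

CFG = cb.EntropyConfig()

#: Eight-point series whose six order-3 ordinal patterns each occur once.
UNIFORM_PATTERN_SERIES = np.array([2.0, 7.0, 6.0, 1.0, 3.0, 4.0, 0.0, 5.0])


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        assert cb.permutation_entropy(np.arange(10.0)) == 0.0

    def test_uniform_patterns_reach_log_6(self):
        pe = cb.permutation_entropy(UNIFORM_PATTERN_SERIES)
        assert pe == pytest.approx(math.log(6), abs=1e-12)

    def test_seven_point_example_matches_oracle(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        expected = oracles.permutation_entropy_oracle(x, 3, 1)
        assert cb.permutation_entropy(x) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, short_series_battery):
        for x in short_series_battery[:5]:
            a = cb.permutation_entropy(x)
            b = cb.permutation_entropy(np.exp(2 * x) + 1)
            assert a == pytest.approx(b, abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            cb.permutation_entropy(np.array([1.0, 2.0]))


class TestShannonEntropy:
    def test_constant_zero(self):
        assert cb.shannon_entropy(np.full(50, 7.0)) == 0.0

    def test_two_values_one_bit(self):
        x = np.array([1.0] * 25 + [2.0] * 25)
        assert cb.shannon_entropy(x) == pytest.approx(1.0, abs=1e-12)

    def test_four_values_two_bits(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0], 10)
        assert cb.shannon_entropy(x, n_bins=4) == pytest.approx(2.0, abs=1e-12)


class TestSpectralEntropy:
    def test_single_tone_near_zero(self):
        # integer cycle count → all power in one spectral line
        n, rate = 1024, 256.0
        x = np.sin(2 * np.pi * 32 * np.arange(n) / rate)
        assert cb.spectral_entropy(x, rate) < 0.05

    def test_two_equal_tones_log2(self):
        n, rate = 2048, 256.0
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 16 * t) + np.sin(2 * np.pi * 96 * t)
        assert cb.spectral_entropy(x, rate) == pytest.approx(math.log(2), abs=0.05)

    def test_white_noise_near_uniform(self):
        values = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(4096)
            values.append(cb.spectral_entropy(x, 256.0))
        assert abs(np.mean(values) - math.log(100)) / math.log(100) < 0.05

    def test_silence_zero(self):
        assert cb.spectral_entropy(np.zeros(512), 256.0) == 0.0


class TestApproximateEntropy:
    def test_constant_guard(self):
        assert cb.approximate_entropy(np.full(30, 2.0)) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(120)
        a = cb.approximate_entropy(x)
        b = cb.approximate_entropy(5.0 * x)
        assert a == pytest.approx(b, abs=1e-12)

    def test_alternating_matches_oracle(self):
        x = np.tile([1.0, -1.0], 5)
        expected = oracles.approximate_entropy_oracle(x, 2, 0.15, 1)
        assert cb.approximate_entropy(x) == pytest.approx(expected, abs=1e-10)


class TestSampleEntropy:
    def test_constant_flagged_missing(self):
        assert math.isnan(cb.sample_entropy(np.full(30, 1.0)))

    def test_twelve_point_matches_oracle(self, rng):
        x = rng.standard_normal(12)
        expected = oracles.sample_entropy_oracle(x, 2, 0.2, 1)
        mine = cb.sample_entropy(x)
        if math.isnan(expected):
            assert math.isnan(mine)
        else:
            assert mine == pytest.approx(expected, abs=1e-10)

    def test_periodic_below_shuffled(self):
        x = np.tile(np.sin(2 * np.pi * np.arange(20) / 20), 10)
        periodic = cb.sample_entropy(x)
        gen = np.random.default_rng(0)
        shuffled = [cb.sample_entropy(gen.permutation(x)) for _ in range(10)]
        assert all(periodic < s for s in shuffled if not math.isnan(s))


class TestSvdEntropy:
    def test_constant_rank_one(self):
        assert cb.svd_entropy(np.full(20, 3.0)) == pytest.approx(0.0, abs=1e-9)

    def test_upper_bound_log2_m(self, short_series_battery):
        for x in short_series_battery:
            assert cb.svd_entropy(x) <= math.log2(CFG.svd_order) + 1e-12

    def test_sixteen_point_matches_dense_oracle(self, rng):
        x = rng.standard_normal(16)
        expected = oracles.svd_entropy_oracle(x, 3, 1)
        assert cb.svd_entropy(x) == pytest.approx(expected, abs=1e-10)

    def test_scaling_invariance(self, rng):
        x = rng.standard_normal(40)
        assert cb.svd_entropy(x) == pytest.approx(cb.svd_entropy(7.0 * x), abs=1e-12)


class TestOracleEquivalence:
    """All six estimators against independent brute-force routes."""

    def test_permutation(self, short_series_battery):
        for x in short_series_battery:
            expected = oracles.permutation_entropy_oracle(x, CFG.pe_order, CFG.pe_delay)
            assert cb.permutation_entropy(x, CFG) == pytest.approx(expected, abs=1e-10)

    def test_shannon(self, short_series_battery):
        for x in short_series_battery:
            expected = oracles.shannon_entropy_oracle(x, CFG.shannon_bins)
            assert cb.shannon_entropy(x, CFG.shannon_bins) == pytest.approx(
                expected, abs=1e-10
            )

    def test_spectral(self, short_series_battery):
        # needs length >= 2·components: use a small component count
        cfg = cb.EntropyConfig(spe_f=4)
        for x in short_series_battery:
            expected = oracles.spectral_entropy_oracle(x, 64.0, 4)
            assert cb.spectral_entropy(x, 64.0, cfg) == pytest.approx(
                expected, abs=1e-10
            )

    def test_approximate(self, short_series_battery):
        for x in short_series_battery:
            expected = oracles.approximate_entropy_oracle(
                x, CFG.apen_m, CFG.apen_r, CFG.apen_tau
            )
            assert cb.approximate_entropy(x, CFG) == pytest.approx(expected, abs=1e-10)

    def test_sample(self, short_series_battery):
        for x in short_series_battery:
            expected = oracles.sample_entropy_oracle(
                x, CFG.saen_m, CFG.saen_r, CFG.saen_tau
            )
            mine = cb.sample_entropy(x, CFG)
            if math.isnan(expected):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(expected, abs=1e-10)

    def test_svd(self, short_series_battery):
        for x in short_series_battery:
            expected = oracles.svd_entropy_oracle(x, CFG.svd_order, CFG.svd_delay)
            assert cb.svd_entropy(x, CFG) == pytest.approx(expected, abs=1e-10)

    def test_non_negative(self, short_series_battery):
        # ApEn carries a known small-sample bias that can dip below zero
        # for very short series (the brute-force oracle agrees), so its
        # sign is only asserted once the series is long enough.
        for x in short_series_battery:
            for name, value in entropy_features(x, 64.0, cb.EntropyConfig(spe_f=4)).items():
                if math.isnan(value):
                    continue
                if name == "approximate_entropy" and len(x) < 32:
                    continue
                assert value >= -1e-12, name


class TestCatalogue:
    def test_elementary_values(self):
        x = np.array([1.0, 2.0, 3.0] + [0.0] * 13)
        feats = cb.catalogue_features(x, 256.0)
        assert feats["absolute_energy"] == pytest.approx(np.sum(x**2))
        assert feats["mean_abs_change"] == pytest.approx(np.mean(np.abs(np.diff(x))))
        assert feats["absolute_sum_of_changes"] == pytest.approx(
            np.sum(np.abs(np.diff(x)))
        )
        assert feats["maximum"] == 3.0
        assert feats["sum_values"] == pytest.approx(6.0)

    def test_full_corridor_equals_mean_abs_change(self, rng):
        x = rng.standard_normal(100)
        assert _change_quantiles(x, 0.0, 1.0) == pytest.approx(
            np.mean(np.abs(np.diff(x))), abs=1e-12
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="16"):
            cb.catalogue_features(np.arange(5.0), 256.0)

    def test_statistics_against_numpy(self, rng):
        x = rng.standard_normal(256)
        feats = cb.catalogue_features(x, 256.0)
        assert feats["standard_deviation"] == pytest.approx(np.std(x))
        assert feats["quantile__0.2"] == pytest.approx(np.quantile(x, 0.2))
        assert feats["range_count__m1_1"] == np.sum((x >= -1) & (x < 1))
        assert feats["ratio_value_number_to_length"] == pytest.approx(1.0)

    def test_fft_coefficients_match_numpy(self, rng):
        x = rng.standard_normal(128)
        feats = cb.catalogue_features(x, 256.0)
        spectrum = np.fft.rfft(x)
        for k in (0, 1, 7, 19):
            assert feats[f"fft_coefficient__{k}_real"] == pytest.approx(
                spectrum[k].real
            )
            assert feats[f"fft_coefficient__{k}_abs"] == pytest.approx(
                abs(spectrum[k])
            )


@pytest.fixture(scope="module")
def extracted():
    x = np.random.default_rng(5).standard_normal(768)
    decomp = cb.ceemd(x, cb.DecomposeConfig(n_pairs=2, seed=0))
    return decomp, x, cb.extract_all(decomp, x, rate=256.0)


class TestExtractAll:

    def test_block_structure(self, extracted):
        decomp, _, feats = extracted
        components = {parse_feature_name(n)[0] for n in feats}
        assert components == {"raw", "residue"} | {
            f"imf_{j + 1}" for j in range(decomp.n_imfs)
        }
        per_component = len(feats) / (decomp.n_imfs + 2)
        assert per_component == int(per_component)

    def test_names_unique_and_parseable(self, extracted):
        _, _, feats = extracted
        assert len(feats) == len(set(feats))
        for name in feats:
            component, feature = parse_feature_name(name)
            assert component and feature

    def test_deterministic(self, extracted):
        decomp, x, feats = extracted
        again = cb.extract_all(decomp, x, rate=256.0)
        for name, value in feats.items():
            other = again[name]
            assert (math.isnan(value) and math.isnan(other)) or value == other

    def test_zero_residue_uses_conventions(self):
        x = np.sin(2 * np.pi * 25 * np.arange(768) / 256)
        decomp = cb.emd(x)
        decomp.residue[:] = 0.0
        feats = cb.extract_all(decomp, x, rate=256.0)
        assert feats["residue__shannon_entropy"] == 0.0
        assert feats["residue__svd_entropy"] == 0.0
        assert math.isnan(feats["residue__sample_entropy"])

    def test_mismatched_length_rejected(self, rng):
        decomp = cb.emd(rng.standard_normal(256))
        with pytest.raises(ValueError, match="match"):
            cb.extract_all(decomp, rng.standard_normal(300), rate=256.0)


class TestRegistry:
    def test_domains_cover_all_four(self):
        registry = cb.feature_registry()
        domains = {entry["domain"] for entry in registry}
        assert domains == {"time", "frequency", "time-frequency", "entropy"}

    def test_known_assignments(self):
        from ceemdboost.features import feature_domain

        assert feature_domain("fft_coefficient__3_abs") == "frequency"
        assert feature_domain("cwt_coefficients__width_5_std") == "time-frequency"
        assert feature_domain("sample_entropy") == "entropy"
        assert feature_domain("change_quantiles__0.1_0.2") == "time"
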