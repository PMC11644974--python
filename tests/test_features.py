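import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    oracle_frequency,
    oracle_mean_diff,
    oracle_pearson,
    oracle_statistical,
)

from imuposture.features import (
    ALL_CHANNELS,
    AXIS_FAMILIES,
    SCALAR_CHANNELS,
    FeatureConfig,
    build_feature_matrix,
    correlation_features,
    difference_features,
    frequency_features,
    statistical_features,
    summary_features,
)
from imuposture.preprocess import DerivedSignals
from imuposture.segmentation import Window


class TestStatistical:
    def test_constant_window_degenerates_to_zeros(self):
        out = statistical_features(np.full((1, 120), 2.5))
        assert out["mean"][0] == 2.5
        assert out["std"][0] == 0.0
        assert out["median"][0] == 2.5
        assert out["min"][0] == out["max"][0] == 2.5
        assert out["skew"][0] == 0.0
        assert out["kurtosis"][0] == 0.0

    def test_small_example_hand_values(self):
        out = statistical_features(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        assert out["mean"][0] == 3.0
        assert out["median"][0] == 3.0
        assert out["min"][0] == 1.0
        assert out["max"][0] == 5.0
        assert out["std"][0] == pytest.approx(np.sqrt(2.5), rel=1e-12)

    def test_symmetric_window_has_zero_skew(self):
        x = np.concatenate([np.arange(60), np.arange(60)[::-1]])[None, :].astype(float)
        out = statistical_features(x)
        assert abs(out["skew"][0]) < 1e-12

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, derandomize=True)
    def test_scaling_equivariance(self, c):
        rng = np.random.default_rng(9)
        W = rng.normal(size=(4, 120))
        base = statistical_features(W)
        scaled = statistical_features(c * W)
        for key in ("mean", "std", "median", "min", "max", "q25", "q75"):
            assert np.allclose(scaled[key], c * base[key], rtol=1e-9)
        for key in ("skew", "kurtosis"):  # shape statistics are scale-free
            assert np.allclose(scaled[key], base[key], rtol=1e-7, atol=1e-10)


class TestFrequency:
    def test_pure_tone_at_bin_center(self):
        t = np.arange(120) / 60.0
        x = np.sin(2 * np.pi * 5.0 * t)[None, :]
        out = frequency_features(x, rate=60.0)
        assert out["fmax"][0] == pytest.approx(5.0)
        assert out["centroid"][0] == pytest.approx(5.0, abs=1e-9)
        assert out["bandwidth"][0] == pytest.approx(0.0, abs=1e-6)

    def test_constant_window_convention(self):
        out = frequency_features(np.full((1, 120), 7.7), rate=60.0)
        for key in ("energy", "entropy", "centroid", "bandwidth", "fmax"):
            assert out[key][0] == 0.0

    def test_two_tone_centroid_is_midpoint(self):
        t = np.arange(120) / 60.0
        x = (np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 15.0 * t))[None, :]
        out = frequency_features(x, rate=60.0)
        assert out["centroid"][0] == pytest.approx(10.0, abs=1e-6)

    def test_time_reversal_leaves_power_features_unchanged(self, rng):
        W = rng.normal(size=(6, 120))
        a = frequency_features(W, rate=60.0)
        b = frequency_features(W[:, ::-1], rate=60.0)
        for key in ("energy", "entropy", "centroid", "bandwidth", "fmax"):
            assert np.allclose(a[key], b[key], rtol=1e-9, atol=1e-9)


class TestCorrelation:
    def test_hand_pearson_cases(self):
        x = np.array([[1.0, 2.0, 3.0]])
        assert correlation_pair(x, x) == pytest.approx(1.0)
        assert correlation_pair(x, -x) == pytest.approx(-1.0)
        y = np.array([[1.0, 3.0, 2.0]])
        assert correlation_pair(x, y) == pytest.approx(0.5)

    def test_zero_variance_pair_is_zero_by_convention(self):
        x = np.array([[1.0, 2.0, 3.0]])
        const = np.full((1, 3), 4.0)
        assert correlation_pair(x, const) == 0.0


def correlation_pair(a, b):
    from imuposture.features import _pearson

    return float(_pearson(a, b)[0])


def _random_wbc(rng, locs, n_windows=8, n=120):
    return {
        (loc, ch): rng.normal(size=(n_windows, n))
        for loc in locs
        for ch in ALL_CHANNELS
    }


class TestCrossChannelGroups:
    def test_summary_constant_legs(self):
        cfg = FeatureConfig(sensor_set=("leg_left", "leg_right"))
        g = 9.81
        wbc = {}
        for loc in cfg.sensor_set:
            for ch in ALL_CHANNELS:
                wbc[(loc, ch)] = np.zeros((2, 120))
            wbc[(loc, "acc_lp_z")] = np.full((2, 120), g)
        out = summary_features(wbc, cfg)
        for loc in cfg.sensor_set:
            assert np.allclose(out[(loc, "acc_lp", "summary", "axis_sum_mean")], g)
        assert np.allclose(out[("combined", "acc_lp_z", "summary", "loc_sum_mean")], 2 * g)

    def test_singleton_location_sum_is_identity(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        wbc = _random_wbc(rng, cfg.sensor_set)
        out = summary_features(wbc, cfg)
        for ch in ALL_CHANNELS:
            expected = wbc[("trunk_a", ch)].mean(axis=1)
            assert np.allclose(
                out[("combined", ch, "summary", "loc_sum_mean")], expected,
                rtol=1e-12,
            )

    def test_difference_constant_vector(self):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        g = 9.81
        wbc = {("trunk_a", ch): np.zeros((1, 120)) for ch in ALL_CHANNELS}
        wbc[("trunk_a", "acc_lp_z")] = np.full((1, 120), g)
        out = difference_features(wbc, cfg)
        assert out[("trunk_a", "acc_lp", "difference", "mean_diff_x_y")][0] == 0.0
        assert out[("trunk_a", "acc_lp", "difference", "mean_diff_x_z")][0] == -g
        assert out[("trunk_a", "acc_lp", "difference", "mean_diff_y_z")][0] == -g

    def test_identical_locations_have_zero_differences(self, rng):
        cfg = FeatureConfig(sensor_set=("leg_left", "leg_right"))
        base = {ch: rng.normal(size=(3, 120)) for ch in ALL_CHANNELS}
        wbc = {(loc, ch): base[ch] for loc in cfg.sensor_set for ch in ALL_CHANNELS}
        out = difference_features(wbc, cfg)
        for (loc, sig, group, name), v in out.items():
            if "leg_left" in name:
                assert np.allclose(v, 0.0)


class TestOracleAgreement:
    """Spot agreement with the brute-force oracle (the full sweep runs in the
    acceptance suite)."""

    def test_statistical_and_frequency_match_oracle(self, rng):
        W = rng.normal(size=(20, 120)) * rng.uniform(0.1, 10)
        stat = statistical_features(W)
        freq = frequency_features(W, rate=60.0)
        for i in range(W.shape[0]):
            o_stat = oracle_statistical(W[i])
            for k, v in o_stat.items():
                assert np.isclose(stat[k][i], v, rtol=1e-9, atol=1e-12), k
            o_freq = oracle_frequency(W[i], rate=60.0)
            for k, v in o_freq.items():
                assert np.isclose(freq[k][i], v, rtol=1e-9, atol=1e-9), k

    def test_pairwise_groups_match_oracle(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a", "leg_left"))
        wbc = _random_wbc(rng, cfg.sensor_set, n_windows=5)
        diff = difference_features(wbc, cfg)
        corr = correlation_features(wbc, cfg)
        fam = "gyro"
        cx, cy, cz = AXIS_FAMILIES[fam]
        for i in range(5):
            a = wbc[("trunk_a", cx)][i]
            b = wbc[("trunk_a", cy)][i]
            assert np.isclose(
                diff[("trunk_a", fam, "difference", "mean_diff_x_y")][i],
                oracle_mean_diff(a, b), rtol=1e-9, atol=1e-12,
            )
            assert np.isclose(
                corr[("trunk_a", fam, "correlation", "corr_x_y")][i],
                oracle_pearson(a, b), rtol=1e-9, atol=1e-12,
            )
            assert np.isclose(
                corr[("combined", cz, "correlation", "corr_leg_left_trunk_a")][i],
                oracle_pearson(wbc[("leg_left", cz)][i], wbc[("trunk_a", cz)][i]),
                rtol=1e-9, atol=1e-12,
            )


class TestBuildFeatureMatrix:
    def _derived(self, rng, locs, n=600):
        t = np.arange(n) / 60.0
        out = {}
        for loc in locs:
            channels = {ch: rng.normal(size=n) for ch in ALL_CHANNELS}
            out[loc] = DerivedSignals(
                location=loc, timestamps=t, channels=channels,
                artifact_mask=np.zeros(n, dtype=bool),
            )
        return out

    def test_empty_window_set_gives_empty_table_with_columns(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        derived = self._derived(rng, cfg.sensor_set)
        table = build_feature_matrix(derived, [], cfg, "i0", "s0")
        assert table.n_windows == 0
        assert table.values.shape[1] > 0

    def test_column_count_enumerates_from_config(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        derived = self._derived(rng, cfg.sensor_set)
        windows = [Window(0.0, 2.0, "Supine", 1.0)]
        table = build_feature_matrix(derived, windows, cfg, "i0", "s0")
        n_ch = len(ALL_CHANNELS)                      # 20
        n_stat = 7 + len(cfg.quantiles)               # 9 per channel
        n_freq_ch = n_ch - 2                          # roll/pitch excluded
        expected = (
            n_ch * n_stat            # statistical
            + n_freq_ch * 5          # frequency
            + len(AXIS_FAMILIES)     # summary: axis sums
            + n_ch                   # summary: singleton location sums
            + 3 * len(AXIS_FAMILIES)  # difference: axis pairs
            + 3 * len(AXIS_FAMILIES)  # correlation: axis pairs
        )
        assert table.values.shape == (1, expected)

    def test_sensor_order_does_not_change_columns(self, rng):
        locs = ("trunk_a", "leg_left", "leg_right")
        derived = self._derived(rng, locs)
        windows = [Window(0.0, 2.0, "Supine", 1.0), Window(1.0, 3.0, "Prone", 0.9)]
        t1 = build_feature_matrix(
            derived, windows, FeatureConfig(sensor_set=locs), "i", "s"
        )
        t2 = build_feature_matrix(
            derived, windows, FeatureConfig(sensor_set=locs[::-1]), "i", "s"
        )
        assert t1 == t2

    def test_unassigned_windows_are_skipped(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        derived = self._derived(rng, cfg.sensor_set)
        windows = [
            Window(0.0, 2.0, "Supine", 1.0),
            Window(1.0, 3.0, "UNASSIGNED", 0.4),
            Window(2.0, 4.0, "Prone", 0.8),
        ]
        table = build_feature_matrix(derived, windows, cfg, "i0", "s0")
        assert list(table.meta["label"]) == ["Supine", "Prone"]

    def test_time_reversed_windows_keep_non_difference_groups(self, rng):
        cfg = FeatureConfig(sensor_set=("trunk_a",))
        derived = self._derived(rng, cfg.sensor_set)
        windows = [Window(0.0, 2.0, "Supine", 1.0)]
        fwd = build_feature_matrix(derived, windows, cfg, "i", "s")
        for loc in derived:
            derived[loc].channels = {
                k: v[:120][::-1].copy() for k, v in derived[loc].channels.items()
            }
            derived[loc].timestamps = derived[loc].timestamps[:120]
            derived[loc].artifact_mask = derived[loc].artifact_mask[:120]
        rev = build_feature_matrix(derived, windows, cfg, "i", "s")
        keep = ~fwd.values.columns.get_level_values("group").isin(["difference"])
        assert np.allclose(
            fwd.values.loc[:, keep].to_numpy(),
            rev.values.loc[:, keep].to_numpy(),
            rtol=1e-9, atol=1e-9,
        )
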