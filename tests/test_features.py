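import numpy as np
import pytest

from accelsym.features import (
    FeatureSet,
    band_power,
    build_feature_set,
    build_signal_matrix,
    dft_columns,
)


def naive_dft(x):
    """O(N²) reference transform of the mean-removed sequence.

    g(k) = Σ_n (x(n) − x̄) · exp(−j·k·n·2π/N), written out as an explicit
    double loop so it shares nothing with the fft-based implementation.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    xc = x - x.mean()
    g = np.zeros(N, dtype=complex)
    for k in range(N):
        for n in range(N):
            g[k] += xc[n] * np.exp(-2j * np.pi * k * n / N)
    return g


def sinusoid_matrix(freqs_amps, N=200, fs=100.0, M=1):
    """Signal matrix whose columns are a named sum of sinusoids."""
    t = np.arange(N) / fs
    col = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    D = np.tile(col[:, None], (1, 2 * M))
    return build_signal_matrix(D[:, 0], D[:, 0], M=M, fs=fs)


class TestBuildSignalMatrix:
    def test_two_segments_of_ten(self):
        series = np.arange(1, 21, dtype=float)
        sm = build_signal_matrix(series, series, M=2, fs=100)
        assert (sm.N, sm.Q) == (10, 4)
        np.testing.assert_array_equal(sm.D[:, 0], np.arange(1, 11))
        np.testing.assert_array_equal(sm.D[:, 1], np.arange(11, 21))
        np.testing.assert_array_equal(sm.D[:, 2], sm.D[:, 0])
        assert sm.side_of_column == ["L", "L", "R", "R"]
        assert sm.pair_index == [1, 2, 1, 2]

    def test_trailing_remainder_discarded(self):
        series = np.arange(205, dtype=float)
        sm = build_signal_matrix(series, series, N=50, fs=100)
        assert (sm.M, sm.N, sm.Q) == (4, 50, 8)
        np.testing.assert_array_equal(sm.D[:, 3], series[150:200])

    def test_ten_segments_of_sixty_seconds(self):
        series = np.zeros(6000)
        sm = build_signal_matrix(series, series, M=10, fs=100)
        assert (sm.N, sm.Q) == (600, 20)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="too short|shorter"):
            build_signal_matrix(np.zeros(3), np.zeros(3), N=10, fs=100)

    def test_both_or_neither_of_m_n_rejected(self):
        series = np.zeros(100)
        with pytest.raises(ValueError):
            build_signal_matrix(series, series, fs=100)
        with pytest.raises(ValueError):
            build_signal_matrix(series, series, M=2, N=10, fs=100)

    def test_large_length_mismatch_warns_and_truncates(self):
        with pytest.warns(UserWarning, match="mismatch"):
            sm = build_signal_matrix(np.zeros(300), np.zeros(100), M=2, fs=100)
        assert sm.N == 50


class TestDftColumns:
    def test_constant_column_transforms_to_zero(self):
        sm = build_signal_matrix(np.full(64, 3.7), np.full(64, -1.2), M=1, fs=100)
        spec = dft_columns(sm)
        np.testing.assert_allclose(np.abs(spec.G), 0.0, atol=1e-12)

    def test_cosine_concentrates_at_two_bins_of_magnitude_n_half(self):
        N, m = 128, 5
        n = np.arange(N)
        col = np.cos(2 * np.pi * m * n / N)
        sm = build_signal_matrix(col, col, M=1, fs=100)
        mags = np.abs(dft_columns(sm).G[:, 0])
        assert mags[m] == pytest.approx(N / 2, rel=1e-9)
        assert mags[N - m] == pytest.approx(N / 2, rel=1e-9)
        others = np.delete(mags, [m, N - m])
        np.testing.assert_allclose(others, 0.0, atol=1e-8)

    @pytest.mark.parametrize("N", [16, 50, 128, 256])
    def test_matches_naive_quadratic_oracle(self, N):
        rng = np.random.default_rng(N)
        col = rng.normal(size=N)
        sm = build_signal_matrix(col, col, M=1, fs=100)
        fast = dft_columns(sm).G[:, 0]
        slow = naive_dft(col)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-9 * N)

    def test_parseval_identity_per_column(self):
        rng = np.random.default_rng(3)
        left, right = rng.normal(size=500), rng.normal(size=500)
        sm = build_signal_matrix(left, right, M=5, fs=100)
        spec = dft_columns(sm)
        centered = sm.D - sm.D.mean(axis=0)
        time_energy = sm.N * (centered**2).sum(axis=0)
        freq_energy = (np.abs(spec.G) ** 2).sum(axis=0)
        np.testing.assert_allclose(freq_energy, time_energy, rtol=1e-9)

    def test_frequency_resolution(self):
        sm = build_signal_matrix(np.zeros(200), np.zeros(200), M=1, fs=100)
        spec = dft_columns(sm)
        assert spec.resolution == pytest.approx(0.5)
        assert spec.freq[10] == pytest.approx(5.0)


class TestBandPower:
    def test_full_half_spectrum_band_normalizes_to_one(self):
        rng = np.random.default_rng(11)
        col = rng.normal(size=200)
        sm = build_signal_matrix(col, col, M=1, fs=100)
        E = band_power(dft_columns(sm), (100 / 200, 50.0))
        np.testing.assert_allclose(E, 1.0, rtol=1e-12)

    def test_pure_one_hertz_line_fully_in_band(self):
        spec = dft_columns(sinusoid_matrix([(1.0, 1.0)]))
        np.testing.assert_allclose(band_power(spec, (0.5, 3.0)), 1.0, rtol=1e-12)

    def test_equal_two_line_spectrum_splits_half(self):
        spec = dft_columns(sinusoid_matrix([(1.0, 1.0), (5.0, 1.0)]))
        np.testing.assert_allclose(band_power(spec, (0.5, 3.0)), 0.5, atol=1e-9)

    def test_band_edges_half_open(self):
        # a line exactly at fc2 belongs to the next band, not this one
        spec = dft_columns(sinusoid_matrix([(3.0, 1.0)]))
        np.testing.assert_allclose(band_power(spec, (0.5, 3.0)), 0.0, atol=1e-12)
        np.testing.assert_allclose(band_power(spec, (3.0, 10.0)), 1.0, rtol=1e-12)

    def test_invalid_band_rejected(self):
        spec = dft_columns(sinusoid_matrix([(1.0, 1.0)]))
        for band in [(3.0, 0.5), (-1.0, 2.0), (0.5, 51.0)]:
            with pytest.raises(ValueError):
                band_power(spec, band)

    def test_constant_column_warns_and_returns_zero(self):
        sm = build_signal_matrix(np.ones(100), np.ones(100), M=1, fs=100)
        with pytest.warns(UserWarning, match="constant"):
            E = band_power(dft_columns(sm), (0.5, 3.0))
        np.testing.assert_array_equal(E, 0.0)


class TestBuildFeatureSet:
    def test_mean_row_reproduces_constant_columns(self):
        left = np.full(40, 2.5)
        right = np.arange(40, dtype=float)
        sm = build_signal_matrix(left, right, M=2, fs=100)
        fs_ = build_feature_set(sm, features=("mean",))
        assert fs_.feature_names == ["mean"]
        np.testing.assert_allclose(fs_.P[0, :2], 2.5)

    def test_std_uses_sample_denominator(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=30)
        sm = build_signal_matrix(col, col, M=1, fs=100)
        fs_ = build_feature_set(sm, features=("std",))
        assert fs_.P[0, 0] == pytest.approx(np.std(col, ddof=1), rel=1e-12)

    def test_target_matrix_one_hot_blocks(self):
        sm = build_signal_matrix(np.arange(20.0), np.arange(20.0), M=2, fs=100)
        fs_ = build_feature_set(sm, features=("mean",))
        np.testing.assert_array_equal(fs_.T[0], [1, 1, 0, 0])
        np.testing.assert_array_equal(fs_.T[1], [0, 0, 1, 1])
        np.testing.assert_array_equal(fs_.T.sum(axis=0), 1.0)

    def test_two_feature_selection_matches_classifier_default(self):
        sm = build_signal_matrix(np.sin(np.arange(400) * 0.1), np.cos(np.arange(400) * 0.1), M=2, fs=100)
        fs_ = build_feature_set(sm, bands=[(0.5, 3.0)], features=("std", "bandpower"))
        assert fs_.R == 2
        assert fs_.feature_names == ["std", "bandpower[0.5,3)"]

    def test_empty_selection_rejected(self):
        sm = build_signal_matrix(np.arange(20.0), np.arange(20.0), M=2, fs=100)
        with pytest.raises(ValueError, match="empty"):
            build_feature_set(sm, features=())

    def test_scaling_a_side_leaves_band_power_and_scales_std(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=300)
        k = 3.7
        sm1 = build_signal_matrix(col, col, M=1, fs=100)
        sm2 = build_signal_matrix(col, k * col, M=1, fs=100)
        f1 = build_feature_set(sm1, features=("std", "bandpower"))
        f2 = build_feature_set(sm2, features=("std", "bandpower"))
        bp_rows = [i for i, n in enumerate(f1.feature_names) if n.startswith("bandpower")]
        np.testing.assert_allclose(f2.P[bp_rows, 1], f1.P[bp_rows, 1], rtol=1e-12)
        assert f2.P[0, 1] == pytest.approx(k * f1.P[0, 1], rel=1e-12)

    def test_csv_and_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        fs_ = build_feature_set(
            build_signal_matrix(rng.normal(size=100), rng.normal(size=100), M=2, fs=100)
        )
        fs_.to_json(tmp_path / "f.json")
        back = FeatureSet.from_json(tmp_path / "f.json")
        np.testing.assert_array_equal(back.P, fs_.P)
        assert back.feature_names == fs_.feature_names
        fs_.to_csv(tmp_path / "f.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "f.csv", index_col=0)
        assert list(df.columns) == fs_.column_labels
        np.testing.assert_allclose(df.to_numpy(), fs_.P)

    def test_select_unknown_feature_raises(self):
        fs_ = build_feature_set(
            build_signal_matrix(np.arange(40.0), np.arange(40.0), M=2, fs=100)
        )
        with pytest.raises(KeyError):
            fs_.select(["kurtosis"])
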