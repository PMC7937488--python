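import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emgait.features import (FuEnParams, estimate_psd, extract_features,
                             fuzzy_entropy, iav, mean_power_frequency,
                             median_frequency, var_power, wavelet_decompose,
                             wavelet_features, zero_crossings, PSD)
from emgait.preprocessing import sliding_windows


def fuen_bruteforce(x, n=2, r=None, p=2.0):
    """Direct double-loop fuzzy entropy, the independent oracle."""
    x = np.asarray(x, float)
    big_n = x.size
    r = 0.15 * np.std(x) if r is None else r

    def phi(m):
        nv = big_n - m
        total = 0.0
        for i in range(nv):
            ti = x[i:i + m] - x[i:i + m].mean()
            s = 0.0
            for j in range(nv):
                if j == i:
                    continue
                tj = x[j:j + m] - x[j:j + m].mean()
                d = np.max(np.abs(ti - tj))
                s += np.exp(-((d / r) ** p))
            total += s / (nv - 1)
        return total / nv

    return np.log(phi(n)) - np.log(phi(n + 1))


class TestTimeDomain:
    @pytest.mark.parametrize("x,expected", [
        ([1, -2, 3], 2.0), ([0, 0, 0, 0], 0.0), ([5.0] * 7, 5.0), ([-3.0], 3.0),
    ])
    def test_iav(self, x, expected):
        assert iav(x) == pytest.approx(expected)

    def test_iav_empty_rejected(self):
        with pytest.raises(ValueError):
            iav([])

    @pytest.mark.parametrize("x,expected", [
        ([1, 2, 3], 7.0), ([0, 0, 0], 0.0), ([-1, 1], 2.0),
    ])
    def test_var_power_no_mean_subtraction(self, x, expected):
        # mean-square with 1/(N-1), deliberately not the centred variance
        assert var_power(x) == pytest.approx(expected)

    def test_var_power_needs_two_samples(self):
        with pytest.raises(ValueError):
            var_power([1.0])

    @pytest.mark.parametrize("x,eps,expected", [
        ([1, -1, 1, -1], 0.0, 3),
        ([2, 3, 1, 4], 0.0, 0),
        ([0.1, -0.1, 5, -5], 1.0, 2),  # first crossing swing 0.2 < eps
    ])
    def test_zero_crossings(self, x, eps, expected):
        assert zero_crossings(x, eps) == expected

    @given(arrays(float, st.integers(2, 50),
                  elements=st.floats(-10, 10, allow_nan=False)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_time_domain_invariants(self, x):
        assert iav(x) >= 0
        assert var_power(x) >= 0
        assert 0 <= zero_crossings(x) <= x.size - 1


class TestSpectral:
    def test_zero_signal_zero_power(self):
        psd = estimate_psd(np.zeros(64), 1000, method="periodogram")
        assert np.all(psd.power == 0)

    def test_line_at_grid_point(self):
        t = np.arange(1024) / 1000
        psd = estimate_psd(np.sin(2 * np.pi * 100 * t), 1000,
                           method="periodogram")
        assert abs(psd.freqs[np.argmax(psd.power)] - 100) <= psd.freqs[1]

    def test_parseval_periodogram(self, rng):
        x = rng.standard_normal(2**15)
        psd = estimate_psd(x, 1000, method="periodogram")
        df = psd.freqs[1] - psd.freqs[0]
        assert np.sum(psd.power) * df == pytest.approx(np.mean(x**2), rel=0.05)

    def test_white_noise_centroid_and_median(self, rng):
        x = rng.standard_normal(2**15)
        psd = estimate_psd(x, 1000, method="periodogram")
        assert mean_power_frequency(psd) == pytest.approx(250, abs=5)
        assert median_frequency(psd) == pytest.approx(250, abs=5)

    def test_point_mass(self):
        psd = PSD(np.array([0.0, 50.0, 100.0]), np.array([0.0, 4.0, 0.0]))
        assert mean_power_frequency(psd) == 50.0

    def test_two_equal_lines_symmetry(self):
        f = np.arange(0, 251, 50.0)
        p = np.zeros_like(f)
        p[f == 50] = 1.0
        p[f == 150] = 1.0
        assert mean_power_frequency(PSD(f, p)) == pytest.approx(100.0)

    def test_median_interpolates_between_lines(self):
        f = np.arange(0, 251, 50.0)
        p = np.zeros_like(f)
        p[f == 50] = 1.0
        p[f == 150] = 3.0
        mf = median_frequency(PSD(f, p))
        assert 50 < mf < 150 and mf > 100  # cumulative=2 sits inside the 150 bin

    def test_degenerate_spectrum_rejected(self):
        psd = PSD(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            mean_power_frequency(psd)
        with pytest.raises(ValueError):
            median_frequency(psd)


class TestWavelet:
    def test_perfect_reconstruction(self, rng):
        import pywt
        x = rng.standard_normal(256)
        approx, details = wavelet_decompose(x, "db5", 6)
        coeffs = [approx] + list(reversed(details))
        back = pywt.waverec(coeffs, "db5", mode="symmetric")[:256]
        assert np.max(np.abs(back - x)) < 1e-8

    def test_constant_signal_vanishing_details(self):
        _, details = wavelet_decompose(np.full(256, 3.7), "db5", 3)
        for d in details:
            assert np.max(np.abs(d)) < 1e-10

    def test_pyramid_lengths_symmetric_extension(self):
        _, details = wavelet_decompose(np.zeros(256), "db5", 6)
        # decimated length recurrence: floor((n + filter_len - 1) / 2)
        lens, n = [], 256
        for _ in range(6):
            n = (n + 10 - 1) // 2
            lens.append(n)
        assert [d.size for d in details] == lens
        assert details[0].size == 132

    def test_singular_value_is_norm(self, rng):
        x = rng.standard_normal(300)
        a_mean, a_sv, d_mean, d_sv = wavelet_features(x, "db5", 6)
        approx, details = wavelet_decompose(x, "db5", 6)
        # SVD of the 1-by-M coefficient matrix as the independent oracle
        assert a_sv == pytest.approx(np.linalg.svd(approx[None, :])[1][0], abs=1e-12)
        assert d_sv == pytest.approx(np.linalg.svd(details[-1][None, :])[1][0],
                                     abs=1e-12)
        assert a_mean == pytest.approx(approx.mean())
        assert d_mean == pytest.approx(details[-1].mean())

    def test_component_mean_and_sv_345(self):
        comp = np.array([3.0, 4.0])
        assert comp.mean() == 3.5
        assert np.linalg.svd(comp[None, :])[1][0] == pytest.approx(5.0)

    def test_zero_window_zero_features(self):
        assert wavelet_features(np.zeros(256)) == (0.0, 0.0, 0.0, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            wavelet_decompose(np.zeros(4), "db5", 6)


class TestFuzzyEntropy:
    def test_constant_signal_is_zero(self):
        assert fuzzy_entropy(np.full(64, 2.5)) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(120)
            got = fuzzy_entropy(x, FuEnParams(n=2, r=0.15, p=2.0))
            assert got == pytest.approx(fuen_bruteforce(x), abs=1e-10)

    def test_matches_oracle_other_params(self, rng):
        x = rng.standard_normal(80)
        got = fuzzy_entropy(x, FuEnParams(n=3, r=0.4, p=1.5, r_mode="absolute"))
        assert got == pytest.approx(fuen_bruteforce(x, n=3, r=0.4, p=1.5),
                                    abs=1e-10)

    def test_noise_more_complex_than_sinusoid(self):
        t = np.arange(1000) / 1000
        sine = np.sin(2 * np.pi * 5 * t)
        for seed in range(20):
            noise = np.random.default_rng(seed).standard_normal(1000)
            assert fuzzy_entropy(noise) > fuzzy_entropy(sine)

    def test_nonnegative(self, rng):
        for _ in range(5):
            assert fuzzy_entropy(rng.standard_normal(200)) >= 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_entropy(np.ones(3), FuEnParams(n=2))


class TestExtraction:
    def test_eighty_columns_for_all_families(self, small_recording):
        ws = sliding_windows(small_recording, 256, 256)
        fm = extract_features(ws)
        assert fm.n_features == 80
        assert len(fm) == len(ws)
        assert np.isfinite(fm.to_numpy()).all()

    def test_time_family_only_24_columns(self, small_recording):
        ws = sliding_windows(small_recording, 256, 256)
        fm = extract_features(ws, families=("T",))
        assert fm.n_features == 24
        assert list(fm.values.columns[:3]) == ["VM.IAV", "VM.VAR", "VM.ZC"]

    def test_channel_permutation_equivariance(self, small_recording):
        from emgait.synthetic import Recording
        ws = sliding_windows(small_recording, 256, 512)
        fm = extract_features(ws, families=("T", "F"))
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        rec_p = Recording(small_recording.samples[:, perm],
                          small_recording.labels, small_recording.fs,
                          [small_recording.channel_names[i] for i in perm])
        fm_p = extract_features(sliding_windows(rec_p, 256, 512),
                                families=("T", "F"))
        for ch in rec_p.channel_names:
            for feat in ("IAV", "VAR", "ZC", "MPF", "MF"):
                col = f"{ch}.{feat}"
                np.testing.assert_allclose(fm_p.values[col], fm.values[col])

    def test_labels_carried_through(self, small_recording):
        ws = sliding_windows(small_recording, 256, 256)
        fm = extract_features(ws, families=("T",))
        assert np.array_equal(fm.labels, ws.labels)

    def test_csv_round_trip(self, small_recording, tmp_path):
        from emgait.features import FeatureMatrix
        ws = sliding_windows(small_recording, 256, 512)
        fm = extract_features(ws, families=("T",))
        fm.to_csv(tmp_path / "f.csv")
        back = FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.to_numpy(), fm.to_numpy())
        assert np.array_equal(back.labels, fm.labels)
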