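"""The 28-feature descriptor: closed forms, brute-force oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmwear.features import (
    FEATURE_NAMES,
    axis_correlations,
    crossing_segments,
    crossing_stats,
    extract_features,
    magnitude,
    magnitude_stats,
    window_feature_matrix,
)


def _brute_sign_changes(x):
    s = [v for v in np.sign(x) if v != 0]
    return sum(1 for a, b in zip(s, s[1:]) if a != b)


def _triaxial(x, fill=1.0):
    out = np.full((len(x), 3), fill)
    out[:, 0] = x
    return out


class TestMagnitude:
    def test_pythagorean_triple(self):
        assert magnitude(np.array([[3.0, 4.0, 0.0]]))[0] == 5.0

    def test_zero_and_unit_axis(self):
        assert np.all(magnitude(np.zeros((5, 3))) == 0)
        x = np.zeros((5, 3))
        x[:, 0] = 1.0
        assert np.all(magnitude(x) == 1.0)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            magnitude(np.zeros((5, 2)))


class TestCrossingSegments:
    def test_2hz_cosine_sampled_at_25hz(self):
        """12 sign changes / 13 runs on one axis, by brute-force oracle."""
        t = np.arange(75) / 25.0
        x = np.cos(2 * np.pi * 2 * t)
        oracle = _brute_sign_changes(x)
        assert oracle == 12
        segs = crossing_segments(_triaxial(x))
        assert len(segs.run_lengths[0]) == oracle + 1 == 13
        assert len(segs.run_lengths[1]) == 1  # constant positive axis

    def test_strictly_positive_axis_single_run(self):
        segs = crossing_segments(np.ones((40, 3)))
        for runs in segs.run_lengths:
            assert len(runs) == 1 and runs[0] == 40

    def test_alternating_signs(self):
        n = 30
        x = np.tile([1.0, -1.0], n // 2)
        segs = crossing_segments(_triaxial(x))
        assert len(segs.run_lengths[0]) == n
        assert np.all(segs.run_lengths[0] == 1)

    def test_run_lengths_partition_series(self, rng):
        x = rng.normal(size=(200, 3))
        segs = crossing_segments(x)
        for runs in segs.run_lengths:
            assert runs.sum() == 200
            assert np.all(runs >= 1)

    def test_zeros_inherit_neighbouring_sign(self):
        x = np.array([0.0, 0.0, 1.0, 0.0, -1.0])
        segs = crossing_segments(_triaxial(x))
        assert list(segs.run_lengths[0]) == [4, 1]


class TestCrossingStats:
    def test_identical_run_lengths_zero_entropy(self):
        y = np.tile([1.0, 1, -1, -1], 20)  # every run has length 2
        segs = crossing_segments(np.tile(y[:, None], (1, 3)))
        _, avg, ent = crossing_stats(segs)
        assert ent == 0.0
        assert avg == 2.0

    def test_two_lengths_equal_frequency_is_ln2(self):
        x = np.tile([1.0, -1, -1], 20)  # runs alternate length 1 and 2
        _, _, ent = crossing_stats(crossing_segments(np.tile(x[:, None], (1, 3))))
        assert ent == pytest.approx(np.log(2), abs=1e-6)

    def test_2hz_cosine_pooled_over_axes(self):
        t = np.arange(75) / 25.0
        x = np.cos(2 * np.pi * 2 * t)
        xyz = np.tile(x[:, None], (1, 3))
        number, avg, _ = crossing_stats(crossing_segments(xyz))
        assert number == 36  # 12 per axis, brute-force verified above
        assert avg == pytest.approx(3 * 75 / 39)


class TestMagnitudeStats:
    def test_constant_series_conventions(self):
        s = magnitude_stats(np.full(100, 3.5), fs=25.0)
        assert s["min"] == s["max"] == s["median"] == s["RMS"] == 3.5
        assert s["entropy"] == 0.0
        assert s["skewness"] == 0.0 and s["kurtosis"] == 0.0

    def test_rectified_sine_doubles_dominant_frequency(self):
        """|sin(2*pi*3t)| has its periodogram peak at 6 Hz."""
        fs, n = 30.0, 90
        t = np.arange(n) / fs
        mag = np.abs(np.sin(2 * np.pi * 3 * t))
        pxx = np.abs(np.fft.rfft(mag)) ** 2  # independent FFT oracle
        k = np.argmax(pxx[1:]) + 1
        assert k * fs / n == pytest.approx(6.0)
        s = magnitude_stats(mag, fs)
        assert s["dom freq over energy"] * pxx.sum() == pytest.approx(6.0, rel=1e-9)

    def test_uniform_histogram_entropy_is_log2_nbins(self):
        x = np.repeat((np.arange(100) + 0.5) / 100, 3)
        s = magnitude_stats(x, fs=25.0)
        assert s["entropy"] == pytest.approx(np.log2(100), abs=0.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            magnitude_stats(np.ones(5), fs=25.0)


class TestAxisCorrelations:
    def test_perfectly_correlated_and_anticorrelated(self, rng):
        x = rng.normal(size=200)
        xyz = np.column_stack([x, x, -x])
        cxy, cxz, cyz = axis_correlations(xyz)
        assert cxy == pytest.approx(1.0)
        assert cxz == pytest.approx(-1.0)
        assert cyz == pytest.approx(-1.0)

    def test_independent_noise_nearly_uncorrelated(self, rng):
        xyz = rng.normal(size=(10000, 3))
        assert max(abs(c) for c in axis_correlations(xyz)) < 0.1

    def test_constant_axis_defined_as_zero(self):
        xyz = np.column_stack([np.arange(10.0), np.ones(10), np.arange(10.0)])
        cxy, cxz, cyz = axis_correlations(xyz)
        assert cxy == 0.0 and cyz == 0.0 and cxz == pytest.approx(1.0)


class TestExtractFeatures:
    def test_exactly_28_named_features(self, rng):
        feats = extract_features(rng.normal(size=(75, 3)), rng.normal(size=(75, 3)), 25.0)
        assert tuple(feats) == FEATURE_NAMES
        assert len(feats) == 28
        assert "Acc crossing entropy" in feats
        assert "Vel dom freq over energy" in feats

    def test_swapping_signals_swaps_halves(self, rng):
        a, v = rng.normal(size=(75, 3)), rng.normal(size=(75, 3))
        f1 = list(extract_features(a, v, 25.0).values())
        f2 = list(extract_features(v, a, 25.0).values())
        assert f1[:14] == f2[14:]
        assert f1[14:] == f2[:14]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scale_equivariance_partition(self, seed):
        """Doubling the signal doubles the amplitude features, leaves the
        shape features (correlations, crossing statistics, skewness,
        kurtosis, histogram entropy) unchanged, and quarters the dominant
        frequency over energy."""
        rng = np.random.default_rng(seed)
        a, v = rng.normal(size=(75, 3)), rng.normal(size=(75, 3))
        f1 = extract_features(a, v, 25.0)
        f2 = extract_features(2 * a, 2 * v, 25.0)
        for prefix in ("Acc", "Vel"):
            for name in ("corr XY", "corr XZ", "corr YZ", "crossing number",
                         "crossing average length", "crossing entropy",
                         "skewness", "kurtosis", "entropy"):
                assert f2[f"{prefix} {name}"] == pytest.approx(
                    f1[f"{prefix} {name}"], abs=1e-9)
            for name in ("min", "max", "median", "RMS"):
                assert f2[f"{prefix} {name}"] == pytest.approx(
                    2 * f1[f"{prefix} {name}"], rel=1e-9)
            assert f2[f"{prefix} dom freq over energy"] == pytest.approx(
                f1[f"{prefix} dom freq over energy"] / 4, rel=1e-9)

    def test_all_features_finite_on_simulated_windows(self, small_cohort):
        _, _, _, window_sets = small_cohort
        data = np.concatenate([w.data for w in window_sets])
        matrix = window_feature_matrix(data, 25.0)
        assert np.isfinite(matrix).all()


class TestBatchEquivalence:
    def test_batch_matches_per_epoch(self, rng):
        windows = rng.normal(size=(30, 75, 6))
        windows[0, :, 2] = 4.0  # constant channel
        windows[1, :, :] = 0.0  # all-zero window
        windows[2, :40, 4] = 0.0  # run of zeros
        batch = window_feature_matrix(windows, 25.0)
        for i in range(len(windows)):
            ref = list(extract_features(windows[i, :, :3], windows[i, :, 3:], 25.0).values())
            assert np.allclose(batch[i], ref, rtol=1e-10, atol=1e-12), i
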