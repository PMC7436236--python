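"""Feature formulas against brute-force oracles, plus normalization rules."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gaitforce import features
from gaitforce.features import (FEATURE_SCALARS, WINDOW_LEN, apply_normalizer,
                                build_feature_matrix, fit_normalizer,
                                median_filter, scale_values, window_features)

IDX = {name: i for i, name in enumerate(FEATURE_SCALARS)}


def brute_force_features(w):
    """Plain, loop-based evaluation of every feature formula."""
    w = np.asarray(w, dtype=float)
    N = len(w)
    mean = sum(w) / N
    d = [w[i] - w[i - 1] for i in range(1, N)]
    rms = (sum(x * x for x in w) / N) ** 0.5
    sav = sum(abs(x) for x in w)
    mad = sum(abs(x - mean) for x in w) / N
    var = sum((x - mean) ** 2 for x in w) / (N - 1)
    wl = sum(abs(x) for x in d)
    ssc = sum(1 for i in range(1, N - 1)
              if (w[i] - w[i - 1]) * (w[i] - w[i + 1]) > 0)
    ssi = sum(x * x for x in w)
    _, detail = pywt.dwt(w, "db7", mode="symmetric")
    mwt = float(np.mean(np.abs(detail)))
    dasdv = (sum(x * x for x in d) / (N - 1)) ** 0.5
    aac = wl / (N - 1)
    log = float(np.exp(sum(np.log(abs(x) + 1e-12) for x in w) / N))
    i = np.arange(1, N + 1)
    slope, intercept = np.polyfit(i, w, 1)
    a, b, c = np.polyfit(i, w, 2)
    return np.array([rms, sav, mad, var, wl, ssc, ssi, mwt, dasdv, aac, log,
                     slope, intercept, a, b, c])


class TestMedianFilter:
    def test_constant_unchanged(self):
        np.testing.assert_array_equal(median_filter(np.full(20, 3.0)),
                                      np.full(20, 3.0))

    def test_center_element(self):
        out = median_filter(np.array([1.0, 9.0, 1.0, 1.0, 5.0]), 5)
        assert out[2] == 1.0  # median of {1, 9, 1, 1, 5}

    def test_width_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=30)
        np.testing.assert_array_equal(median_filter(x, 1), x)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros(10), 4)

    def test_length_preserved(self):
        assert median_filter(np.arange(17.0)).shape == (17,)


class TestWindowFeatures:
    def test_null_signal(self):
        f = window_features(np.zeros(11))
        for name in ("rms", "sav", "wl", "ssc", "ssi", "linfit.slope"):
            assert f[IDX[name]] == 0.0

    def test_constant_ones(self):
        f = window_features(np.ones(11))
        assert f[IDX["rms"]] == pytest.approx(1.0)
        assert f[IDX["sav"]] == pytest.approx(11.0)
        assert f[IDX["var"]] == pytest.approx(0.0)
        assert f[IDX["wl"]] == pytest.approx(0.0)
        assert f[IDX["dasdv"]] == pytest.approx(0.0)

    def test_alternating_signal(self):
        w = np.array([1.0, -1.0] * 5 + [1.0])
        f = window_features(w)
        assert f[IDX["wl"]] == pytest.approx(20.0)
        assert f[IDX["aac"]] == pytest.approx(2.0)
        assert f[IDX["dasdv"]] == pytest.approx(2.0)
        assert f[IDX["ssc"]] == 9

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            window_features(np.zeros(10))

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            w = rng.normal(scale=rng.uniform(0.1, 10), size=11)
            got = window_features(w)
            want = brute_force_features(w)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_translation_invariance_split(self):
        """Shape features ignore a constant offset; energy features do not."""
        rng = np.random.default_rng(3)
        w = rng.normal(size=11)
        f0, f1 = window_features(w), window_features(w + 5.0)
        invariant = ["wl", "ssc", "dasdv", "aac", "var", "mad", "linfit.slope"]
        changing = ["rms", "sav", "ssi", "logdet"]
        for name in invariant:
            assert f1[IDX[name]] == pytest.approx(f0[IDX[name]], abs=1e-9), name
        for name in changing:
            assert abs(f1[IDX[name]] - f0[IDX[name]]) > 1e-3, name


_windows = arrays(np.float64, WINDOW_LEN,
                  elements=st.floats(-100, 100, allow_nan=False,
                                     allow_infinity=False, width=64))


class TestFeatureProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_windows)
    def test_oracle_agreement_on_arbitrary_windows(self, w):
        np.testing.assert_allclose(window_features(w),
                                   brute_force_features(w),
                                   rtol=1e-9, atol=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(_windows)
    def test_all_features_finite(self, w):
        assert np.all(np.isfinite(window_features(w)))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(_windows, st.floats(0.1, 10))
    def test_scaling_homogeneity_of_amplitude_features(self, w, c):
        """SAV, WL and RMS are degree-1 homogeneous in the signal amplitude."""
        f0, f1 = window_features(w), window_features(c * w)
        for name in ("sav", "wl", "rms"):
            assert f1[IDX[name]] == pytest.approx(c * f0[IDX[name]],
                                                  rel=1e-9, abs=1e-12)


class TestBuildFeatureMatrix:
    def test_shape_and_alignment(self, quiet_trial):
        fm = build_feature_matrix(quiet_trial, "shank")
        assert fm.values.shape == (quiet_trial.n_samples, 96)
        assert len(fm.feature_names) == 96
        np.testing.assert_array_equal(fm.target, quiet_trial.vgrf)

    def test_unknown_location_rejected(self, quiet_trial):
        with pytest.raises(KeyError):
            build_feature_matrix(quiet_trial, "sternum")

    def test_window_locality_away_from_edges(self, quiet_subject):
        """Feature rows more than half a window from a record boundary do not
        depend on what lies beyond it: a 6 s record's interior rows match the
        same rows of the 12 s record it is a prefix of."""
        from gaitforce.synthetic import simulate_trial
        short = build_feature_matrix(simulate_trial(quiet_subject, 1.0, 6.0),
                                     "shank")
        long = build_feature_matrix(simulate_trial(quiet_subject, 1.0, 12.0),
                                    "shank")
        n = short.n_samples
        np.testing.assert_allclose(long.values[8:n - 8], short.values[8:n - 8],
                                   rtol=1e-12, atol=1e-12)


class TestNormalizer:
    def test_linear_rescale(self):
        lo, hi = fit_normalizer(np.array([[2.0], [4.0], [6.0]]))
        out = scale_values(np.array([[2.0], [4.0], [6.0]]), lo, hi)
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0]])
        lo, hi = fit_normalizer(X)
        out = scale_values(X, lo, hi)
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_out_of_range_clipped(self):
        lo, hi = fit_normalizer(np.array([[0.0], [1.0]]))
        out = scale_values(np.array([[2.0], [-1.0]]), lo, hi)
        np.testing.assert_allclose(out.ravel(), [1.0, 0.0])

    def test_idempotent_after_clipping(self):
        rng = np.random.default_rng(1)
        train = rng.normal(size=(50, 4))
        test = rng.normal(size=(20, 4)) * 2
        lo, hi = fit_normalizer(train)
        once = scale_values(test, lo, hi)
        clipped = np.clip(test, lo, hi)
        np.testing.assert_allclose(scale_values(clipped, lo, hi), once,
                                   atol=1e-12)

    def test_mismatched_names_rejected(self, quiet_trial):
        fm = build_feature_matrix(quiet_trial, "shank")
        lo, hi = fit_normalizer(fm.values)
        with pytest.raises(ValueError):
            apply_normalizer(fm, (lo, hi), feature_names=["bogus"] * 96)

    def test_every_entry_in_unit_interval(self, quiet_trial):
        fm = build_feature_matrix(quiet_trial, "shank")
        scaled = apply_normalizer(fm, fit_normalizer(fm.values))
        assert scaled.values.min() >= 0.0 and scaled.values.max() <= 1.0
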