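import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroictal import (CANONICAL_FEATURES, CDParams, DWDConfig, SampEnParams,
                        correlation_dimension, correlation_sum, dwd_decompose,
                        dwd_reconstruct, embed_delay, extract_epoch_features,
                        fit_quantizer, quantize, sample_entropy,
                        subband_frequency_ranges, subband_stats,
                        wavelet_artifact_clean)
from neuroictal.eeg_data import Epoch
from neuroictal.features import (DB4_HI, DB4_LO, FeatureConfig,
                                 DegenerateSeriesError, dequantize)


def sampen_bruteforce(x, m, r):
    """Independent O(n^2) template-counting oracle (Richman-Moorman)."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0:
        raise ZeroDivisionError
    return float("inf") if a == 0 else -np.log(a / b)


class TestFilterBank:
    def test_db4_is_orthonormal_qmf_pair(self):
        assert np.isclose(DB4_LO.sum(), np.sqrt(2.0))
        assert np.isclose((DB4_LO ** 2).sum(), 1.0)
        for shift in (2, 4, 6):
            assert abs(np.dot(DB4_LO[:-shift], DB4_LO[shift:])) < 1e-12
        assert abs(np.dot(DB4_LO, DB4_HI)) < 1e-12

    @pytest.mark.parametrize("band,expected", [
        ("D1", (125.0, 250.0)),
        ("D2", (62.5, 125.0)),
        ("D3", (31.25, 62.5)),
        ("D4", (15.625, 31.25)),
        ("D5", (7.8125, 15.625)),
        ("D6", (3.90625, 7.8125)),
        ("A6", (0.0, 3.90625)),
    ])
    def test_dyadic_band_ranges_at_500hz(self, band, expected):
        ranges = subband_frequency_ranges(500.0, 6)
        names = ["D1", "D2", "D3", "D4", "D5", "D6", "A6"]
        assert ranges[names.index(band)] == expected

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(f0=st.floats(1.0, 500.0))
    def test_level1_detail_dyadic_identity(self, f0):
        ranges = subband_frequency_ranges(2 * f0, 1)
        assert np.allclose(ranges[0], (f0 / 2, f0))

    def test_decomposition_yields_seven_subsignals(self, rng):
        sub = dwd_decompose(rng.normal(size=2500), DWDConfig(fs=500))
        assert len(sub.sub_signals()) == 7

    def test_perfect_reconstruction(self, rng):
        for n in (2500, 1000, 640, 711):
            x = rng.normal(size=n)
            sub = dwd_decompose(x, DWDConfig(fs=500))
            assert np.abs(dwd_reconstruct(sub, n) - x).max() < 1e-8

    def test_too_short_epoch_raises_with_minimum(self, rng):
        with pytest.raises(ValueError, match="64"):
            dwd_decompose(rng.normal(size=32), DWDConfig(fs=500))


class TestCleaning:
    def test_sinusoid_preserved(self):
        t = np.arange(2500) / 500.0
        x = 40 * np.sin(2 * np.pi * 10 * t)
        y = wavelet_artifact_clean(x, DWDConfig(fs=500))
        assert np.corrcoef(x, y)[0, 1] > 0.99

    def test_constant_offset_removed(self, rng):
        x = rng.normal(size=1280) + 500.0
        y = wavelet_artifact_clean(x, DWDConfig(fs=500))
        assert abs(y.mean()) < 1.0

    def test_zeros_in_zeros_out(self):
        y = wavelet_artifact_clean(np.zeros(640), DWDConfig(fs=500))
        assert np.allclose(y, 0.0)


class TestSubbandStats:
    def test_plus_minus_one(self):
        sub = dwd_decompose(np.random.default_rng(0).normal(size=128),
                            DWDConfig(n_levels=1, fs=100))
        sub.details[0] = np.array([1.0, -1.0])
        sub.approximation = np.array([2.0, 2.0])
        stats = subband_stats(sub)
        # D1: RMS=1, MA=1, AM=0; A1: all = 2
        assert np.allclose(stats, [1.0, 1.0, 0.0, 2.0, 2.0, 2.0])

    def test_six_level_count_is_21(self, rng):
        stats = subband_stats(dwd_decompose(rng.normal(size=2500),
                                            DWDConfig(fs=500)))
        assert stats.shape == (21,)


class TestSampleEntropy:
    def test_constant_series_absolute_r_is_zero(self):
        v = sample_entropy(np.ones(60),
                           SampEnParams(r_mode="absolute", r_value=0.1))
        assert v == 0.0

    def test_constant_series_relative_r_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            sample_entropy(np.ones(60), SampEnParams())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=200)
        r = 0.2 * x.std()
        mine = sample_entropy(
            x, SampEnParams(m=2, r_mode="absolute", r_value=r))
        assert abs(mine - sampen_bruteforce(x, 2, r)) < 1e-10

    def test_periodic_hand_enumeration(self):
        # x = [0,1]*8, m=2, absolute r=0.5: every same-parity pair of
        # templates matches exactly and extends, so A == B and SampEn = 0
        x = np.array([0.0, 1.0] * 8)
        v = sample_entropy(x, SampEnParams(m=2, r_mode="absolute",
                                           r_value=0.5))
        n = 16
        nt = n - 2
        b = sum(1 for i in range(nt) for j in range(nt)
                if i != j and (i - j) % 2 == 0)
        assert b > 0
        assert v == -np.log(b / b) == 0.0

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-100, 100),
           seed=st.integers(0, 10))
    def test_affine_invariance_with_relative_r(self, scale, offset, seed):
        x = np.random.default_rng(seed).normal(size=150)
        a = sample_entropy(x)
        b = sample_entropy(scale * x + offset)
        assert abs(a - b) < 1e-9

    def test_b_zero_raises(self):
        x = np.array([0.0, 100.0, -100.0, 50.0, -50.0, 75.0])
        with pytest.raises(ValueError, match="B = 0"):
            sample_entropy(x, SampEnParams(m=2, r_mode="absolute",
                                           r_value=1e-6))


class TestCorrelationDimension:
    def test_correlation_sum_matches_bruteforce(self, rng):
        pts = rng.normal(size=(50, 3))
        times = np.arange(50.0)
        for r in (0.5, 1.5, 3.0):
            cs = correlation_sum(pts, r, times, theiler=2)
            count = valid = 0
            for i in range(50):
                for j in range(i + 1, 50):
                    if abs(times[i] - times[j]) <= 2:
                        continue
                    valid += 1
                    if np.linalg.norm(pts[i] - pts[j]) <= r:
                        count += 1
            assert cs == count / valid

    def test_sinusoid_dimension_near_one(self):
        # incommensurate frequency so sampled phases fill the limit cycle
        x = np.sin(2 * np.pi * 9.7 * np.arange(4000) / 500.0)
        assert 0.8 <= correlation_dimension(x) <= 1.2

    def test_white_noise_dimension_high(self):
        x = np.random.default_rng(7).normal(size=2000)
        assert correlation_dimension(x, CDParams(embed_dim=5)) > 3.0

    def test_embedding_shape_and_content(self):
        x = np.arange(10.0)
        e = embed_delay(x, 3, 2)
        assert e.shape == (6, 3)
        assert np.array_equal(e[0], [0, 2, 4])

    def test_degenerate_constant_series(self):
        with pytest.raises(ValueError):
            correlation_dimension(np.zeros(500))


class TestExtraction:
    def test_full_set_shape_21x23(self, rng):
        ep = Epoch(data=rng.normal(size=(21, 1500)), start_s=0,
                   duration_s=3.0, fs=500.0)
        fv = extract_epoch_features(ep)
        assert fv.values.shape == (21, 23)
        assert fv.feature_names == list(CANONICAL_FEATURES)

    def test_subset_excludes_cd(self, rng):
        ep = Epoch(data=rng.normal(size=(2, 1000)), start_s=0,
                   duration_s=2.0, fs=500.0)
        names = [nm for nm in CANONICAL_FEATURES if nm != "CD"]
        fv = extract_epoch_features(ep, names)
        assert "CD" not in fv.feature_names
        assert fv.values.shape == (2, 22)

    def test_unknown_feature_rejected(self, rng):
        ep = Epoch(data=rng.normal(size=(1, 1000)), start_s=0,
                   duration_s=2.0, fs=500.0)
        with pytest.raises(ValueError, match="unknown feature"):
            extract_epoch_features(ep, ["CD", "bogus"])

    def test_deterministic(self, rng):
        data = rng.normal(size=(2, 1000))
        ep1 = Epoch(data=data.copy(), start_s=0, duration_s=2.0, fs=500.0)
        ep2 = Epoch(data=data.copy(), start_s=5, duration_s=2.0, fs=500.0)
        a = extract_epoch_features(ep1, ["SampEn", "RMS_D3"])
        b = extract_epoch_features(ep2, ["SampEn", "RMS_D3"])
        assert np.array_equal(a.values, b.values)


class TestQuantization:
    def test_endpoints_and_midpoint(self):
        q = fit_quantizer(np.array([[0.0], [10.0]]))
        assert quantize([0.0], q)[0] == 0
        assert quantize([10.0], q)[0] == 255
        # midpoint rounds half-up to 128
        assert quantize([5.0], q)[0] == 128

    def test_out_of_range_clipped_constant_zero(self):
        q = fit_quantizer(np.array([[0.0, 7.0], [10.0, 7.0]]))
        assert quantize([-5.0, 7.0], q)[0] == 0
        assert quantize([99.0, 7.0], q)[0] == 255
        assert quantize([3.0, 7.0], q)[1] == 0   # constant feature -> 0

    def test_pattern_budget_252_bytes(self):
        # 21 channels x 12 one-byte features
        nf = 21 * 12
        assert nf == 252 <= 256
        q = fit_quantizer(np.vstack([np.zeros(nf), np.ones(nf)]))
        assert quantize(np.full(nf, 0.5), q).nbytes == 252

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 100))
    def test_quantization_idempotent(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(20, 6)) * r.uniform(0.1, 100, size=6)
        q = fit_quantizer(X)
        v = r.normal(size=6) * 10
        q1 = quantize(v, q)
        q2 = quantize(dequantize(q1, q), q)
        assert np.array_equal(q1, q2)
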