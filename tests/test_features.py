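"""Windowing and the 33-feature contract, checked against naive-loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from tremorwild.features import (
    FEATURE_NAMES,
    N_FEATURES,
    WindowConfig,
    build_feature_matrix,
    energy_features,
    extract_features,
    make_windows,
    periodogram_psd,
    spectral_features,
    standardize,
    time_features,
    to_arrays,
)
from tremorwild.io_preprocess import SubjectMeta, preprocess_dataset
from tremorwild.synthetic import SyntheticCohortConfig, simulate_cohort

from conftest import make_recording


# ---------------------------------------------------------------------------
# naive-loop oracles, kept deliberately dumb and independent of the package


def naive_stats(v):
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    std = math.sqrt(m2)
    kurt = m4 / m2**2 - 3.0 if m2 else 0.0
    skew = m3 / m2**1.5 if m2 else 0.0
    return max(v), min(v), mean, std, kurt, skew


def naive_energy(seg):
    te = sum(x * x + y * y + z * z for x, y, z in seg)
    sma = sum(abs(x) + abs(y) + abs(z) for x, y, z in seg)
    return te, sma


def naive_spectral(freqs, psd):
    total = sum(psd)
    centroid = sum(f * p for f, p in zip(freqs, psd)) / total
    acc, rolloff = 0.0, freqs[-1]
    for f, p in zip(freqs, psd):
        acc += p
        if acc >= 0.85 * total:
            rolloff = f
            break
    var = sum(p / total * (f - centroid) ** 2 for f, p in zip(freqs, psd))
    sd = math.sqrt(var)
    if sd == 0.0:
        skew, kurt = 0.0, 0.0
    else:
        skew = sum(p / total * ((f - centroid) / sd) ** 3 for f, p in zip(freqs, psd))
        kurt = sum(p / total * ((f - centroid) / sd) ** 4 for f, p in zip(freqs, psd)) - 3
    ent = -sum(
        (p / total) * math.log2(p / total) for p in psd if p > 0
    )
    return centroid, rolloff, skew, kurt, ent


# ---------------------------------------------------------------------------


class TestMakeWindows:
    def test_overlapping_window_starts(self):
        rec = make_recording(np.arange(250.0))
        wins = make_windows(rec, WindowConfig(100, 0.5))
        assert [w[0] for w in wins] == [0, 1, 2, 3]
        starts = [int(seg[0, 0]) for _, seg in wins]
        assert starts == [0, 50, 100, 150]
        assert all(seg.shape == (100, 3) for _, seg in wins)

    def test_exact_length_gives_one_window(self):
        rec = make_recording(np.arange(100.0))
        assert len(make_windows(rec, WindowConfig())) == 1

    def test_short_recording_gives_none(self):
        rec = make_recording(np.arange(99.0))
        assert make_windows(rec, WindowConfig()) == []

    def test_window_count_formula(self):
        cfg = WindowConfig(100, 0.5)
        for L in (100, 149, 150, 199, 200, 1000):
            rec = make_recording(np.zeros(L))
            expected = (L - cfg.window_size) // cfg.step + 1
            assert len(make_windows(rec, cfg)) == expected


class TestTimeFeatures:
    def test_constant_segment_degenerate_conventions(self):
        seg = np.full((100, 3), 2.5)
        v = time_features(seg)
        named = dict(zip(FEATURE_NAMES[:22], v))
        for ax in "xyz":
            assert named[f"max_{ax}"] == named[f"min_{ax}"] == named[f"mean_{ax}"] == 2.5
            assert named[f"std_{ax}"] == named[f"kurtosis_{ax}"] == named[f"skewness_{ax}"] == 0.0
        assert named["zero_crossing_rate"] == 0.0
        assert named["corr_xy"] == named["corr_xz"] == named["corr_yz"] == 0.0

    def test_zero_crossing_rate_alternating_magnitude(self):
        # magnitude alternates between two values; mean-removed it flips sign
        # every sample, so the rate is exactly 1
        seg = np.zeros((100, 3))
        seg[:, 0] = np.where(np.arange(100) % 2 == 0, 2.0, 1.0)
        v = dict(zip(FEATURE_NAMES[:22], time_features(seg)))
        assert v["zero_crossing_rate"] == pytest.approx(1.0)

    def test_matches_naive_oracle_on_random_segment(self):
        rng = np.random.default_rng(42)
        seg = rng.standard_normal((100, 3))
        v = time_features(seg)
        for j, ax in enumerate("xyz"):
            mx, mn, mean, std, kurt, skew = naive_stats(list(seg[:, j]))
            named = dict(zip(FEATURE_NAMES[:22], v))
            assert named[f"max_{ax}"] == pytest.approx(mx, abs=1e-10)
            assert named[f"min_{ax}"] == pytest.approx(mn, abs=1e-10)
            assert named[f"mean_{ax}"] == pytest.approx(mean, abs=1e-10)
            assert named[f"std_{ax}"] == pytest.approx(std, abs=1e-10)
            assert named[f"kurtosis_{ax}"] == pytest.approx(kurt, abs=1e-10)
            assert named[f"skewness_{ax}"] == pytest.approx(skew, abs=1e-10)

    def test_correlation_of_identical_axes_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        seg = np.column_stack([x, x, -x])
        v = dict(zip(FEATURE_NAMES[:22], time_features(seg)))
        assert v["corr_xy"] == pytest.approx(1.0)
        assert v["corr_xz"] == pytest.approx(-1.0)

    def test_per_axis_stats_equivariant_under_axis_permutation(self):
        rng = np.random.default_rng(3)
        seg = rng.standard_normal((100, 3))
        v = time_features(seg)
        w = time_features(seg[:, [1, 2, 0]])
        # stat blocks are stat-major: permuting axes permutes within blocks
        for b in range(6):
            block_v = v[3 * b : 3 * b + 3]
            block_w = w[3 * b : 3 * b + 3]
            np.testing.assert_allclose(block_w, block_v[[1, 2, 0]], atol=1e-12)


class TestSpectralFeatures:
    def test_pure_tone_centroid_and_rolloff(self):
        t = np.arange(100) / 100.0
        seg = np.zeros((100, 3))
        seg[:, 0] = 10.0 + np.sin(2 * np.pi * 5.0 * t)
        v = dict(zip(FEATURE_NAMES[22:31], spectral_features(seg, 100.0)))
        assert abs(v["spectral_centroid"] - 5.0) <= 1.0
        assert abs(v["spectral_rolloff"] - 5.0) <= 1.0

    def test_flatness_separates_noise_from_tone(self):
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((100, 3))
        flat_noise = dict(zip(FEATURE_NAMES[22:31], spectral_features(noise, 100.0)))
        t = np.arange(100) / 100.0
        tone = np.zeros((100, 3))
        tone[:, 0] = 5.0 + np.sin(2 * np.pi * 5 * t)
        flat_tone = dict(zip(FEATURE_NAMES[22:31], spectral_features(tone, 100.0)))
        assert flat_noise["spectral_flatness"] >= 0.3
        assert flat_tone["spectral_flatness"] <= 0.1
        assert 0 < flat_tone["spectral_flatness"] <= 1.0

    def test_all_zero_segment_returns_zeros(self):
        assert np.all(spectral_features(np.zeros((100, 3)), 100.0) == 0.0)

    def test_single_bin_spectrum_entropy_zero(self):
        # entropy of p = (1, 0, ..., 0) is 0 by Shannon's formula
        freqs = np.arange(5.0)
        psd = np.array([4.0, 0, 0, 0, 0])
        _, _, _, _, ent = naive_spectral(freqs, psd)
        assert ent == 0.0

    def test_matches_naive_oracle_on_random_segment(self):
        rng = np.random.default_rng(5)
        seg = rng.standard_normal((100, 3))
        freqs, psd = periodogram_psd(
            np.sqrt((seg**2).sum(axis=1)) - np.sqrt((seg**2).sum(axis=1)).mean(),
            100.0,
        )
        centroid, rolloff, skew, kurt, ent = naive_spectral(list(freqs), list(psd))
        v = dict(zip(FEATURE_NAMES[22:31], spectral_features(seg, 100.0)))
        assert v["psd_max"] == pytest.approx(max(psd), abs=1e-12)
        assert v["psd_mean"] == pytest.approx(sum(psd) / len(psd), abs=1e-12)
        assert v["spectral_centroid"] == pytest.approx(centroid, abs=1e-9)
        assert v["spectral_rolloff"] == pytest.approx(rolloff, abs=1e-9)
        assert v["spectral_skewness"] == pytest.approx(skew, abs=1e-9)
        assert v["spectral_kurtosis"] == pytest.approx(kurt, abs=1e-9)
        assert v["spectral_entropy"] == pytest.approx(ent, abs=1e-9)

    def test_entropy_bounded_by_log_bins(self):
        rng = np.random.default_rng(9)
        seg = rng.standard_normal((100, 3))
        v = dict(zip(FEATURE_NAMES[22:31], spectral_features(seg, 100.0)))
        n_bins = len(periodogram_psd(np.zeros(100), 100.0)[0])
        assert 0.0 <= v["spectral_entropy"] <= np.log2(n_bins)


class TestEnergyFeatures:
    def test_constant_ones_closed_form(self):
        seg = np.ones((100, 3))
        np.testing.assert_allclose(energy_features(seg), [300.0, 300.0])

    def test_zeros(self):
        np.testing.assert_array_equal(energy_features(np.zeros((10, 3))), [0.0, 0.0])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_naive_double_loop(self, seed):
        seg = np.random.default_rng(seed).normal(0, 2, (50, 3))
        te, sma = naive_energy(seg.tolist())
        np.testing.assert_allclose(energy_features(seg), [te, sma], atol=1e-9)


class TestExtractFeatures:
    def test_vector_length_and_finiteness(self):
        rng = np.random.default_rng(0)
        vec = extract_features(rng.standard_normal((100, 3)), 100.0)
        assert vec.shape == (N_FEATURES,)
        assert np.all(np.isfinite(vec))
        assert len(FEATURE_NAMES) == N_FEATURES == 33

    def test_canonical_decomposition(self):
        # 18 per-axis + 1 ZCR + 3 correlations + 9 spectral + 2 energy
        per_axis = [n for n in FEATURE_NAMES if n[-2:] in ("_x", "_y", "_z")]
        corr = [n for n in FEATURE_NAMES if n.startswith("corr_")]
        spectral = [n for n in FEATURE_NAMES if "psd" in n or "spectral" in n]
        energy = ["total_energy", "signal_magnitude_area"]
        assert len(per_axis) == 18
        assert len(corr) == 3
        assert len(spectral) == 9
        assert len(energy) == 2
        assert "zero_crossing_rate" in FEATURE_NAMES

    def test_constant_window_degenerate_but_finite(self):
        vec = extract_features(np.full((100, 3), 9.81), 100.0)
        assert np.all(np.isfinite(vec))
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["total_energy"] == pytest.approx(3 * 100 * 9.81**2)

    def test_tremor_windows_separate_from_control(self, small_cohort):
        recs, meta, _ = small_cohort
        recs = preprocess_dataset(recs)
        windows = build_feature_matrix(recs, meta)
        X, y = to_arrays(windows)
        j = FEATURE_NAMES.index("spectral_centroid")
        stat = mannwhitneyu(X[y == 1, j], X[y == 0, j])
        assert stat.pvalue < 1e-3


class TestBuildFeatureMatrix:
    def test_window_count_and_labels(self):
        recs = [
            make_recording(np.random.default_rng(i).standard_normal(250),
                           subject=f"s{i}", call="c0")
            for i in range(2)
        ]
        meta = [SubjectMeta("s0", 1, 1, 0, 0), SubjectMeta("s1", 0, 0, 0, 0)]
        windows = build_feature_matrix(recs, meta)
        assert len(windows) == 8  # 4 windows per 250-sample call, 2 calls
        assert {w.label for w in windows if w.subject_id == "s0"} == {1}
        assert {w.label for w in windows if w.subject_id == "s1"} == {0}

    def test_subject_without_metadata_errors(self):
        recs = [make_recording(np.zeros(100), subject="ghost")]
        with pytest.raises(KeyError, match="ghost"):
            build_feature_matrix(recs, [])

    def test_standardization_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 3, (50, 33))
        Xs, mu, sd = standardize(X)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, atol=1e-9)
        # test data uses train statistics, not its own
        Xt, _, _ = standardize(X + 1.0, mu, sd)
        np.testing.assert_allclose(Xt.mean(axis=0), Xs.mean(axis=0) + 1.0 / np.where(sd == 0, 1, sd), atol=1e-9)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_feature_vector_always_valid(seed):
    rng = np.random.default_rng(seed)
    seg = rng.normal(0, rng.uniform(0.01, 10), (100, 3))
    vec = extract_features(seg, 100.0)
    named = dict(zip(FEATURE_NAMES, vec))
    assert np.all(np.isfinite(vec))
    assert named["total_energy"] >= 0
    assert named["signal_magnitude_area"] >= 0
    assert 0 < named["spectral_flatness"] <= 1.0 + 1e-12
    assert named["spectral_entropy"] >= 0
    assert 0 <= named["zero_crossing_rate"] <= 1
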