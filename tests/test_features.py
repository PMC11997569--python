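import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmfd import features as F
from tests.conftest import make_uniform_window


def dft_oracle(x):
    """Direct O(N^2) summation: X_k = sum_n x_n exp(-2i pi k n / N)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in range(n)])


# ---------------------------------------------------------------------------
# time stats
# ---------------------------------------------------------------------------


def test_time_stats_constant():
    out = F.time_stats(np.full(10, 3.0))
    assert np.allclose(out, [3.0, 0.0, 3.0, 3.0])


def test_time_stats_worked_example():
    # population sd of [1,2,3,4]: sqrt(1.25)
    out = F.time_stats(np.array([1.0, 2.0, 3.0, 4.0]))
    assert out[0] == pytest.approx(2.5)
    assert out[1] == pytest.approx(np.sqrt(1.25))
    assert out[1] == pytest.approx(1.1180, abs=1e-4)


def test_percentile_median():
    out = F.time_stats(np.array([1.0, 2.0, 3.0]), stats=("p50",))
    assert out[0] == pytest.approx(2.0)


def test_time_stats_empty_rejected():
    with pytest.raises(ValueError):
        F.time_stats(np.array([]))


def test_rmssd():
    assert F.rmssd(np.array([1.0, 2.0, 4.0])) == pytest.approx(np.sqrt((1 + 4) / 2))
    assert F.rmssd(np.array([5.0])) == 0.0


# ---------------------------------------------------------------------------
# DFT
# ---------------------------------------------------------------------------


def test_dft_constant_pure_dc():
    X = F.dft(np.full(4, 2.0))
    assert np.allclose(X, [8.0, 0, 0, 0], atol=1e-12)


def test_dft_alternating_tone():
    X = F.dft(np.array([1.0, 0.0, -1.0, 0.0]))
    assert np.allclose(np.abs(X), [0, 2, 0, 2], atol=1e-12)


def test_dft_matches_direct_sum_n17():
    rng = np.random.default_rng(3)
    x = rng.normal(size=17)
    assert np.max(np.abs(F.dft(x) - dft_oracle(x))) < 1e-9


@settings(max_examples=20, deadline=None)
@given(st.integers(2, 64), st.integers(0, 2**32 - 1))
def test_parseval(n, seed):
    x = np.random.default_rng(seed).normal(size=n)
    X = F.dft(x)
    assert np.sum(np.abs(x) ** 2) == pytest.approx(np.sum(np.abs(X) ** 2) / n, abs=1e-9)


# ---------------------------------------------------------------------------
# band powers
# ---------------------------------------------------------------------------


def test_band_powers_pure_tone():
    n, rate = 64, 8.0
    t = np.arange(n) / rate
    x = np.sin(2 * np.pi * 1.0 * t)  # bin 8 of 32 -> normalized 0.25 -> band 0 of 4
    bp = F.band_powers(F.dft(x), rate, 4)
    assert bp[0] > 0
    assert np.allclose(bp[1:], 0.0, atol=1e-18)


def test_band_powers_partition_conservation():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    X = F.dft(x)
    bp = F.band_powers(X, 4.0, 5)
    half = len(x) // 2
    assert bp.sum() == pytest.approx(np.sum(np.abs(X[1 : half + 1]) ** 2))


def test_band_powers_zero_signal():
    assert np.allclose(F.band_powers(F.dft(np.zeros(16)), 4.0, 4), 0.0)


def test_band_powers_too_many_bands():
    with pytest.raises(ValueError):
        F.band_powers(F.dft(np.zeros(8)), 4.0, 10)


# ---------------------------------------------------------------------------
# feature dataset
# ---------------------------------------------------------------------------


def _toy_windows(n=4, label=0, const=None):
    rng = np.random.default_rng(0)
    rates = {"ACC_X": 32.0, "ACC_Y": 32.0, "ACC_Z": 32.0, "EDA": 4.0, "HR": 1.0, "TEMP": 4.0}
    out = []
    for i in range(n):
        chans = {}
        for name, rate in rates.items():
            size = int(rate * 60)
            chans[name] = (
                np.full(size, float(const)) if const is not None else rng.normal(size=size)
            )
        out.append(make_uniform_window(chans, rates, label=label))
    return out


def test_shape_contract():
    ds = F.build_feature_dataset(_toy_windows(), F.FeatureConfig())
    assert ds.X_t.shape == (4, 12, 24)  # 6 channels x 4 stats
    assert ds.X_f.shape == (4, 64, 6)


def test_constant_window_blocks():
    ds = F.build_feature_dataset(_toy_windows(n=2, const=5.0), F.FeatureConfig())
    cols = ds.meta["time_columns"]
    mean_cols = [i for i, c in enumerate(cols) if c.endswith(":mean")]
    sd_cols = [i for i, c in enumerate(cols) if c.endswith(":std")]
    assert np.allclose(ds.X_t[:, :, mean_cols], 5.0)
    assert np.allclose(ds.X_t[:, :, sd_cols], 0.0)
    assert np.allclose(ds.X_f, 0.0, atol=1e-9)  # DC excluded -> empty spectrum


def test_hrv_columns_optional():
    ds = F.build_feature_dataset(_toy_windows(), F.FeatureConfig(include_hrv=True))
    assert ds.X_t.shape[-1] == 26
    assert ds.meta["time_columns"][-2:] == ["HR:hrv_sd", "HR:rmssd"]


def test_row_order_preserved():
    wins = _toy_windows(6)
    ds = F.build_feature_dataset(wins)
    perm = [3, 1, 5, 0, 2, 4]
    ds2 = F.build_feature_dataset([wins[i] for i in perm])
    assert np.allclose(ds2.X_t, ds.X_t[perm])
    assert np.allclose(ds2.X_f, ds.X_f[perm])


def test_freq_separable_pair_time_blocks_agree(default_spec_design):
    """Generator ground truth: freq pair differs in X_f, matches in X_t."""
    from mmfd import synthgen
    from mmfd.preprocess import windows_from_stream

    spec, design = default_spec_design
    spec = synthgen.SynthSpec(
        session_lengths_s=[240.0],
        inter_session_gap_s=spec.inter_session_gap_s,
        channel_rates=dict(spec.channel_rates),
        class_params=spec.class_params,
        noise_sd={ch: 0.0 for ch in spec.channel_rates},  # noise-free draws
        seed=11,
    )
    a, b = design.freq_separable_pair
    wins_a, wins_b = [], []
    for i in range(4):
        wins_a += windows_from_stream(synthgen.generate_recording(spec, f"a{i}", a))
        wins_b += windows_from_stream(synthgen.generate_recording(spec, f"b{i}", b))
    ds = F.build_feature_dataset(wins_a + wins_b, F.FeatureConfig(n_freq_bins=60))
    na = len(wins_a)
    t_gap = np.abs(ds.X_t[:na].mean(axis=(0, 1)) - ds.X_t[na:].mean(axis=(0, 1)))
    pooled = ds.X_t.std(axis=(0, 1)) + 1e-12
    cols = ds.meta["time_columns"]
    ms_cols = [i for i, c in enumerate(cols) if c.endswith((":mean", ":std"))]
    # window-level mean/sd of the freq-separable pair differ by < 0.05 pooled-sd units
    assert np.all(t_gap[ms_cols] / pooled[ms_cols] < 0.05)
    f_gap = np.abs(ds.X_f[:na].mean(0) - ds.X_f[na:].mean(0))
    assert f_gap.max() > 1.0  # spectra differ strongly


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def test_standardize_fit_rows_moments():
    rng = np.random.default_rng(1)
    ds = F.build_feature_dataset(_toy_windows(8))
    fit = np.arange(6)
    out = F.standardize_features(ds, fit)
    assert np.all(np.abs(out.X_t[fit].mean(axis=0)) < 1e-9)
    sds = out.X_t[fit].std(axis=0)
    assert np.all(np.abs(sds - 1.0) < 1e-6)


def test_standardize_constant_feature_zero():
    ds = F.build_feature_dataset(_toy_windows(4, const=2.0))
    out = F.standardize_features(ds, np.arange(4))
    assert np.allclose(out.X_t, 0.0)
    assert np.allclose(out.X_f, 0.0)


def test_standardize_heldout_manual_arithmetic():
    # 3-row toy checked by hand: fit rows {0,1}: means (1+3)/2=2, sd=1
    ds = F.build_feature_dataset(_toy_windows(3))
    ds.X_t[...] = 0.0
    ds.X_t[0, 0, 0] = 1.0
    ds.X_t[1, 0, 0] = 3.0
    ds.X_t[2, 0, 0] = 4.0
    out = F.standardize_features(ds, np.array([0, 1]))
    assert out.X_t[0, 0, 0] == pytest.approx(-1.0)
    assert out.X_t[1, 0, 0] == pytest.approx(1.0)
    assert out.X_t[2, 0, 0] == pytest.approx(2.0)  # (4-2)/1 with training mu, sigma


def test_pipeline_determinism_same_seed(small_windows):
    a = F.standardize_features(F.build_feature_dataset(small_windows), np.arange(5))
    b = F.standardize_features(F.build_feature_dataset(small_windows), np.arange(5))
    assert np.array_equal(a.X_t, b.X_t)
    assert np.array_equal(a.X_f, b.X_f)
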