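import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmfd import signals_io as sio
from mmfd.signals_io import ChannelRegistry, RecordingStream


def _stream(values, rate=1.0, name="EDA", subject="s"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / rate
    return RecordingStream(
        subject=subject, channels={name: (t, values)}, rates={name: rate}
    )


# ---------------------------------------------------------------------------
# min-max scaling
# ---------------------------------------------------------------------------


def test_minmax_endpoints():
    scaled, _ = sio.minmax_scale(_stream([2.0, 4.0, 6.0]))
    assert np.allclose(scaled.channels["EDA"][1], [0.0, 0.5, 1.0])


def test_minmax_constant_channel_warns():
    with pytest.warns(UserWarning, match="constant"):
        scaled, _ = sio.minmax_scale(_stream([5.0, 5.0, 5.0]))
    assert np.allclose(scaled.channels["EDA"][1], 0.5)


def test_minmax_roundtrip_identity():
    rng = np.random.default_rng(0)
    orig = _stream(rng.normal(size=50))
    scaled, scaler = sio.minmax_scale(orig)
    back = scaler.inverse(scaled)
    assert np.allclose(back.channels["EDA"][1], orig.channels["EDA"][1], atol=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
def test_minmax_range_and_monotone(values):
    import warnings

    arr = np.asarray(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # constant channels allowed here
        scaled, _ = sio.minmax_scale(_stream(arr))
    out = scaled.channels["EDA"][1]
    assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)
    order = np.argsort(arr, kind="stable")
    assert np.all(np.diff(out[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def test_resample_upsample_linear():
    grid, vals = sio.resample_channel([0.0, 1.0], [0.0, 2.0], 2.0, "linear_interp")
    assert np.allclose(grid, [0.0, 0.5, 1.0])
    assert np.allclose(vals, [0.0, 1.0, 2.0])


def test_resample_block_mean_constant():
    t = np.arange(64) / 32.0
    grid, vals = sio.resample_channel(t, np.full(64, 7.0), 4.0, "block_mean")
    assert np.allclose(vals, 7.0)


def test_resample_block_mean_tone_averages_out():
    # 0-mean tone, integer periods per block -> block means ~ 0
    rate, f = 32.0, 4.0
    t = np.arange(int(rate * 8)) / rate
    x = np.sin(2 * np.pi * f * t)
    grid, vals = sio.resample_channel(t, x, 1.0, "block_mean")
    # independent oracle: direct per-block averaging
    for i, g in enumerate(grid[:-1]):
        mask = (t >= g) & (t < g + 1.0)
        assert vals[i] == pytest.approx(x[mask].mean(), abs=1e-12)
    assert np.all(np.abs(vals[:-1]) < 1e-10)


def test_resample_errors():
    with pytest.raises(ValueError):
        sio.resample_channel([], [], 1.0)
    with pytest.raises(ValueError):
        sio.resample_channel([0.0, 1.0], [0.0, 1.0], -1.0)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def test_read_wide_toy(tmp_path):
    p = tmp_path / "toy.csv"
    p.write_text("datetime,EDA,HR,label\n0,1.0,60,0\n1,1.5,61,0\n2,2.0,62,0\n")
    streams = sio.read_wide_csv(p)
    assert len(streams) == 1
    s = streams[0]
    assert set(s.channels) == {"EDA", "HR"}
    assert s.n_samples("EDA") == 3 and s.n_samples("HR") == 3
    assert np.allclose(s.channels["EDA"][1], [1.0, 1.5, 2.0])


def test_read_wide_interpolates_missing_cell(tmp_path):
    p = tmp_path / "gap.csv"
    p.write_text("datetime,EDA\n0,1.0\n1,\n2,3.0\n3,4.0\n")
    s = sio.read_wide_csv(p)[0]
    t, v = s.channels["EDA"]
    assert np.allclose(t, [0, 1, 2, 3])
    assert v[1] == pytest.approx(2.0)


def test_read_wide_no_channels_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("datetime,foo\n0,1\n")
    with pytest.raises(ValueError, match="channel"):
        sio.read_wide_csv(p)


def test_wide_roundtrip_multirate(tmp_path, small_streams):
    path = tmp_path / "rt.csv"
    orig = small_streams[0]
    sio.write_wide_csv(path, orig)
    back = sio.read_wide_csv(path)[0]
    assert set(back.channels) == set(orig.channels)
    for name in orig.channels:
        t0, v0 = orig.channels[name]
        t1, v1 = back.channels[name]
        assert len(t0) == len(t1)
        assert np.allclose(v0, v1, atol=1e-9)
        assert np.allclose(t0, t1, atol=1e-9)
    assert np.array_equal(back.labels["EDA"], orig.labels["EDA"])


def test_long_roundtrip(tmp_path, small_streams):
    path = tmp_path / "rt_long.csv"
    sio.write_long_csv(path, small_streams[:2])
    back = sio.read_long_csv(path)
    assert len(back) == 2
    by_subject = {s.subject: s for s in back}
    for orig in small_streams[:2]:
        got = by_subject[orig.subject]
        for name in orig.channels:
            assert np.allclose(got.channels[name][1], orig.channels[name][1], atol=1e-9)


def test_datetime_parsing(tmp_path):
    p = tmp_path / "dt.csv"
    p.write_text(
        "datetime,EDA\n2024-01-01 08:00:00,1.0\n2024-01-01 08:00:01,2.0\n2024-01-01 08:00:02,3.0\n"
    )
    s = sio.read_wide_csv(p)[0]
    assert np.allclose(s.channels["EDA"][0], [0.0, 1.0, 2.0])


def test_registry_aliases():
    reg = ChannelRegistry()
    assert reg.canonical("X") == "ACC_X"
    assert reg.canonical("ST") == "TEMP"
    assert reg.canonical("nope") is None


def test_stream_invariants():
    with pytest.raises(ValueError, match="increasing"):
        RecordingStream("s", {"EDA": (np.array([0.0, 0.0]), np.array([1.0, 2.0]))}, {"EDA": 4.0})
    with pytest.raises(ValueError, match="timestamps vs"):
        RecordingStream("s", {"EDA": (np.array([0.0]), np.array([1.0, 2.0]))}, {"EDA": 4.0})
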