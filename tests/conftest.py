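import numpy as np
import pytest

from mmfd import synthgen
from mmfd.preprocess import Window, windows_from_stream


@pytest.fixture(scope="session")
def default_spec_design():
    return synthgen.default_design()


@pytest.fixture(scope="session")
def small_streams(default_spec_design):
    """Six short streams (2 per class), one 330 s session each."""
    spec, design = default_spec_design
    spec = synthgen.SynthSpec(
        session_lengths_s=[330.0],
        inter_session_gap_s=spec.inter_session_gap_s,
        channel_rates=dict(spec.channel_rates),
        class_params=spec.class_params,
        noise_sd=dict(spec.noise_sd),
        seed=42,
    )
    return synthgen.generate_dataset(spec, design, 2)


@pytest.fixture(scope="session")
def small_windows(small_streams):
    windows = []
    for stream in small_streams:
        windows.extend(windows_from_stream(stream))
    return windows


def make_uniform_window(values_by_channel: dict, rates: dict, label=0, length_s=60.0) -> Window:
    return Window(
        subject="t",
        start_s=0.0,
        length_s=length_s,
        channels={k: np.asarray(v, dtype=float) for k, v in values_by_channel.items()},
        rates=rates,
        label=label,
    )
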