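import numpy as np
import pytest

from arcomp import (
    EEGRecording,
    HeadModel,
    RunConfig,
    build_leadfield,
    default_channel_positions,
)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def leadfield_62(head):
    """Default-geometry lead field: 62 channels, 387 sources."""
    pos, names = default_channel_positions(62, head.outer_radius)
    return build_leadfield(pos, 387, head=head, channel_names=names)


@pytest.fixture(scope="session")
def leadfield_small(head):
    """Cheap lead field for unit tests: 24 channels, 80 sources."""
    pos, names = default_channel_positions(24, head.outer_radius)
    return build_leadfield(pos, 80, head=head, channel_names=names)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=500.0, boundaries=()):
    """Recording with synthetic cap positions for the given data."""
    n_ch = data.shape[0]
    pos, names = default_channel_positions(n_ch)
    return EEGRecording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        channel_positions=pos,
        segment_boundaries=np.asarray(boundaries, dtype=int),
    )


@pytest.fixture
def fast_config():
    """Reduced-size config for pipeline unit tests."""
    return RunConfig(n_sources=80, K_max=3, n_starts=4, max_iter=500, seed=0)
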