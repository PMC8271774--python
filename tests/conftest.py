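import numpy as np
import pytest

from micromotion import LandmarkStream


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def make_stream():
    """Factory for small random landmark streams."""

    def _make(n_frames=50, fps=30.0, seed=0, meta=None):
        r = np.random.default_rng(seed)
        frames = r.uniform(0, 1000, size=(n_frames, 68, 2))
        return LandmarkStream(frames=frames, fps=fps, meta=meta or {})

    return _make
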