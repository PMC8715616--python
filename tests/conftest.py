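import numpy as np
import pytest

from mixclock import FrameSequence, ReactorMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_sequence(frames, interval_s=1.0, fps=None):
    """Build a FrameSequence from a (T, H, W, 3) uint8 array."""
    frames = np.asarray(frames, dtype=np.uint8)
    return FrameSequence(
        frames=frames,
        timestamps_s=np.arange(len(frames), dtype=float) * interval_s,
        source_fps=fps if fps is not None else 1.0 / interval_s,
        source_path="test",
    )


def constant_sequence(n, h, w, rgb):
    """n identical frames of a single color."""
    frame = np.tile(np.asarray(rgb, dtype=np.uint8), (h, w, 1))
    return make_sequence(np.tile(frame, (n, 1, 1, 1)))


def random_mask(rng, h, w, p=0.4):
    """Random boolean mask with at least two true pixels."""
    mask = rng.random((h, w)) < p
    if mask.sum() < 2:
        mask.flat[:2] = True
    return ReactorMask(mask)
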