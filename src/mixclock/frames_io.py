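"""Frame-sequence I/O: decode videos / frame directories, write frame stacks.

A mixing video is reduced to a :class:`FrameSequence`: an ordered stack of
equally sized 8-bit RGB frames with timestamps relative to the first sampled
frame.  Sampling is tick-based — for a requested rate ``r`` the ticks are
``0, 1/r, 2/r, …`` and the temporally nearest decoded frame is kept for each
tick — so non-integer ratios between the source frame rate and the sampling
rate behave predictably.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError, ParameterError

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


def _as_rgb8(arr: np.ndarray, origin: str) -> np.ndarray:
    """Coerce a decoded image to H×W×3 uint8 (drop alpha, expand grey)."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = np.stack([a, a, a], axis=-1)
    if a.ndim != 3 or a.shape[-1] not in (3, 4):
        raise FormatError(f"{origin}: expected greyscale/RGB/RGBA image, got shape {a.shape}")
    if a.shape[-1] == 4:
        a = a[..., :3]
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a.astype(np.float64)), 0, 255).astype(np.uint8)
    return a


@dataclass
class FrameSequence:
    """Ordered, timestamped stack of equally sized 8-bit RGB frames.

    ``frames`` is a (T, H, W, 3) uint8 array; ``timestamps_s`` holds seconds
    relative to the first sampled frame (``timestamps_s[0] == 0``).
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    source_fps: float | None = None
    source_path: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise FormatError(
                f"frames must be (T, H, W, 3); got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise FormatError(f"frames must be uint8; got {self.frames.dtype}")
        if len(self.frames) != len(self.timestamps_s) or len(self.frames) < 1:
            raise FormatError("need >= 1 frame with one timestamp per frame")
        if self.timestamps_s[0] != 0.0:
            raise FormatError("timestamps_s[0] must be 0")
        if len(self.timestamps_s) > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise FormatError("timestamps_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1])


def _source_fps_from_meta(meta: dict) -> float | None:
    fps = meta.get("fps")
    if fps:
        return float(fps)
    # GIF and friends report per-frame duration in milliseconds
    dur_ms = meta.get("duration")
    if dur_ms:
        return 1000.0 / float(dur_ms)
    return None


def extract_frames(
    video_path: str | Path,
    sample_rate_hz: float,
    source_fps: float | None = None,
) -> FrameSequence:
    """Decode a video and sample it at ``sample_rate_hz``.

    Frames are taken at ticks ``t = 0, 1/rate, 2/rate, …`` up to the source
    duration; for each tick the temporally nearest decoded frame is selected
    and the tick time (not the source frame time) is recorded.  ``source_fps``
    overrides (or supplies, for containers without rate metadata) the source
    frame rate.
    """
    path = Path(video_path)
    if not path.is_file():
        raise InputError(f"video file not found: {path}")
    if sample_rate_hz <= 0:
        raise ParameterError(f"sample_rate_hz must be > 0, got {sample_rate_hz}")
    try:
        raw = iio.imread(path, index=None)
    except Exception as exc:  # decoder-specific failure
        raise InputError(f"cannot decode {path}: {exc}") from exc
    if source_fps is None:
        try:
            source_fps = _source_fps_from_meta(iio.immeta(path))
        except Exception:
            source_fps = None
    if source_fps is None:
        raise InputError(
            f"{path}: no frame-rate metadata found; pass source_fps explicitly"
        )
    if source_fps <= 0:
        raise ParameterError(f"source_fps must be > 0, got {source_fps}")
    if sample_rate_hz > source_fps * (1 + 1e-9):
        raise ParameterError(
            f"sample_rate_hz ({sample_rate_hz}) exceeds source fps ({source_fps})"
        )

    frames = np.stack([_as_rgb8(f, str(path)) for f in np.asarray(raw)])
    n_src = len(frames)
    duration = (n_src - 1) / source_fps
    n_ticks = int(np.floor(duration * sample_rate_hz + 1e-9)) + 1
    ticks = np.arange(n_ticks, dtype=np.float64) / sample_rate_hz
    nearest = np.clip(np.rint(ticks * source_fps).astype(int), 0, n_src - 1)
    return FrameSequence(
        frames=frames[nearest],
        timestamps_s=ticks,
        source_fps=float(source_fps),
        source_path=str(path),
        meta={"sample_rate_hz": float(sample_rate_hz), "source_frames": n_src},
    )


def load_frame_dir(dir_path: str | Path, interval_s: float) -> FrameSequence:
    """Load a directory of frame images (lexicographic = temporal order).

    Timestamps are ``0, interval_s, 2*interval_s, …``.
    """
    path = Path(dir_path)
    if not path.is_dir():
        raise InputError(f"not a directory: {path}")
    if interval_s <= 0:
        raise ParameterError(f"interval_s must be > 0, got {interval_s}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
    )
    if not files:
        raise InputError(f"no image files in {path}")
    frames = [_as_rgb8(iio.imread(p), str(p)) for p in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
    return FrameSequence(
        frames=np.stack(frames),
        timestamps_s=np.arange(len(frames), dtype=np.float64) * interval_s,
        source_fps=1.0 / interval_s,
        source_path=str(path),
        meta={"files": [f.name for f in files]},
    )


def write_frames(seq: FrameSequence, dir_path: str | Path) -> int:
    """Write one PNG per frame (zero-padded indices); returns files written.

    The round trip through :func:`load_frame_dir` is pixel-exact.
    """
    path = Path(dir_path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(len(seq) - 1)))
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)
    except OSError as exc:
        raise InputError(f"cannot write frames to {path}: {exc}") from exc
    return len(seq)


def natural_interval(seq: FrameSequence) -> float:
    """Median inter-frame interval of a sequence, in seconds."""
    if len(seq) < 2:
        raise InputError("need >= 2 frames to infer an interval")
    return float(np.median(np.diff(seq.timestamps_s)))
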