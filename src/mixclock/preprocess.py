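"""Cropping, reactor segmentation and value-channel conversion.

The optical method needs three preparation steps before the heterogeneity
statistic can be computed: crop each frame to the reactor and a small border,
decide which pixels belong to the reactor (the background must not enter the
statistic), and collapse color to a single intensity.  The greyscale used is
the HSV "value" pseudochannel — per pixel the maximum of R, G and B — which
discards hue/saturation while keeping intensity contrast.

Background removal is deterministic here.  Three methods are provided:

``reference_diff``
    Pixels whose RGB Euclidean distance from a pre-tracer reference frame
    exceeds a threshold in *any* frame.  The dye only ever appears inside the
    reactor, so the union of changed pixels outlines it.  Default method.
``luminance_threshold``
    Pixels darker than a cutoff on the value channel of a chosen frame;
    appropriate when the reactor stands in front of a white backdrop.
``explicit``
    A user-supplied binary mask image, validated and passed through.

For the first two methods the raw mask is post-processed by keeping the
largest 4-connected component and filling its holes, so the statistic is
always taken over one contiguous reactor region of stable pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import FormatError, ParameterError, SegmentationError
from .frames_io import FrameSequence

#: Luma (Rec. 709) weights for the optional alternative greyscale.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class Roi:
    """Axis-aligned region of interest; 0-based, top-left origin, half-open."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ParameterError(f"Roi needs width/height >= 1, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ParameterError(f"Roi offsets must be >= 0, got {self}")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height


@dataclass
class ReactorMask:
    """Boolean pixel grid: True = reactor pixel included in the statistic."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {self.mask.shape}")
        if self.n_true < 2:
            raise SegmentationError(
                f"mask covers {self.n_true} pixel(s); need >= 2 for a spatial SD"
            )

    @property
    def n_true(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def crop(self, roi: Roi) -> "ReactorMask":
        _check_roi_bounds(roi, self.shape)
        return ReactorMask(self.mask[roi.y0 : roi.y1, roi.x0 : roi.x1])


@dataclass
class GreyFrame:
    """Single-channel intensity grid in [0, 255] (float64)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FormatError(f"grey frame must be 2-D, got {self.values.shape}")


def _check_roi_bounds(roi: Roi, shape: tuple[int, int]) -> None:
    h, w = shape
    if roi.x1 > w or roi.y1 > h:
        raise ParameterError(
            f"Roi {roi} exceeds frame bounds (height {h}, width {w})"
        )


def crop(seq: FrameSequence, roi: Roi) -> FrameSequence:
    """Crop every frame identically to ``roi``; timestamps unchanged."""
    _check_roi_bounds(roi, seq.frame_shape)
    return FrameSequence(
        frames=seq.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1, :].copy(),
        timestamps_s=seq.timestamps_s.copy(),
        source_fps=seq.source_fps,
        source_path=seq.source_path,
        meta={**seq.meta, "crop_roi": (roi.x0, roi.y0, roi.width, roi.height)},
    )


def to_value_channel(frame: np.ndarray, mode: str = "value") -> GreyFrame:
    """Collapse an RGB frame to greyscale.

    ``mode="value"`` (default) takes the per-pixel channel maximum — the HSV
    "value" pseudochannel.  ``mode="luma"`` uses Rec. 709 weights and rounds;
    it spreads contrast better when dye and liquid share a bright channel.
    """
    a = np.asarray(frame)
    if a.ndim != 3 or a.shape[-1] != 3:
        raise FormatError(f"expected H×W×3 frame, got shape {a.shape}")
    if mode == "value":
        return GreyFrame(a.max(axis=-1).astype(np.float64))
    if mode == "luma":
        return GreyFrame(np.rint(a.astype(np.float64) @ _LUMA_WEIGHTS))
    raise ParameterError(f"unknown greyscale mode: {mode!r}")


def _postprocess(raw: np.ndarray, method: str) -> ReactorMask:
    """Largest 4-connected component + hole filling."""
    if not raw.any():
        raise SegmentationError(
            f"{method}: empty mask — threshold too strict for this sequence"
        )
    labels, n = ndimage.label(raw)  # default structure = 4-connectivity
    largest = 1 + int(np.argmax(ndimage.sum_labels(raw, labels, range(1, n + 1))))
    mask = ndimage.binary_fill_holes(labels == largest)
    if mask.sum() < 2:
        raise SegmentationError(
            f"{method}: largest component has {int(mask.sum())} pixel(s)"
        )
    return ReactorMask(mask)


def segment_reactor(
    seq: FrameSequence,
    method: str = "reference_diff",
    *,
    ref_index: int = 0,
    threshold: float = 30.0,
    cutoff: float = 240.0,
    frame_index: int = 0,
    mask_path: str | Path | None = None,
    mask: np.ndarray | None = None,
) -> ReactorMask:
    """Compute a single reactor mask applied to all frames.

    Parameters depend on ``method``: ``reference_diff`` uses ``ref_index``
    (pre-tracer reference frame) and ``threshold`` (RGB Euclidean distance,
    of 255·√3 max); ``luminance_threshold`` uses ``cutoff`` on the value
    channel of frame ``frame_index``; ``explicit`` takes ``mask`` (boolean
    array) or ``mask_path`` (PNG, nonzero = reactor).
    """
    h, w = seq.frame_shape
    if method == "reference_diff":
        if not 0 <= ref_index < len(seq):
            raise ParameterError(f"ref_index {ref_index} out of range")
        ref = seq.frames[ref_index].astype(np.float64)
        diff = seq.frames.astype(np.float64) - ref[None]
        dist = np.sqrt((diff * diff).sum(axis=-1))
        raw = (dist > threshold).any(axis=0)
        return _postprocess(raw, method)
    if method == "luminance_threshold":
        if not 0 <= frame_index < len(seq):
            raise ParameterError(f"frame_index {frame_index} out of range")
        grey = to_value_channel(seq.frames[frame_index]).values
        return _postprocess(grey < cutoff, method)
    if method == "explicit":
        if mask is None and mask_path is None:
            raise ParameterError("explicit method needs mask or mask_path")
        if mask is None:
            mask = read_mask(mask_path).mask
        m = np.asarray(mask, dtype=bool)
        if m.shape != (h, w):
            raise FormatError(
                f"explicit mask shape {m.shape} != frame shape {(h, w)}"
            )
        return ReactorMask(m)
    raise ParameterError(f"unknown segmentation method: {method!r}")


def read_mask(path: str | Path) -> ReactorMask:
    """Read a mask image (any nonzero pixel = reactor)."""
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return ReactorMask(img > 0)


def write_mask(rmask: ReactorMask, path: str | Path) -> None:
    """Write a mask as single-channel PNG (0 = background, 255 = reactor)."""
    iio.imwrite(Path(path), (rmask.mask.astype(np.uint8)) * 255)
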