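"""Pixel-to-pixel heterogeneity: the optical tracer signal.

While dye disperses through the reactor, some pixels are dark and some are
bright, so the spatial spread of intensities is large; before addition and
after complete mixing the liquid is uniform and the spread is minimal.  The
spread is quantified per frame as the population standard deviation of the
value-channel intensities over the reactor mask, giving a scalar trace whose
decay tracks homogenization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateMaskError, FormatError
from .frames_io import FrameSequence
from .preprocess import GreyFrame, ReactorMask, to_value_channel


@dataclass
class Trace:
    """Timestamped scalar signal: optical SD per frame, or pH per reading."""

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "optical_sd"  # "optical_sd" | "ph"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise FormatError("times_s and values must be equal-length 1-D")
        if len(self.times_s) < 2:
            raise FormatError("a trace needs >= 2 samples")
        if not np.all(np.diff(self.times_s) > 0):
            raise FormatError("times_s must be strictly increasing")
        if self.kind == "optical_sd" and np.any(self.values < 0):
            raise FormatError("optical_sd values must be >= 0")

    def __len__(self) -> int:
        return len(self.times_s)


def pixel_sd(grey: GreyFrame | np.ndarray, mask: ReactorMask) -> float:
    """Population standard deviation of grey values at mask-true pixels.

    Pixels outside the mask have no influence.  Accumulation is in double
    precision on mean-shifted values, so the result matches a two-pass
    mean/variance computation to ~1e-9 relative even for large masks.
    """
    values = grey.values if isinstance(grey, GreyFrame) else np.asarray(grey)
    if values.shape != mask.shape:
        raise FormatError(
            f"grey frame shape {values.shape} != mask shape {mask.shape}"
        )
    if mask.n_true < 2:
        raise DegenerateMaskError(f"mask covers {mask.n_true} pixel(s)")
    v = values[mask.mask].astype(np.float64)
    # two-pass, mean-shifted: numerically stable for 8-bit-scale data
    centered = v - v.mean()
    return float(np.sqrt((centered * centered).mean()))


def compute_trace(
    seq: FrameSequence, mask: ReactorMask, grey_mode: str = "value"
) -> Trace:
    """Per-frame masked pixel SD of the greyscale sequence."""
    if mask.shape != seq.frame_shape:
        raise FormatError(
            f"mask shape {mask.shape} != frame shape {seq.frame_shape}"
        )
    sds = [
        pixel_sd(to_value_channel(frame, grey_mode), mask) for frame in seq.frames
    ]
    return Trace(
        times_s=seq.timestamps_s.copy(),
        values=np.array(sds),
        kind="optical_sd",
        meta={
            "mask_pixels": mask.n_true,
            "grey_mode": grey_mode,
            "source": seq.source_path,
        },
    )


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as 2-column CSV with a ``#``-commented meta header."""
    path = Path(path)
    header = "# " + json.dumps({"kind": trace.kind, **trace.meta}, default=str)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.times_s, trace.values):
            fh.write(f"{t:.6g},{v:.10g}\n")


def read_trace(path: str | Path, kind: str | None = None) -> Trace:
    """Read a 2-column (time_s, value) CSV, tolerating ``#`` comments."""
    path = Path(path)
    meta: dict = {}
    try:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            try:
                meta = json.loads(first.lstrip("# "))
            except json.JSONDecodeError:
                meta = {}
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError as exc:
        raise FormatError(f"trace file not found: {path}") from exc
    except Exception as exc:
        raise FormatError(f"cannot parse trace CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: need two columns (time_s, value), got {df.shape[1]}"
        )
    if df.shape[0] < 2:
        raise FormatError(f"{path}: need >= 2 rows, got {df.shape[0]}")
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.isnan(times).any() or np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric entries in time/value columns")
    if kind is None:
        kind = meta.get("kind", "optical_sd")
    return Trace(times_s=times, values=values, kind=kind, meta=meta)
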