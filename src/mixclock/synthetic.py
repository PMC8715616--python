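"""Synthetic bubble-column mixing videos and pH traces with known truth.

The generator stands in for the physical experiment: a vertical column of
liquid in front of a white backdrop, a dye pulse added at the top at a known
time, and homogenization that reaches the column bottom last.  It is built
for testability rather than hydrodynamic realism — no bubbles, refraction or
camera model — but reproduces the phenomenology the optical method relies
on: the pixel-SD trace is minimal before addition, high while the dye is
partly distributed, and minimal again after complete mixing.

Concentration model
-------------------
The column is discretized into rows.  Before ``t_add_s`` the concentration
is 0 everywhere.  At ``t_add_s`` the top 10% of rows is set to c = 1
(the pulse); every row then relaxes exponentially toward the column mean
c̄ (the conserved average):

    c(y, t) = c̄ + (c(y, t_add) − c̄) · exp(−r(y) · (t − t_add) / tau_s)

with the rate factor r(y) interpolating linearly from 1 at the top row to
``gradient`` at the bottom row.  ``gradient = 1`` mixes uniformly and gives
a closed-form SD decay; ``gradient < 1`` makes the bottom mix last.

Rendering maps concentration linearly from ``clear_rgb`` to ``dye_rgb``
inside the column, leaves the background untouched (so reference-frame
segmentation is exact), adds seeded Gaussian pixel noise inside the column,
and quantizes to 8 bits.

Ground truth
------------
:func:`ground_truth_mixing_time` evaluates the expected value-channel SD
trace of the rendering directly from the row concentrations — without
rendering any pixels — and scans it with the same band/criterion convention
as the analysis.  For a noiseless rendering the 8-bit quantization of the
row intensities is reproduced exactly (quantization visibly staircases the
SD of a few-level field, shifting the band crossing — ``quantize=False``
returns the idealized continuous-intensity answer instead).  With noise,
quantization acts as a dither and the noise floor and quantization variance
(sd² + 1/12) add in quadrature to the spatial signal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import MixclockError, ParameterError
from .frames_io import FrameSequence
from .heterogeneity import Trace
from .preprocess import Roi

QUANT_VAR = 1.0 / 12.0  # variance of uniform rounding error, dithered case


@dataclass(frozen=True)
class SyntheticMixingConfig:
    """Full parameterization of the synthetic mixing-video generator."""

    frame_w: int = 120
    frame_h: int = 320
    column_roi: Roi | None = None  # default: centered column, 90% height
    background_rgb: tuple[int, int, int] = (255, 255, 255)
    clear_rgb: tuple[int, int, int] = (235, 235, 235)
    dye_rgb: tuple[int, int, int] = (70, 70, 200)
    tau_s: float = 8.0
    gradient: float = 1.0
    t_add_s: float = 5.0
    duration_s: float = 60.0
    fps: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    top_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.column_roi is None:
            w = max(2, self.frame_w // 3)
            h = max(2, int(self.frame_h * 0.9))
            roi = Roi((self.frame_w - w) // 2, (self.frame_h - h) // 2, w, h)
            object.__setattr__(self, "column_roi", roi)
        r = self.column_roi
        if r.x1 > self.frame_w or r.y1 > self.frame_h:
            raise ParameterError(f"column_roi {r} exceeds frame bounds")
        if self.tau_s <= 0:
            raise ParameterError(f"tau_s must be > 0, got {self.tau_s}")
        if not 0 < self.gradient <= 1:
            raise ParameterError(f"gradient must be in (0, 1], got {self.gradient}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.t_add_s < self.duration_s:
            raise ParameterError("need 0 <= t_add_s < duration_s")
        if self.fps <= 0:
            raise ParameterError(f"fps must be > 0, got {self.fps}")
        if not 0 < self.top_fraction < 1:
            raise ParameterError(f"top_fraction must be in (0, 1)")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s * self.fps - 1e-9)) + 1

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=np.float64) / self.fps

    @property
    def n_top_rows(self) -> int:
        return max(1, int(round(self.top_fraction * self.column_roi.height)))

    @property
    def c_mean(self) -> float:
        """Conserved column-mean concentration (pulse mass / column height)."""
        return self.n_top_rows / self.column_roi.height


def row_concentration(
    config: SyntheticMixingConfig, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise concentration profiles: returns (times, c of shape (T, h)).

    The field is laterally uniform, so rows fully determine every frame.
    """
    if times is None:
        times = config.frame_times
    times = np.asarray(times, dtype=np.float64)
    h = config.column_roi.height
    y = np.arange(h, dtype=np.float64)
    rate = 1.0 + (config.gradient - 1.0) * (y / max(h - 1, 1))
    c0 = np.zeros(h)
    c0[: config.n_top_rows] = 1.0
    cbar = config.c_mean
    dt = np.maximum(times[:, None] - config.t_add_s, 0.0)
    c = cbar + (c0[None, :] - cbar) * np.exp(-rate[None, :] * dt / config.tau_s)
    c[times < config.t_add_s, :] = 0.0
    return times, np.clip(c, 0.0, 1.0)


def simulate_concentration(
    config: SyntheticMixingConfig, times: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration fields over the column region: (times, c of (T, h, w))."""
    times, rows = row_concentration(config, times)
    return times, np.repeat(
        rows[:, :, None], config.column_roi.width, axis=2
    )


def _row_colors(config: SyntheticMixingConfig, c_rows: np.ndarray) -> np.ndarray:
    """Float RGB per row: clear + c·(dye − clear); shape (..., 3)."""
    clear = np.asarray(config.clear_rgb, dtype=np.float64)
    dye = np.asarray(config.dye_rgb, dtype=np.float64)
    return clear[None] + c_rows[..., None] * (dye - clear)[None]


def render_frames(
    fields: np.ndarray, config: SyntheticMixingConfig
) -> FrameSequence:
    """Render concentration fields to an 8-bit RGB frame sequence.

    Background pixels are constant across frames; Gaussian pixel noise
    (seeded) is added inside the column only, then values are rounded and
    clipped to [0, 255].
    """
    fields = np.asarray(fields, dtype=np.float64)
    roi = config.column_roi
    t_n = fields.shape[0]
    if fields.shape[1:] != (roi.height, roi.width):
        raise ParameterError(
            f"fields shape {fields.shape[1:]} != column_roi {roi.height, roi.width}"
        )
    rng = np.random.default_rng(config.seed)
    frames = np.empty((t_n, config.frame_h, config.frame_w, 3), dtype=np.uint8)
    frames[:] = np.asarray(config.background_rgb, dtype=np.uint8)
    column = _row_colors(config, fields)  # (T, h, w, 3)
    if config.noise_sd > 0:
        column = column + rng.normal(0.0, config.noise_sd, column.shape)
    frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1, :] = np.clip(
        np.rint(column), 0, 255
    ).astype(np.uint8)
    return FrameSequence(
        frames=frames,
        timestamps_s=config.frame_times[:t_n],
        source_fps=config.fps,
        source_path=f"synthetic(seed={config.seed})",
        meta={"synthetic": True, "seed": config.seed, "tau_s": config.tau_s},
    )


def generate_mixing_video(config: SyntheticMixingConfig) -> FrameSequence:
    """Simulate and render in one step."""
    _, fields = simulate_concentration(config)
    return render_frames(fields, config)


def expected_sd_trace(
    config: SyntheticMixingConfig,
    times: np.ndarray | None = None,
    quantize: bool = True,
) -> Trace:
    """Expected value-channel pixel SD over the column, per frame.

    Computed from the row concentrations alone.  Noiseless + quantize:
    exact SD of the rounded row intensities.  With noise: spatial variance,
    noise variance and (if quantize) dithered quantization variance add in
    quadrature.
    """
    times, rows = row_concentration(config, times)
    v = _row_colors(config, rows).max(axis=-1)  # value channel, (T, h)
    if config.noise_sd == 0 and quantize:
        v = np.rint(v)
        sd = v.std(axis=1)
    else:
        var = v.var(axis=1) + config.noise_sd**2
        if quantize:
            var = var + QUANT_VAR
        sd = np.sqrt(var)
    return Trace(
        times_s=times,
        values=sd,
        kind="optical_sd",
        meta={"synthetic": True, "model": "expected_sd", "quantize": quantize},
    )


def _scan_band_crossing(
    trace: Trace,
    t_add_s: float,
    tolerance: float,
    band_mode: str,
    n_last: int,
    criterion: str,
) -> float | None:
    """Brute-force band scan, independent of the analysis implementation."""
    f = float(np.mean(trace.values[-n_last:]))
    after = [i for i, t in enumerate(trace.times_s) if t >= t_add_s]
    if band_mode == "relative_final":
        half = tolerance * abs(f)
    else:
        half = tolerance * (max(trace.values[i] for i in after) - f)
    if half <= 0:
        raise DegenerateTruthBand(f)
    lo, hi = f - half, f + half
    if criterion == "first_cross":
        for i in after:
            if lo <= trace.values[i] <= hi:
                return float(trace.times_s[i]) - t_add_s
        return None
    for j, i in enumerate(after):
        if all(lo <= trace.values[q] <= hi for q in after[j:]):
            return float(trace.times_s[i]) - t_add_s
    return None


class DegenerateTruthBand(Exception):
    """Internal: relative_final band collapsed (final SD is 0)."""

    def __init__(self, final: float):
        self.final = final


def ground_truth_mixing_time(
    config: SyntheticMixingConfig,
    tolerance: float = 0.05,
    band_mode: str = "relative_range",
    n_last: int = 15,
    criterion: str = "stay",
    sample_rate_hz: float | None = None,
    quantize: bool = True,
) -> float:
    """Analytic mixing time of the expected SD trace of the rendering.

    The oracle is the expectation of the measured statistic: for a noisy
    rendering the configured noise floor enters the trace (and hence the
    band anchored at the last-``n_last`` mean) exactly as it does in the
    measurement, so the analytic answer is what an ideal analysis of the
    configured video recovers — not the answer for a different, noise-free
    experiment.  Evaluated on the sampling grid (default: the configured
    frame rate), so the result is already rounded up to the grid.  Under
    ``relative_final`` with a zero final SD the band collapses; the
    ``relative_range`` answer is returned with a warning in that case.
    """
    cfg = config
    rate = sample_rate_hz if sample_rate_hz is not None else cfg.fps
    n = int(np.floor(cfg.duration_s * rate - 1e-9)) + 1
    times = np.arange(n, dtype=np.float64) / rate
    trace = expected_sd_trace(cfg, times, quantize=quantize)
    try:
        t_mix = _scan_band_crossing(
            trace, cfg.t_add_s, tolerance, band_mode, n_last, criterion
        )
    except DegenerateTruthBand:
        warnings.warn(
            "final SD is 0: relative_final band is degenerate; "
            "returning the relative_range answer",
            stacklevel=2,
        )
        t_mix = _scan_band_crossing(
            trace, cfg.t_add_s, tolerance, "relative_range", n_last, criterion
        )
    if t_mix is None:
        raise MixclockError(
            "ground-truth criterion not reached within duration_s; "
            "increase duration_s"
        )
    return t_mix


def simulate_ph_trace(
    ph0: float = 7.0,
    ph_inf: float = 9.0,
    tau_s: float = 8.0,
    t_add_s: float = 6.0,
    interval_s: float = 3.0,
    duration_s: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Trace:
    """First-order pH step response to an alkaline tracer pulse.

    pH(t) = ph0 before addition, then ph_inf + (ph0 − ph_inf)·exp(−Δt/tau_s),
    plus seeded Gaussian readout noise; sampled every ``interval_s`` seconds
    (probe logging interval, default 3 s).
    """
    if tau_s <= 0:
        raise ParameterError(f"tau_s must be > 0, got {tau_s}")
    if interval_s <= 0:
        raise ParameterError(f"interval_s must be > 0, got {interval_s}")
    if not 0 <= t_add_s < duration_s:
        raise ParameterError("need 0 <= t_add_s < duration_s")
    n = int(np.floor(duration_s / interval_s + 1e-9)) + 1
    times = np.arange(n, dtype=np.float64) * interval_s
    dt = np.maximum(times - t_add_s, 0.0)
    ph = ph_inf + (ph0 - ph_inf) * np.exp(-dt / tau_s)
    ph[times < t_add_s] = ph0
    if noise_sd > 0:
        ph = ph + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return Trace(
        times_s=times,
        values=ph,
        kind="ph",
        meta={"synthetic": True, "seed": seed, "tau_s": tau_s, "t_add_s": t_add_s},
    )
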