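"""Mixing-time determination from a tracer trace.

Works identically for the optical pixel-SD signal and for a pH-probe log.
The mixing time is the time from tracer addition until the signal reaches
(and, by default, stays within) ±5% of its final stable value, the final
stable value being the mean of the last 15 samples.

Two ambiguities in that recipe are made explicit:

* ``criterion`` — ``"stay"`` (default) requires the signal to remain inside
  the band from the crossing to the end of the trace, which is what "signal
  stability" means for an oscillating SD trace; ``"first_cross"`` takes the
  first in-band sample.  They coincide on monotone traces.
* ``band_mode`` — ``"relative_final"`` (default) sets the band to
  F ± tol·|F|.  For the optical SD the final value approaches zero and the
  band degenerates; ``"relative_range"`` (F ± tol·(max − F), max taken after
  addition) is the usable variant there, and the degenerate-band error says
  so rather than switching silently.

Times are reported on the trace's sampling grid; no sub-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateBandError, DetectionError, InputError
from .heterogeneity import Trace, read_trace

DEFAULT_TOLERANCE = 0.05
DEFAULT_N_LAST = 15


@dataclass
class MixingTimeResult:
    """Outcome of the ±tolerance stability criterion on one trace."""

    t_add_s: float
    t_mix_s: float | None
    final_value: float
    band_low: float
    band_high: float
    tolerance: float
    n_last: int
    criterion: str
    band_mode: str
    converged: bool

    def as_dict(self) -> dict:
        return {
            "t_add_s": self.t_add_s,
            "t_mix_s": self.t_mix_s,
            "final_value": self.final_value,
            "band_low": self.band_low,
            "band_high": self.band_high,
            "tolerance": self.tolerance,
            "n_last": self.n_last,
            "criterion": self.criterion,
            "band_mode": self.band_mode,
            "converged": self.converged,
        }


def final_value(trace: Trace, n_last: int = DEFAULT_N_LAST) -> float:
    """Mean of the last ``n_last`` samples — the final stable value."""
    if n_last < 1:
        raise InputError(f"n_last must be >= 1, got {n_last}")
    if len(trace) < n_last:
        raise InputError(
            f"trace has {len(trace)} samples, fewer than n_last={n_last}"
        )
    return float(np.mean(trace.values[-n_last:]))


def detect_tracer_addition(
    trace: Trace,
    baseline_n: int = 10,
    k: float = 5.0,
    m: int = 3,
    eps: float = 1e-6,
) -> float:
    """Detect the tracer-addition time from the signal itself.

    Baseline mean and SD are taken over the first ``baseline_n`` samples;
    the addition time is the time of the first sample that begins a run of
    ``m`` consecutive samples deviating from the baseline mean by more than
    ``k * max(baseline SD, eps)``.  When addition was logged manually, pass
    that time to :func:`mixing_time` directly instead.
    """
    if len(trace) <= baseline_n + m:
        raise InputError(
            f"trace too short ({len(trace)}) for baseline_n={baseline_n}, m={m}"
        )
    v = trace.values
    mu0 = float(np.mean(v[:baseline_n]))
    sd0 = float(np.std(v[:baseline_n]))
    thresh = k * max(sd0, eps)
    dev = np.abs(v - mu0) > thresh
    for i in range(baseline_n, len(v) - m + 1):
        if dev[i : i + m].all():
            return float(trace.times_s[i])
    raise DetectionError(
        "no run of deviating samples found; supply the addition time manually"
    )


def mixing_time(
    trace: Trace,
    t_add_s: float,
    tolerance: float = DEFAULT_TOLERANCE,
    n_last: int = DEFAULT_N_LAST,
    criterion: str = "stay",
    band_mode: str = "relative_final",
) -> MixingTimeResult:
    """Apply the ±tolerance stability criterion; see module docstring."""
    if not 0 < tolerance < 1:
        raise InputError(f"tolerance must be in (0, 1), got {tolerance}")
    if criterion not in ("stay", "first_cross"):
        raise InputError(f"unknown criterion: {criterion!r}")
    if band_mode not in ("relative_final", "relative_range"):
        raise InputError(f"unknown band_mode: {band_mode!r}")
    t = trace.times_s
    if not t[0] <= t_add_s <= t[-1]:
        raise InputError(
            f"t_add_s={t_add_s} outside trace span [{t[0]}, {t[-1]}]"
        )
    f = final_value(trace, n_last)
    after = t >= t_add_s
    if band_mode == "relative_final":
        half = tolerance * abs(f)
    else:
        half = tolerance * (float(np.max(trace.values[after])) - f)
    if half <= 0:
        raise DegenerateBandError(
            f"band width is 0 under band_mode={band_mode!r} (final value {f:g}); "
            "for a signal that decays to zero use band_mode='relative_range'"
        )
    band_low, band_high = f - half, f + half

    idx = np.nonzero(after)[0]
    in_band = (trace.values >= band_low) & (trace.values <= band_high)
    t_end: float | None = None
    if criterion == "first_cross":
        hits = idx[in_band[idx]]
        if hits.size:
            t_end = float(t[hits[0]])
    else:  # stay: earliest sample from which the signal never leaves the band
        if in_band[idx].all() and idx.size:
            t_end = float(t[idx[0]])
        else:
            out = idx[~in_band[idx]]
            if out.size and out[-1] + 1 < len(t):
                t_end = float(t[out[-1] + 1])
    converged = t_end is not None
    return MixingTimeResult(
        t_add_s=float(t_add_s),
        t_mix_s=(t_end - t_add_s) if converged else None,
        final_value=f,
        band_low=band_low,
        band_high=band_high,
        tolerance=tolerance,
        n_last=n_last,
        criterion=criterion,
        band_mode=band_mode,
        converged=converged,
    )


def analyze_ph_csv(
    path: str | Path,
    t_add_s: float | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    n_last: int = DEFAULT_N_LAST,
    criterion: str = "stay",
    band_mode: str = "relative_final",
    baseline_n: int = 10,
) -> MixingTimeResult:
    """Mixing time from a pH-probe CSV (time_s, pH).

    Composes tracer-addition detection (unless ``t_add_s`` is given) with
    the stability criterion at its pH-method defaults: tolerance 0.05 and a
    final stable value over the last 15 readings.
    """
    trace = read_trace(path, kind="ph")
    if t_add_s is None:
        t_add_s = detect_tracer_addition(trace, baseline_n=baseline_n)
    return mixing_time(
        trace,
        t_add_s,
        tolerance=tolerance,
        n_last=n_last,
        criterion=criterion,
        band_mode=band_mode,
    )
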