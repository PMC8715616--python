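"""End-to-end pipelines: video → mixing time, pH CSV → mixing time.

Each run persists every intermediate (frames, mask, trace CSV, result CSV,
diagnostic plot) plus a machine-readable provenance record of all inputs
and parameters, so a run can be reproduced exactly from its output
directory.  These functions are the library face of the CLI's ``run-video``
and ``run-ph`` commands.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from . import __version__
from .errors import MixclockError, ParameterError
from .frames_io import FrameSequence, extract_frames, load_frame_dir, write_frames
from .heterogeneity import Trace, compute_trace, write_trace
from .preprocess import Roi, crop, segment_reactor, write_mask
from .tracer_analysis import (
    MixingTimeResult,
    analyze_ph_csv,
    detect_tracer_addition,
    mixing_time,
)

log = logging.getLogger("mixclock")


def write_result_csv(result: MixingTimeResult, path: str | Path) -> None:
    """One-row CSV serialization of a mixing-time result."""
    d = result.as_dict()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(d))
        writer.writeheader()
        writer.writerow(d)


def _write_provenance(path: Path, record: dict) -> None:
    record = {"mixclock_version": __version__, **record}
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def _plot_trace(trace: Trace, result: MixingTimeResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trace.times_s, trace.values, lw=1.2, label=trace.kind)
    ax.axhspan(result.band_low, result.band_high, alpha=0.2, label="±5% band")
    ax.axvline(result.t_add_s, ls="--", lw=1, label="tracer addition")
    if result.converged:
        ax.axvline(
            result.t_add_s + result.t_mix_s, ls=":", lw=1.5,
            label=f"mixed (t_mix = {result.t_mix_s:g} s)",
        )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pixel SD" if trace.kind == "optical_sd" else "pH")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_video_pipeline(
    video: str | Path | None = None,
    frames_dir: str | Path | None = None,
    out_dir: str | Path = "mixclock_run",
    sample_rate_hz: float = 1.0,
    interval_s: float = 1.0,
    source_fps: float | None = None,
    roi: Roi | None = None,
    method: str = "reference_diff",
    ref_index: int = 0,
    threshold: float = 30.0,
    cutoff: float = 240.0,
    mask_path: str | Path | None = None,
    grey_mode: str = "value",
    t_add_s: float | None = None,
    tolerance: float = 0.05,
    n_last: int = 15,
    criterion: str = "stay",
    band_mode: str = "relative_range",
    plot: bool = True,
    seq: FrameSequence | None = None,
) -> MixingTimeResult:
    """Full optical pipeline: extract → crop → segment → trace → mixing time.

    Exactly one of ``video``, ``frames_dir`` or ``seq`` (an in-memory
    sequence) must be given.  ``band_mode`` defaults to ``relative_range``:
    the optical SD decays toward zero, where a ±5%-of-final band degenerates.
    All intermediates are persisted under ``out_dir``.
    """
    if sum(x is not None for x in (video, frames_dir, seq)) != 1:
        raise ParameterError("give exactly one of video, frames_dir or seq")
    if method == "explicit" and mask_path is None:
        raise ParameterError("method='explicit' requires mask_path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "extract"
    try:
        if video is not None:
            seq = extract_frames(video, sample_rate_hz, source_fps=source_fps)
        elif frames_dir is not None:
            seq = load_frame_dir(frames_dir, interval_s)
        log.info("extract: %d frames of %s", len(seq), seq.frame_shape)

        if roi is not None:
            stage = "crop"
            seq = crop(seq, roi)
        stage = "write_frames"
        write_frames(seq, out / "frames")

        stage = "segment"
        mask = segment_reactor(
            seq,
            method,
            ref_index=ref_index,
            threshold=threshold,
            cutoff=cutoff,
            mask_path=mask_path,
        )
        write_mask(mask, out / "mask.png")
        log.info("segment: %s, %d reactor pixels", method, mask.n_true)

        stage = "trace"
        trace = compute_trace(seq, mask, grey_mode=grey_mode)
        write_trace(trace, out / "trace.csv")

        stage = "mixtime"
        if t_add_s is None:
            t_add_s = detect_tracer_addition(trace)
            log.info("detected tracer addition at t = %g s", t_add_s)
        result = mixing_time(
            trace,
            t_add_s,
            tolerance=tolerance,
            n_last=n_last,
            criterion=criterion,
            band_mode=band_mode,
        )
    except MixclockError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    write_result_csv(result, out / "result.csv")
    if plot:
        _plot_trace(trace, result, out / "trace.png")
    _write_provenance(
        out / "provenance.json",
        {
            "pipeline": "video",
            "video": video,
            "frames_dir": frames_dir,
            "in_memory_sequence": seq.source_path if seq is not None else None,
            "sample_rate_hz": sample_rate_hz,
            "interval_s": interval_s,
            "source_fps": source_fps,
            "roi": None if roi is None else (roi.x0, roi.y0, roi.width, roi.height),
            "method": method,
            "ref_index": ref_index,
            "threshold": threshold,
            "cutoff": cutoff,
            "mask_path": mask_path,
            "mask_pixels": mask.n_true,
            "grey_mode": grey_mode,
            "t_add_s": t_add_s,
            "tolerance": tolerance,
            "n_last": n_last,
            "criterion": criterion,
            "band_mode": band_mode,
        },
    )
    log.info(
        "mixing time: %s",
        f"{result.t_mix_s:g} s" if result.converged else "not converged",
    )
    return result


def run_ph_pipeline(
    ph_csv: str | Path,
    out_dir: str | Path = "mixclock_ph_run",
    t_add_s: float | None = None,
    tolerance: float = 0.05,
    n_last: int = 15,
    criterion: str = "stay",
    band_mode: str = "relative_final",
    plot: bool = True,
) -> MixingTimeResult:
    """Reference pipeline: pH-probe CSV → mixing time, with artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = analyze_ph_csv(
        ph_csv,
        t_add_s=t_add_s,
        tolerance=tolerance,
        n_last=n_last,
        criterion=criterion,
        band_mode=band_mode,
    )
    write_result_csv(result, out / "result.csv")
    if plot:
        from .heterogeneity import read_trace

        _plot_trace(read_trace(ph_csv, kind="ph"), result, out / "trace.png")
    _write_provenance(
        out / "provenance.json",
        {
            "pipeline": "ph",
            "ph_csv": str(ph_csv),
            "t_add_s": result.t_add_s,
            "tolerance": tolerance,
            "n_last": n_last,
            "criterion": criterion,
            "band_mode": band_mode,
        },
    )
    return result
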