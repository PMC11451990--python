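"""End-to-end driver: movie + mask -> contours -> kymographs -> traces ->
summary report.

The pipeline mirrors the study workflow: blur, segment (or consume an
external segmenter's label mask), pair mother/daughter lobes, extract
sub-pixel contours, exclude the bud neck, build circumferential kymographs
per compartment and channel, detect event traces, and tabulate lifetime
and frequency statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .cell_geometry import (
    Contour,
    blur_frame,
    exclude_neck,
    extract_contour,
    pair_mother_daughter,
    segment_cells,
    validate_mask,
)
from .core import CmekymoError, ConfigError, FrameStack
from .kymograph import Kymograph, build_kymograph
from .trace_quant import LifetimeSummary, Trace, detect_traces, estimate_baseline, summarize_lifetimes

log = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with study-scale defaults.

    Thresholds are deliberately explicit: the original measurements were
    made visually, so every automated stand-in here is a parameter.
    """

    step_px: float = 1.0
    band_width_px: int = 5
    reduction: str = "max"
    neck_margin_px: float = 5.0  # default = band width, keeping bands disjoint
    k_sigma: float = 4.0
    min_len_frames: int = 3
    min_rows: int = 1
    censor_policy: str = "exclude"
    median_radius_px: int = 2
    erosion_radius_px: int = 1

    def validate(self) -> None:
        if self.step_px <= 0:
            raise ConfigError("step_px must be > 0")
        if self.band_width_px < 1 or self.band_width_px % 2 == 0:
            raise ConfigError("band_width_px must be odd and >= 1")
        if self.min_len_frames < 1 or self.min_rows < 1:
            raise ConfigError("min_len_frames and min_rows must be >= 1")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (paths + parameters + seed)."""

    movie_paths: list[str] = field(default_factory=list)
    mask_path: str | None = None
    out_dir: str | None = None
    pixel_size_nm: float | None = None  # override sidecar calibration
    frame_interval_s: float | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ConfigError("pixel_size_nm must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        self.params.validate()


@dataclass
class CompartmentResult:
    cell_id: int
    compartment: str
    channel_name: str
    contour: Contour
    kymograph: Kymograph
    traces: list[Trace]
    summary: LifetimeSummary


@dataclass
class ReportTable:
    """Consolidated per-compartment statistics of one analysis run."""

    results: list[CompartmentResult]
    singletons: list[int]

    @property
    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            s = r.summary
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "compartment": r.compartment,
                    "channel": r.channel_name,
                    "n_events": s.n_events,
                    "n_censored": s.n_censored,
                    "mean_lifetime_s": s.mean_s,
                    "sd_lifetime_s": s.sd_s,
                    "cv_percent": s.cv_percent,
                    "frequency_per_um_min": s.frequency_per_um_min,
                    "retained_length_um": s.retained_length_um,
                    "duration_min": s.duration_min,
                }
            )
        return pd.DataFrame(rows)

    @property
    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for tr in r.traces:
                rows.append(
                    {
                        "cell_id": r.cell_id,
                        "compartment": r.compartment,
                        "channel": r.channel_name,
                        "trace_id": tr.trace_id,
                        "row_min": int(tr.rows.min()),
                        "row_max": int(tr.rows.max()),
                        "t_start_frame": tr.t_start,
                        "t_end_frame": tr.t_end,
                        "lifetime_s": tr.lifetime_s,
                        "censored_start": tr.censored_start,
                        "censored_end": tr.censored_end,
                        "peak": tr.peak,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "compartment", "channel", "trace_id", "row_min", "row_max",
                "t_start_frame", "t_end_frame", "lifetime_s", "censored_start",
                "censored_end", "peak",
            ],
        )


def contours_frame(results: list[CompartmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        c = r.contour
        for i, (y, x) in enumerate(c.points):
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "compartment": r.compartment,
                    "index": i,
                    "y": y,
                    "x": x,
                    "excluded": bool(c.excluded[i]),
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "compartment", "index", "y", "x", "excluded"])


def analyze_movie(
    stacks: list[FrameStack],
    mask: np.ndarray | None = None,
    params: AnalysisParams | None = None,
) -> ReportTable:
    """Analyse one field of view: every budded cell, compartment, channel.

    With no external ``mask``, the first channel's time-mean image is
    blurred and segmented by the built-in thresholder; an external
    (e.g. deep-learning) mask is consumed as-is after validation.
    """
    if not stacks:
        raise ConfigError("at least one channel stack required")
    params = params or AnalysisParams()
    params.validate()
    if mask is None:
        mean_img = stacks[0].pixels.mean(axis=0)
        blurred = blur_frame(mean_img, params.median_radius_px, params.erosion_radius_px)
        mask = segment_cells(blurred)
    else:
        mask = validate_mask(mask)
    cells, singletons = pair_mother_daughter(mask)
    results: list[CompartmentResult] = []
    for cell in cells:
        for compartment, label in (("mother", cell.mother_label), ("daughter", cell.daughter_label)):
            try:
                contour = extract_contour(
                    mask,
                    label,
                    step_px=params.step_px,
                    pixel_size_nm=stacks[0].pixel_size_nm,
                    compartment=compartment,
                    cell_id=cell.cell_id,
                )
                contour = exclude_neck(contour, cell.neck_pixels, params.neck_margin_px)
            except CmekymoError as exc:
                raise CmekymoError(
                    f"geometry stage failed for cell {cell.cell_id} {compartment}: {exc}"
                ) from exc
            for stack in stacks:
                try:
                    kymo = build_kymograph(stack, contour, params.band_width_px, params.reduction)
                    baseline, noise = estimate_baseline(kymo)
                    traces = detect_traces(
                        kymo,
                        k_sigma=params.k_sigma,
                        min_len_frames=params.min_len_frames,
                        min_rows=params.min_rows,
                        baseline=baseline,
                        noise=noise,
                    )
                    summary = summarize_lifetimes(
                        traces,
                        retained_length_um=contour.retained_length_um,
                        duration_min=stack.duration_s / 60.0,
                        censor_policy=params.censor_policy,
                        compartment=compartment,
                        channel_name=stack.channel_name,
                    )
                except CmekymoError as exc:
                    raise CmekymoError(
                        f"trace stage failed for cell {cell.cell_id} {compartment} "
                        f"{stack.channel_name}: {exc}"
                    ) from exc
                results.append(
                    CompartmentResult(
                        cell_id=cell.cell_id,
                        compartment=compartment,
                        channel_name=stack.channel_name,
                        contour=contour,
                        kymograph=kymo,
                        traces=traces,
                        summary=summary,
                    )
                )
    return ReportTable(results=results, singletons=singletons)


def run_pipeline(config: RunConfig) -> ReportTable:
    """Load inputs per ``config``, analyse, and write all outputs.

    Writes contours, traces and summaries as versioned CSVs plus a
    machine-readable parameter log sufficient to reproduce the run.
    """
    stacks = [kio.read_stack(p) for p in config.movie_paths]
    for s in stacks:
        if config.pixel_size_nm is not None:
            s.pixel_size_nm = config.pixel_size_nm
        if config.frame_interval_s is not None:
            s.frame_interval_s = config.frame_interval_s
    mask = kio.read_mask(config.mask_path) if config.mask_path else None
    report = analyze_movie(stacks, mask=mask, params=config.params)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kio.write_table(report.summary_frame, out / "summaries.csv", "summaries")
        kio.write_table(report.traces_frame, out / "traces.csv", "traces")
        kio.write_table(contours_frame(report.results), out / "contours.csv", "contours")
        param_log = {
            "movie_paths": [str(p) for p in config.movie_paths],
            "mask_path": str(config.mask_path) if config.mask_path else None,
            "seed": config.seed,
            "pixel_size_nm": config.pixel_size_nm,
            "frame_interval_s": config.frame_interval_s,
            "params": dataclasses.asdict(config.params),
        }
        (out / "run_parameters.json").write_text(json.dumps(param_log, indent=1))
        log.info("run parameters: %s", json.dumps(param_log))
    return report
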