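"""Shared readers/writers, pipeline configuration, and the end-to-end
secretion-analysis pipeline.

Stacks are multi-page TIFF with a JSON sidecar carrying the frame interval,
pixel size and NH4Cl window — TIFF metadata dialects vary, the sidecar is
unambiguous.  Every pipeline run writes a manifest recording the package
version, the full resolved configuration and its hash, so a run is
reproducible from (input, manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import Movie, StimProtocol
from .fusion import detect_events, extract_trace, place_rois, summarize_events
from .pool import corrected_pool_count, detect_puncta, released_fraction

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "read_stack", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters of the secretion-analysis pipeline.

    Acquisition defaults follow the standard paradigm this pipeline targets:
    2 Hz acquisition, 30 s baseline, 10-frame F0, 2 SD amplitude threshold,
    rise time < 1 s.
    """

    frame_interval: float = 0.5
    pixel_size: float = 0.2
    baseline_window: tuple[float, float] = (0.0, 30.0)
    stim_protocol: StimProtocol = field(default_factory=StimProtocol)
    nh4cl_window: tuple[float, float] | None = None
    # ROI placement
    roi_size: int = 3
    n_baseline_frames: int = 10
    smoothing_sigma: float = 1.0
    min_separation: int = 4
    roi_threshold_sd: float = 5.0
    # event detection
    threshold_sd: float = 2.0
    max_rise: float = 1.0
    median_prefilter: int = 3
    # pool
    dog_sigmas: tuple[float, float] = (1.0, 3.0)
    pool_threshold_sd: float = 4.0
    area_range: tuple[int, int] = (3, 200)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        stim = raw.pop("stim_protocol", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if stim is not None:
            cfg.stim_protocol = StimProtocol(**stim)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def read_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
    nh4cl_window: tuple[float, float] | None = None,
) -> Movie:
    """Read a multi-page TIFF stack with its JSON metadata sidecar.

    The sidecar defaults to ``<stack>.json`` next to the stack; explicit
    keyword metadata overrides the sidecar.  Raises if the frame interval
    can be found in neither.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D/3-D TIFF stack, got shape {data.shape}")

    meta: dict = {}
    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    fi = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)
    win = nh4cl_window if nh4cl_window is not None else meta.get("nh4cl_window_s")
    if fi is None:
        raise ValueError(
            "frame interval unknown: provide a sidecar JSON with frame_interval_s "
            "or pass frame_interval explicitly"
        )
    return Movie(
        data=data,
        frame_interval=float(fi),
        pixel_size=float(px),
        nh4cl_window=tuple(win) if win else None,
    )


def run_pipeline(
    config: PipelineConfig,
    movie_path: str | Path | Movie,
    out_dir: str | Path,
    rois: list[tuple[int, int]] | None = None,
) -> dict:
    """End-to-end secretion analysis of one neuron's recording.

    Stages: ROI placement -> trace extraction -> event detection -> event
    summary -> NH4Cl pool segmentation -> overlap correction -> released
    fraction.  Outputs (events CSV, pool CSV, summary and manifest JSON) are
    written under ``out_dir``; a stage failure aborts with the stage named,
    keeping partial outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie = movie_path if isinstance(movie_path, Movie) else read_stack(movie_path)
    if movie.nh4cl_window is None and config.nh4cl_window is not None:
        movie.nh4cl_window = config.nh4cl_window

    result: dict = {}
    stage = "place_rois"
    try:
        t0 = time.perf_counter()
        if rois is None:
            rois = place_rois(
                movie,
                config.stim_protocol,
                smoothing_sigma=config.smoothing_sigma,
                min_separation=config.min_separation,
                threshold_sd=config.roi_threshold_sd,
            )
        logger.info("place_rois: %d ROIs (%.2fs)", len(rois), time.perf_counter() - t0)

        stage = "detect_events"
        events = []
        half = config.roi_size // 2
        # fusion events are counted before the ammonium pulse: the dequench
        # step would otherwise register as a sudden rise in every ROI
        detect_movie = movie
        if movie.nh4cl_window is not None:
            end = movie.frame_index(movie.nh4cl_window[0])
            detect_movie = movie.with_data(movie.data[:end])
        for roi_id, (r, c) in enumerate(rois):
            r = int(np.clip(r, half, movie.shape[1] - 1 - half))
            c = int(np.clip(c, half, movie.shape[2] - 1 - half))
            trace = extract_trace(
                detect_movie, (r, c), config.roi_size, config.n_baseline_frames, roi_id=roi_id
            )
            events.extend(
                detect_events(
                    trace,
                    baseline_window=config.baseline_window,
                    threshold_sd=config.threshold_sd,
                    max_rise=config.max_rise,
                    median_prefilter=config.median_prefilter,
                )
            )
        events_df = pd.DataFrame(
            [
                {
                    "roi_id": ev.roi_id,
                    "onset_s": ev.onset_frame * movie.frame_interval,
                    "peak_s": ev.peak_frame * movie.frame_interval,
                    "peak_ratio": ev.peak_ratio,
                    "amplitude": ev.amplitude,
                    "rise_s": ev.rise_time,
                }
                for ev in events
            ],
            columns=["roi_id", "onset_s", "peak_s", "peak_ratio", "amplitude", "rise_s"],
        )
        events_df.to_csv(out_dir / "events.csv", index=False)

        stage = "summarize_events"
        summary = summarize_events(
            events, movie.n_frames, config.stim_protocol, movie.frame_interval
        )
        result["n_events"] = summary.n_events
        result["mean_peak_ratio"] = summary.mean_peak_ratio
        result["events_per_window"] = summary.events_per_window

        stage = "detect_puncta"
        pool_est = None
        if movie.nh4cl_window is not None:
            pool_est = detect_puncta(
                movie,
                dog_sigmas=config.dog_sigmas,
                threshold_sd=config.pool_threshold_sd,
                area_range=config.area_range,
            )
            stage = "corrected_pool_count"
            pool_est = corrected_pool_count(pool_est)
            pool_est.components.to_csv(out_dir / "pool.csv", index=False)
            result["raw_pool"] = pool_est.raw_count
            result["pool"] = pool_est.corrected_count

            stage = "released_fraction"
            if pool_est.corrected_count > 0:
                rf = released_fraction(summary.n_events, pool_est.corrected_count)
                result["released_fraction"] = rf.fraction
            else:
                result["released_fraction"] = None
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "dcvpipe_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.rng_seed,
        "n_rois": len(rois),
        "results": result,
    }
    (out_dir / "summary.json").write_text(json.dumps(result, indent=2, default=float))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return result
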