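"""End-to-end spot analysis pipeline: detect -> classify -> quantify -> traces.

The pipeline consumes an MCP-channel movie and a nucleus label movie
(produced by an external segmentation/tracking tool) and produces per-spot
measurements and per-nucleus MS2 traces with uncertainties. Processing is
chunked per time point, so memory stays bounded for large movies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import classify_candidates
from .detection import detect_candidate_spots, dog_threshold_from_quantile, \
    dog_filter_slicewise, extract_voxel, mask_bright_regions
from .quantification import quantify_voxel
from .traces import (DetectionErrorRates, assemble_traces,
                     estimate_trace_uncertainty, filter_traces_spatially,
                     traces_to_frame)

log = logging.getLogger("ms2quant")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the reference values."""

    # paths (optional: arrays may be passed directly to run_pipeline)
    mcp_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "ms2quant_run"
    # detection
    sigma_small: float = 1.0
    sigma_large: float = 3.0
    dog_quantile: float = 0.995
    bright_blur_sigma: float = 8.0
    bright_threshold: float | None = None  # None disables bright-region masking
    # classification
    accept_threshold: float = 0.7
    # quantification
    localization_method: str = "gaussian_fit"
    background_method: str = "shell"
    # trace assembly
    refine_iterations: int = 10
    ma_window: int = 5
    ma_threshold: float = 1.0
    width_range: tuple = (0.5, 3.0)
    min_spots: int = 10
    fp: float = 0.04
    fn: float = 0.08
    pixel_size: tuple = (0.97, 0.485, 0.485)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self):
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


def detect_and_quantify_movie(mcp_movie: np.ndarray, config: PipelineConfig,
                              model=None) -> pd.DataFrame:
    """Per-time-point detection, classification and quantification.

    Returns the spot table (one row per accepted spot) with columns
    t, z, y, x, probability, intensity, background, structuredness,
    sigma_z/y/x, converged, truncated.
    """
    rows = []
    for t in range(mcp_movie.shape[0]):
        t0 = time.time()
        volume = np.asarray(mcp_movie[t], dtype=float)
        mask = None
        if config.bright_threshold is not None:
            mask = mask_bright_regions(volume, config.bright_blur_sigma,
                                       config.bright_threshold)
        dog = dog_filter_slicewise(volume, config.sigma_small, config.sigma_large)
        threshold = dog_threshold_from_quantile(dog, config.dog_quantile)
        cands = detect_candidate_spots(volume, config.sigma_small,
                                       config.sigma_large, threshold,
                                       mask=mask, t=t)
        if model is not None and len(cands):
            cands = classify_candidates(model, volume, cands,
                                        config.accept_threshold)
        for row in cands.itertuples():
            try:
                voxel = extract_voxel(volume, (row.z, row.y, row.x))
            except IndexError:
                continue
            m = quantify_voxel(voxel, method=config.localization_method,
                               background_method=config.background_method)
            center = (np.round([row.z, row.y, row.x]).astype(int)
                      - np.asarray(voxel.shape) // 2 + np.asarray(m.center))
            sig = m.sigma_fit if m.sigma_fit is not None else (np.nan,) * 3
            rows.append({
                "t": t, "z": center[0], "y": center[1], "x": center[2],
                "probability": getattr(row, "probability", 1.0),
                "intensity": m.integrated_intensity,
                "background": m.background,
                "structuredness": m.structuredness,
                "sigma_z": sig[0], "sigma_y": sig[1], "sigma_x": sig[2],
                "converged": m.converged, "truncated": m.truncated,
            })
        log.info("t=%d: %d spots (%.2fs)", t, len(cands), time.time() - t0)
    columns = ["t", "z", "y", "x", "probability", "intensity", "background",
               "structuredness", "sigma_z", "sigma_y", "sigma_x",
               "converged", "truncated"]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig, mcp_movie=None, label_movie=None,
                 model=None) -> dict:
    """Run the full pipeline and persist stage outputs.

    Arrays can be passed directly or loaded from the configured paths.
    Returns a dict with the spot table, traces, and the output directory.
    Outputs (spots.csv, traces.csv, config.json) are written under
    ``config.out_dir``; re-running with identical config and inputs
    reproduces them.
    """
    from .io import read_movie, write_json

    if mcp_movie is None:
        if config.mcp_path is None:
            raise FileNotFoundError("no MCP movie given (mcp_path missing)")
        mcp_movie = read_movie(config.mcp_path)
    if label_movie is None:
        if config.labels_path is None:
            raise FileNotFoundError("no label movie given (labels_path missing)")
        label_movie = read_movie(config.labels_path)
    if mcp_movie.shape != label_movie.shape:
        raise ValueError(
            f"stage 'input': movie shape {mcp_movie.shape} != labels "
            f"{label_movie.shape}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spots = detect_and_quantify_movie(mcp_movie, config, model=model)
    spots.to_csv(out / "spots.csv", index=False)

    traces = assemble_traces(spots, label_movie, mcp_movie, model=model,
                             pixel_size=config.pixel_size,
                             iterations=config.refine_iterations,
                             ma_window=config.ma_window,
                             ma_threshold=config.ma_threshold,
                             width_range=config.width_range,
                             accept_threshold=config.accept_threshold)
    rates = DetectionErrorRates(fp=config.fp, fn=config.fn)
    for tr in traces:
        estimate_trace_uncertainty(tr, rates)
    kept = filter_traces_spatially(traces, min_spots=config.min_spots)
    traces_to_frame(kept).to_csv(out / "traces.csv", index=False)

    write_json(out / "config.json",
               {"version": __version__, "config_hash": config.config_hash(),
                **config.to_dict()})
    return {"spots": spots, "traces": kept, "out_dir": out}
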