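"""End-to-end orchestration: simulate -> detect -> track -> mobility ->
clustering index -> kymographs -> group statistics.

A run is described by a :class:`PipelineConfig` whose defaults are the
standard acquisition/analysis settings of this workflow (0.4 µm spot
diameter, 0.4 µm linking gate, >= 10-point tracks, first four MSD lags, 8 µm
line profiles, 3 lines per cell, 5% clustering-index tails, 20 fps). Every
stage writes plain CSV/TIFF artifacts into the output directory and the run
ends with a manifest (file list + parameter hash); identical config and seed
reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import detect, mobility, nanodomain, simulate, stats, track
from .movie import Movie

log = logging.getLogger("nanospt")

ALL_STAGES = ("simulate", "detect", "track", "mobility", "sci", "kymo", "stats")

#: Analysis defaults; deviating from them is allowed but logged.
REFERENCE_DEFAULTS = {
    "diameter_um": 0.4,
    "max_link_um": 0.4,
    "min_points": 10,
    "n_msd_lags": 4,
    "sci_fraction": 0.05,
    "line_length_um": 8.0,
    "n_lines": 3,
    "fps": 20.0,
}


@dataclass
class PipelineConfig:
    """Parameters for one pipeline run. Defaults are the standard settings
    listed in the module docstring; deviations are logged, not forbidden."""

    outdir: str = "nanospt_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic input (ignored when input_movies is given)
    scenarios: tuple[str, ...] = ("static_clustered", "mobile_dispersed")
    n_cells: int = 8
    n_frames: int = 40
    input_movies: tuple[str, ...] = ()  # existing TIFF paths, one per cell
    pixel_size: float = 0.1
    # analysis parameters
    diameter_um: float = 0.4
    quality_threshold: float | None = None  # None -> Otsu auto mode
    max_link_um: float = 0.4
    min_points: int = 10
    n_msd_lags: int = 4
    sci_fraction: float = 0.05
    line_length_um: float = 8.0
    n_lines: int = 3
    fps: float = 20.0
    projection_frames: int = 20
    background_radius_px: int = 30
    subtract_for_sci: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for key, default in REFERENCE_DEFAULTS.items():
            if getattr(self, key) != default:
                log.warning("non-default %s = %r (standard value: %r)",
                            key, getattr(self, key), default)


def _cell_seed(seed: int, scenario_idx: int, cell: int) -> int:
    # deterministic, collision-free per (run, scenario, cell), < 2**31
    return (seed * 1_000_003 + scenario_idx * 10_007 + cell) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(asdict(config)), "files": [], "cells": []}

    cells: list[dict] = []
    if "simulate" in config.stages and not config.input_movies:
        for si, scenario in enumerate(config.scenarios):
            for c in range(config.n_cells):
                seed = _cell_seed(config.seed, si, c)
                cfg = simulate.make_scenario(
                    scenario, seed=seed, n_frames=config.n_frames,
                    frame_interval=1.0 / config.fps, pixel_size=config.pixel_size,
                )
                truth = simulate.simulate_tracks(cfg)
                movie = simulate.render_movie(truth, cfg)
                cell_dir = out / f"{scenario}_cell{c:02d}"
                cell_dir.mkdir(exist_ok=True)
                movie.to_tiff(cell_dir / "movie.tif")
                truth.to_csv(cell_dir / "ground_truth.csv")
                simulate.write_config(cfg, cell_dir / "sim_config.txt")
                manifest["files"] += [str(cell_dir / "movie.tif"),
                                      str(cell_dir / "ground_truth.csv")]
                cells.append({"scenario": scenario, "cell": c, "dir": cell_dir,
                              "movie": movie, "seed": seed})
    else:
        for c, path in enumerate(config.input_movies):
            movie = Movie.from_tiff(path, pixel_size=config.pixel_size,
                                    frame_interval=1.0 / config.fps)
            cell_dir = out / f"input_cell{c:02d}"
            cell_dir.mkdir(exist_ok=True)
            cells.append({"scenario": "input", "cell": c, "dir": cell_dir,
                          "movie": movie, "seed": _cell_seed(config.seed, 0, c)})

    summary_rows = []
    for cell in cells:
        movie: Movie = cell["movie"]
        cell_dir: Path = cell["dir"]
        row = {"group": cell["scenario"], "cell": cell["cell"]}

        spots = None
        if "detect" in config.stages:
            spots = detect.detect_spots(movie, config.diameter_um,
                                        config.quality_threshold)
            spots.to_csv(cell_dir / "spots.csv", index=False)
            manifest["files"].append(str(cell_dir / "spots.csv"))

        tracks = None
        if "track" in config.stages and spots is not None:
            tracks = track.filter_tracks(
                track.link_spots(spots, config.max_link_um), config.min_points
            )
            tracks[track.TRACK_COLUMNS].to_csv(cell_dir / "tracks.csv", index=False)
            manifest["files"].append(str(cell_dir / "tracks.csv"))

        if "mobility" in config.stages and tracks is not None and not tracks.empty:
            diff = mobility.analyze_tracks(tracks, movie.frame_interval,
                                           n_lags=config.n_msd_lags)
            diff.to_csv(cell_dir / "diffusion.csv", index=False)
            manifest["files"].append(str(cell_dir / "diffusion.csv"))
            if len(diff):
                row["median_D"] = float(diff["D_um2_s"].median())
                row["n_tracks"] = int(len(diff))

        if "sci" in config.stages:
            # SCI is a top/bottom intensity ratio: it needs the background
            # offset in the denominator, so it is measured on the raw
            # projection. Background subtraction is display preprocessing.
            proj = nanodomain.max_project(
                movie, min(config.projection_frames, movie.n_frames))
            if config.subtract_for_sci:
                proj = nanodomain.subtract_background(proj, config.background_radius_px)
            profiles = nanodomain.sample_lines(
                proj, movie.pixel_size, n_lines=config.n_lines,
                length_um=config.line_length_um, seed=cell["seed"],
            )
            measurements = [
                nanodomain.compute_sci(p, config.sci_fraction,
                                       cell_id=cell["cell"], line_id=i)
                for i, p in enumerate(profiles)
            ]
            sci_df = pd.DataFrame(
                [(m.cell_id, m.line_id, m.sci, m.mean_intensity, ";".join(m.flags))
                 for m in measurements],
                columns=["cell_id", "line_id", "sci", "mean_intensity", "flags"],
            )
            sci_df.to_csv(cell_dir / "sci.csv", index=False)
            manifest["files"].append(str(cell_dir / "sci.csv"))
            row["median_sci"] = float(np.median([m.sci for m in measurements]))
            if "profiles" not in cell:
                cell["profiles"] = profiles

        if "kymo" in config.stages and cell.get("profiles"):
            kymo = nanodomain.kymograph(movie, cell["profiles"][0].line)
            kymo16 = np.clip(np.rint(kymo), 0, 65535).astype(np.uint16)
            tifffile.imwrite(str(cell_dir / "kymograph.tif"), kymo16)
            manifest["files"].append(str(cell_dir / "kymograph.tif"))

        summary_rows.append(row)
        manifest["cells"].append({"scenario": cell["scenario"],
                                  "cell": cell["cell"], "seed": cell["seed"]})

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "per_cell_summary.csv", index=False)
    manifest["files"].append(str(out / "per_cell_summary.csv"))

    if "stats" in config.stages and len(summary) and summary["group"].nunique() >= 2:
        results = []
        metrics = [c for c in ("median_D", "median_sci") if c in summary]
        if summary["group"].nunique() == 2:
            for metric in metrics:
                sub = summary.dropna(subset=[metric])
                res = stats.compare_two_groups(sub, "group", metric)
                results.append(res)
        else:
            for metric in metrics:
                sub = summary.dropna(subset=[metric])
                kd = stats.kruskal_dunn(sub, "group", metric)
                results.append(pd.DataFrame(
                    [("kruskal_wallis", "all", metric, kd.H, kd.p)],
                    columns=["test", "groups", "metric", "statistic", "p"]))
                pw = kd.pairwise.copy()
                pw.insert(0, "metric", metric)
                pw.to_csv(out / f"dunn_{metric}.csv", index=False)
                manifest["files"].append(str(out / f"dunn_{metric}.csv"))
        stats_df = pd.concat(results, ignore_index=True)
        stats_df.to_csv(out / "stats.csv", index=False)
        manifest["files"].append(str(out / "stats.csv"))

    manifest["parameter_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
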