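"""End-to-end pipeline driver: simulate -> segment -> track -> metrics ->
msd -> frap -> quantify, with per-stage CSV/TIFF artifacts and a manifest.

Reruns with the same configuration (and seed) reproduce identical outputs;
every artifact directory carries a manifest recording the software
version, the configuration hash, and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .frap import FrapSeries, analyze_frap
from .geometry import category_fractions, midplane_table
from .io import write_labels, write_volume
from .motion import MsdWindowConfig, Trajectory, analyze_trajectory, classify_active
from .quant import DiskRoi, roi_mean
from .segmentation import SegmentationParams, segment_series, track_table
from .simulate import (FrapTruthConfig, SceneConfig, generate_frap,
                       generate_roi_fixture, generate_trajectories,
                       render_volume)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("nucdyn")

STAGES = ("simulate", "segment", "metrics", "msd", "frap", "quantify")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: Path
    scene: SceneConfig = dataclasses.field(default_factory=SceneConfig)
    seg_params: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    msd_config: MsdWindowConfig = dataclasses.field(default_factory=MsdWindowConfig)
    frap_config: FrapTruthConfig = dataclasses.field(default_factory=FrapTruthConfig)
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["stages"] = list(self.stages)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages in order; return the artifact index.

    A stage failure halts the run with the stage name in the raised error.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    scene = dataclasses.replace(config.scene, rng_seed=config.seed)
    artifacts: dict[str, str] = {}
    state: dict = {}

    current = "setup"

    def _stage(name):
        nonlocal current
        if name in config.stages:
            current = name
            log.info("stage %s", name)
            return True
        return False

    try:
        if _stage("simulate"):
            truth = generate_trajectories(scene)
            vol, labels_truth = render_volume(truth, scene)
            write_volume(out / "volume.tif", vol)
            write_labels(out / "labels_truth.tif", labels_truth)
            truth.to_table().to_csv(out / "truth.csv", index=False)
            (out / "scene.yaml").write_text(yaml.safe_dump(dataclasses.asdict(scene)))
            artifacts.update(volume="volume.tif", labels_truth="labels_truth.tif",
                             truth="truth.csv", scene="scene.yaml")
            state.update(truth=truth, vol=vol)

        if _stage("segment"):
            if "vol" not in state:
                from .io import read_volume
                state["vol"] = read_volume(out / "volume.tif")
            labels, iso, meta = segment_series(state["vol"], config.seg_params)
            write_labels(out / "labels.tif", labels)
            tracks = track_table(labels)
            tracks.to_csv(out / "tracks.csv", index=False)
            artifacts.update(labels="labels.tif", tracks="tracks.csv")
            state.update(labels=labels, tracks=tracks)

        if _stage("metrics"):
            mp = midplane_table(state["labels"], apical_reference=0.0)
            mp.to_csv(out / "midplanes.csv", index=False)
            frac_rows = []
            for t, grp in mp.groupby("frame"):
                depths = grp.loc[grp["valid"], "midplane_depth_um"].to_numpy()
                if depths.size == 0:
                    continue
                fr = category_fractions(depths)
                fr["frame"] = t
                frac_rows.append(fr)
            pd.DataFrame(frac_rows).to_csv(out / "category_fractions.csv", index=False)
            artifacts.update(midplanes="midplanes.csv",
                             category_fractions="category_fractions.csv")
            state.update(midplanes=mp)

        if _stage("msd"):
            mp = state["midplanes"]
            rows = []
            for tid, grp in mp.sort_values("frame").groupby("track_id"):
                depth = grp["midplane_depth_um"].to_numpy()
                if np.isfinite(depth).sum() < max(config.msd_config.window, 2):
                    continue
                depth = pd.Series(depth).interpolate(limit_direction="both").to_numpy()
                traj = Trajectory(int(tid), depth, scene.frame_interval)
                res = analyze_trajectory(traj, config.msd_config)
                rows.append({
                    "track_id": int(tid),
                    "active": res["active"],
                    "active_min_run_1": classify_active(res["gammas"], 1),
                    "mean_gamma": float(np.nanmean(res["gammas"])) if res["gammas"].size else np.nan,
                    "mean_speed_um_per_min": res["mean_speed"],
                    "peak_speed_um_per_min": res["peak_speed"],
                })
            pd.DataFrame(rows).to_csv(out / "msd_summary.csv", index=False)
            artifacts["msd_summary"] = "msd_summary.csv"

        if _stage("frap"):
            fcfg = dataclasses.replace(config.frap_config, rng_seed=config.seed)
            data = generate_frap(fcfg)
            series = FrapSeries(times=data["times"], Ip=data["Ip"], Ap=data["Ap"],
                                Inp=data["Inp"], Anp=data["Anp"],
                                background=data["background"], prebleach=data["prebleach"])
            res = analyze_frap(series)
            summary = {k: float(res[k]) for k in ("plateau", "k", "t_half", "immobile_fraction")}
            summary["truth"] = data["truth"]
            (out / "frap_fit.json").write_text(json.dumps(summary, indent=2))
            artifacts["frap_fit"] = "frap_fit.json"

        if _stage("quantify"):
            img, truth_rois = generate_roi_fixture(
                (64, 64), background=10.0,
                disks=[{"center": (32.0, 32.0), "diameter": 12.0, "value": 100.0}],
            )
            measured = roi_mean(img, DiskRoi((32.0, 32.0), 12.0))
            pd.DataFrame([
                {"roi_id": "disk_0", "raw_mean_au": measured,
                 "background_au": truth_rois["background"],
                 "corrected_mean_au": measured - truth_rois["background"]},
            ]).to_csv(out / "quant.csv", index=False)
            artifacts["quant"] = "quant.csv"
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": list(config.stages),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
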