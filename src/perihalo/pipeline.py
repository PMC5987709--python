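"""Umbrella pipeline: a config-driven run of any subset of analysis stages.

The configuration (YAML/JSON, see :class:`RunConfig`) names input files and
stage parameters.  ``run_pipeline`` executes the requested stages in a fixed
canonical order, writes per-stage TSV/JSON outputs under ``out_dir`` and
returns a report that records, for every stage, the parameters used —
including every default that was applied implicitly, so paper-gap defaults
stay auditable.  Inputs are never modified; equal configs and seeds give
identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import assays, halo, io, morphometry, proteomics, tracks as tracks_mod

log = logging.getLogger("perihalo")

STAGE_ORDER = [
    "tracks",
    "shape",
    "halo",
    "proteomics",
    "distance",
    "adhesion",
    "transwell",
    "nta",
    "pore_coverage",
]


class StageError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: dict[str, dict[str, Any]]
    out_dir: Path
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict) or "stages" not in data:
            raise ValueError(f"{path}: config must be a mapping with a 'stages' section")
        cfg = cls(
            stages=data["stages"],
            out_dir=Path(out_dir or data.get("out_dir", "perihalo_out")),
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
        )
        unknown = set(cfg.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"{path}: unknown stages {sorted(unknown)}")
        for stage, params in cfg.stages.items():
            for key, value in (params or {}).items():
                if isinstance(value, str) and key.endswith(("_csv", "_tsv", "_file", "_gmt")):
                    if not Path(value).exists():
                        raise FileNotFoundError(f"stage {stage!r}: missing input file {value}")
        return cfg


def _default(params: dict, key: str, default: Any, used: dict) -> Any:
    """Fetch a parameter, recording whether the default was applied."""
    if key in params:
        used[key] = {"value": params[key], "default_applied": False}
        return params[key]
    used[key] = {"value": default, "default_applied": True}
    log.info("default applied: %s = %r", key, default)
    return default


def _stage_tracks(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    dx = float(_default(params, "gradient_dx", 1.0, used))
    dy = float(_default(params, "gradient_dy", 0.0, used))
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise StageError("tracks: gradient direction must be nonzero")
    gradient = tracks_mod.GradientFrame(direction=np.array([dx, dy]) / norm)
    min_disp = _default(params, "min_displacement", 24.1, used)
    n_bins = int(_default(params, "angle_bins", 8, used))
    groups = params["groups"]  # {label: csv path}
    metrics_by_group = {}
    tracks_by_group = {}
    for label, path in groups.items():
        cell_tracks = io.read_tracks(path)
        kept = tracks_mod.filter_by_displacement(cell_tracks, min_disp)
        tracks_by_group[label] = kept
        metrics_by_group[label] = [tracks_mod.track_metrics(t, gradient) for t in kept]
    per_track = pd.DataFrame(
        [dict(group=g, **m.as_dict()) for g, ms in metrics_by_group.items() for m in ms]
    )
    per_track.to_csv(out_dir / "track_metrics.tsv", sep="\t", index=False)
    comparisons = tracks_mod.group_compare(
        metrics_by_group, reference=_default(params, "reference", next(iter(groups)), used)
    )
    summary = [
        {
            "metric": c.metric,
            "treated": c.treated,
            "reference": c.reference,
            "fold_change": c.fold_change,
            "p_value": c.p_value,
            "means": c.group_means,
            "sems": c.group_sems,
        }
        for c in comparisons
    ]
    hist = {}
    for label, kept in tracks_by_group.items():
        centers, fractions = tracks_mod.angle_histogram(kept, gradient, n_bins)
        hist[label] = dict(zip(map(str, centers.tolist()), fractions.tolist()))
    return {"parameters": used, "comparisons": summary, "angle_histograms": hist,
            "outputs": ["track_metrics.tsv"]}


def _stage_shape(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    groups = params["groups"]  # {label: contour csv}
    contours_by_group = {
        label: list(io.read_contours(path).values()) for label, path in groups.items()
    }
    rows = [
        {"group": g, "contour_id": c.contour_id, "circularity": morphometry.circularity(c)}
        for g, cs in contours_by_group.items()
        for c in cs
    ]
    pd.DataFrame(rows).to_csv(out_dir / "circularity.tsv", sep="\t", index=False)
    comparisons = morphometry.circularity_series(
        contours_by_group, reference=_default(params, "reference", next(iter(groups)), used)
    )
    return {
        "parameters": used,
        "comparisons": [
            {"treated": c.treated, "fold_change": c.fold_change, "p_value": c.p_value,
             "means": c.group_means}
            for c in comparisons
        ],
        "outputs": ["circularity.tsv"],
    }


def _stage_halo(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    profile = io.read_profile(params["profile_csv"])
    measurement = halo.diameter_ratio(
        profile,
        marker_channel=_default(params, "marker", "CD9", used),
        vessel_channel=_default(params, "vessel", "podoplanin", used),
        smoothing_window_um=_default(params, "smoothing_window_um", halo.DEFAULT_SMOOTHING_UM, used),
        prominence_fraction=_default(
            params, "prominence_fraction", halo.DEFAULT_PROMINENCE_FRACTION, used
        ),
        sigma_mode=_default(params, "sigma_mode", "band", used),
    )
    result = {
        "parameters": used,
        "status": measurement.status,
        "ratio": measurement.ratio,
        "sigma_marker_um": measurement.marker.sigma,
        "sigma_vessel_um": measurement.vessel.sigma,
        "positions_marker": measurement.marker.positions,
        "positions_vessel": measurement.vessel.positions,
    }
    if not measurement.ok:
        raise StageError(f"halo: detection failed ({measurement.status})")
    return result


def _stage_proteomics(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    table = io.read_peptides(params["peptides_tsv"])
    meta = io.read_sample_meta(params["meta_file"])
    alpha = _default(params, "alpha", 0.05, used)
    quant = proteomics.ratios_and_significance(table, meta, alpha=alpha)
    quant.stats.to_csv(out_dir / "protein_stats.tsv", sep="\t")
    quant.abundances.to_csv(out_dir / "protein_abundances.tsv", sep="\t")
    heat = proteomics.heatmap_matrix(quant)
    heat.to_csv(out_dir / "heatmap.tsv", sep="\t")
    edges, fractions, overall = proteomics.ratio_density(quant)
    result: dict[str, Any] = {
        "parameters": used,
        "n_proteins": int(len(quant.stats)),
        "n_significant": int(quant.stats["significant"].sum()),
        "n_up_1p5": int((quant.stats["ratio"] >= 1.5).sum()),
        "n_down_1p5": int((quant.stats["ratio"] <= 1 / 1.5).sum()),
        "overall_fold_change": overall,
        "outputs": ["protein_stats.tsv", "protein_abundances.tsv", "heatmap.tsv"],
    }
    if "clusters_gmt" in params:
        clusters = io.read_gmt(params["clusters_gmt"])
        enrichments = proteomics.cluster_enrichment(quant, clusters)
        result["cluster_enrichment"] = [
            {"cluster": e.cluster, "n_members": e.n_members,
             "enrichment": e.enrichment, "p_value": e.p_value}
            for e in enrichments
        ]
    return result


def _stage_distance(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    bounds = params.get("bounds")
    vessels = io.read_vessels(params["vessels_csv"], tuple(bounds) if bounds else None)
    used["bounds"] = {"value": list(vessels.bounds), "default_applied": bounds is None}
    points = io.read_points(params["points_csv"])
    n_mc = int(_default(params, "n_monte_carlo", 10_000, used))
    result = assays.normalized_mean_distance(points, vessels, seed=seed, n_monte_carlo=n_mc)
    return {"parameters": used, **result}


def _stage_adhesion(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    df = pd.read_csv(params["events_csv"])
    if not {"track_id", "frame", "present"} <= set(df.columns):
        raise StageError("adhesion: events CSV needs columns track_id,frame,present")
    events = {
        str(tid): sub.sort_values("frame")["present"].astype(bool).tolist()
        for tid, sub in df.groupby("track_id")
    }
    count = assays.adherent_tracks(
        events,
        min_duration_s=_default(params, "min_duration_s", 3.0, used),
        frame_interval_s=_default(params, "frame_interval_s", 1.0, used),
    )
    return {"parameters": used, "n_tracks": len(events), "n_adherent": count}


def _stage_transwell(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    curve = io.read_standard_curve(params["curve_csv"])
    readings_df = pd.read_csv(params["readings_csv"])
    if "t_min" not in readings_df.columns:
        raise StageError("transwell: readings CSV needs a t_min column")
    times = readings_df["t_min"].to_numpy(dtype=float)
    reps = readings_df.drop(columns=["t_min"]).to_numpy(dtype=float)
    result = assays.calibrate_transwell(curve, reps, times_min=times)
    out = pd.DataFrame({"t_min": times, "mean_cells": result["mean"], "sem_cells": result["sem"]})
    out.to_csv(out_dir / "transwell_kinetics.tsv", sep="\t", index=False)
    return {
        "parameters": used,
        "n_times": int(len(times)),
        "n_replicates": int(reps.shape[1]),
        "final_mean_cells": float(result["mean"][-1]),
        "outputs": ["transwell_kinetics.tsv"],
    }


def _stage_nta(params: dict, out_dir: Path, seed: int) -> dict:
    replicates = io.read_size_histograms(params["histograms_csv"])
    averaged, summary = assays.nta_average(replicates)
    io.write_size_histograms(out_dir / "nta_average.csv", [averaged])
    return {"parameters": {}, "n_replicates": len(replicates), **summary,
            "outputs": ["nta_average.csv"]}


def _stage_pore_coverage(params: dict, out_dir: Path, seed: int) -> dict:
    used: dict = {}
    coverage = assays.pore_coverage(
        pore_diameter_um=_default(params, "pore_diameter_um", 3.0, used),
        pore_density_per_cm2=_default(params, "pore_density_per_cm2", 8e5, used),
    )
    return {"parameters": used, "coverage_percent": coverage}


_STAGE_FUNCS: dict[str, Callable[[dict, Path, int], dict]] = {
    "tracks": _stage_tracks,
    "shape": _stage_shape,
    "halo": _stage_halo,
    "proteomics": _stage_proteomics,
    "distance": _stage_distance,
    "adhesion": _stage_adhesion,
    "transwell": _stage_transwell,
    "nta": _stage_nta,
    "pore_coverage": _stage_pore_coverage,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write ``report.json``.

    A stage failure raises :class:`StageError` naming the stage; outputs of
    stages that already completed are retained on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = config.stages[stage] or {}
        log.info("running stage %s", stage)
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](params, config.out_dir, config.seed)
        except StageError:
            _write_report(config.out_dir, report)
            raise
        except Exception as exc:
            _write_report(config.out_dir, report)
            raise StageError(f"{stage}: {exc}") from exc
    payload = json.dumps(report, sort_keys=True, default=_jsonify)
    report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    _write_report(config.out_dir, report)
    return report


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _write_report(out_dir: Path, report: dict) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify) + "\n"
    )
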