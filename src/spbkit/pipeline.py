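"""End-to-end orchestration of the phospho and imaging pipelines.

A run is described by a flat configuration mapping (typically loaded from a
YAML file): a ``paths`` block, a ``params`` block with per-module keys, and
a ``seed``.  Every run writes a machine-readable provenance record
(config hash, package/library versions, seed, per-stage row counts) next to
its outputs, sufficient to re-execute it exactly; re-running the same
config + seed produces byte-identical artifacts.

Thresholds the underlying methods treat as empirical (spot quality,
segmentation artifact thresholds) are required configuration keys here;
example configs ship defaults calibrated on the synthetic generators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from spbkit import __version__
from spbkit import imaging_synth, phospho_synth
from spbkit import phospho_io, phospho_normalize, phospho_stats
from spbkit import segmentation_tracking as seg
from spbkit import spot_colocalization as spots_mod
from spbkit.phospho_io import HP_INSENSITIVE, HP_SENSITIVE

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _provenance(config: dict, seed: int, stage_counts: dict) -> dict:
    return {
        "spbkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_sha256": config_hash(config),
        "config": config,
        "seed": seed,
        "stage_counts": stage_counts,
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


# ---------------------------------------------------------------------------
# phospho pipeline
# ---------------------------------------------------------------------------


def run_phospho(config: dict) -> dict:
    """Execute read -> filter -> normalize -> ratio -> classify -> compare.

    Returns a result bundle dict (also written to ``paths.out``): site
    results, the group comparison, trajectory summaries and provenance.
    """
    paths = config.get("paths", {})
    params = config.get("params", {})
    seed = int(config.get("seed", 0))
    out_dir = Path(paths.get("out", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    design = phospho_io.ChannelDesign.read_tsv(paths["design"])
    sites = phospho_io.read_sites_table(paths["sites"], design)
    proteins = phospho_io.read_protein_table(paths["proteins"], design)
    stage_counts["sites_read"] = len(sites)

    ann_path = paths.get("annotations")
    annotations = None
    if ann_path and Path(ann_path).exists():
        annotations = phospho_io.read_annotations(ann_path)
    elif ann_path:
        logger.warning("annotations file %s missing; all events unclassified", ann_path)

    filtered, filter_report = phospho_io.filter_events(
        sites, design, min_loc_prob=float(params.get("min_loc_prob", 0.7))
    )
    stage_counts["sites_filtered"] = len(filtered)
    annotated = phospho_io.join_annotations(filtered, annotations)

    traj, norm_report = phospho_normalize.normalize_pipeline(
        annotated, proteins, design
    )
    stage_counts["events_normalized"] = int(traj["event_id"].nunique())

    ratios = phospho_stats.max_phospho_ratios(traj)
    results = phospho_stats.classify_rescue(
        ratios,
        annotated,
        rescue_threshold=float(params.get("rescue_threshold", 1.2)),
    )
    stage_counts["events_scored"] = len(results)
    percentages = phospho_stats.rescue_percentages(results)

    comparison = None
    sens = results.loc[results["hp_class"] == HP_SENSITIVE, "R"]
    insens = results.loc[results["hp_class"] == HP_INSENSITIVE, "R"]
    if len(sens) and len(insens):
        comparison = phospho_stats.rank_sum_test(sens, insens)
    else:
        logger.warning("missing HP class annotations; group comparison skipped")

    summaries = []
    sens_ids = set(results.loc[results["hp_class"] == HP_SENSITIVE, "event_id"])
    for strain in phospho_io.STRAINS:
        sub = traj[(traj["strain"] == strain) & traj["event_id"].isin(sens_ids)]
        if sub["event_id"].nunique() >= 2:
            s = phospho_stats.median_trajectory_ci(
                sub, n_boot=int(params.get("n_boot", 10000)), seed=seed
            )
            s.insert(0, "strain", strain)
            summaries.append(s)
    summary = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )

    breakdown = phospho_stats.localization_breakdown(
        results[results["hp_class"] == HP_SENSITIVE]
    )

    # --- artifacts ---------------------------------------------------------
    filtered.to_csv(out_dir / "filtered_sites.tsv", sep="\t", index=False,
                    float_format="%.10g")
    phospho_normalize.write_trajectories(traj, out_dir / "trajectories.tsv")
    results.to_csv(out_dir / "site_results.tsv", sep="\t", index=False,
                   float_format="%.10g")
    if len(summary):
        summary.to_csv(out_dir / "trajectory_summary.tsv", sep="\t", index=False,
                       float_format="%.10g")
    _write_json(
        {
            "filter": filter_report.to_dict(),
            "normalization": norm_report.to_dict(),
            "rescue_percent_by_hp_class": percentages,
        },
        out_dir / "reports.json",
    )
    _write_json(
        comparison.to_dict() if comparison else {"skipped": True},
        out_dir / "comparison.json",
    )
    provenance = _provenance(config, seed, stage_counts)
    _write_json(provenance, out_dir / "provenance.json")

    return {
        "results": results,
        "comparison": comparison,
        "trajectories": traj,
        "summary": summary,
        "breakdown": breakdown,
        "rescue_percent_by_hp_class": percentages,
        "filter_report": filter_report,
        "provenance": provenance,
    }


def simulate_phospho(config: dict) -> Path:
    """Generate a synthetic phospho dataset and write its five artifacts."""
    params_cfg = dict(config.get("params", {}))
    params_cfg["seed"] = int(config.get("seed", params_cfg.get("seed", 0)))
    if "timepoints_minutes" in params_cfg:
        params_cfg["timepoints_minutes"] = tuple(params_cfg["timepoints_minutes"])
    sim_params = phospho_synth.PhosphoSimParams(**params_cfg)
    out_dir = Path(config["paths"]["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = phospho_synth.generate_phospho_dataset(sim_params)
    phospho_io.write_sites_table(sim.sites, out_dir / "sites.tsv")
    phospho_io.write_protein_table(sim.proteins, out_dir / "proteins.tsv")
    sim.design.write_tsv(out_dir / "design.tsv")
    sim.annotations.to_csv(out_dir / "annotations.tsv", sep="\t", index=False)
    _write_json(sim.truth.to_dict(), out_dir / "truth.json")
    return out_dir


# ---------------------------------------------------------------------------
# imaging pipeline
# ---------------------------------------------------------------------------


def _load_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return np.asarray(arr, dtype=float)


def run_imaging(config: dict) -> dict:
    """Execute segment -> link -> intensities -> detect -> assign -> score."""
    paths = config.get("paths", {})
    params = config.get("params", {})
    mode = config.get("mode", "still")
    if mode not in ("still", "timelapse"):
        raise ConfigError(f"mode must be 'still' or 'timelapse', got {mode!r}")
    seed = int(config.get("seed", 0))
    out_dir = Path(paths.get("out", "."))
    out_dir.mkdir(parents=True, exist_ok=True)

    cyclin = _load_stack(paths["cyclin"])
    spb = _load_stack(paths["spb"])
    edge = _load_stack(paths["edge"])
    if not (cyclin.shape == spb.shape == edge.shape):
        raise ConfigError("channel stacks differ in shape")
    n_frames = cyclin.shape[0]
    if mode == "timelapse" and n_frames < 3:
        logger.warning(
            "time-lapse of %d frame(s): two-of-three rule not evaluable, "
            "intersection rule only",
            n_frames,
        )

    seg_params = seg.SegmentationParams(**params.get("segmentation", {}))
    try:
        det_cyc = spots_mod.SpotDetectionParams(
            pixel_size_um=float(params["pixel_size_um"]),
            quality_threshold=float(params["quality_threshold_cyclin"]),
            estimated_diameter_um=float(params.get("diameter_um", 0.35)),
        )
        det_spb = dataclasses.replace(
            det_cyc, quality_threshold=float(params["quality_threshold_spb"])
        )
    except KeyError as exc:
        raise ConfigError(f"missing required imaging parameter: {exc}") from exc

    background = float(params.get("autofluorescence_background", 0.0))
    stage_counts: dict[str, int] = {"frames": n_frames}

    label_stack = np.stack(
        [seg.segment_cells(edge[f], seg_params) for f in range(n_frames)]
    )
    tracks = seg.track_timelapse(label_stack)
    stage_counts["cells_frame0"] = int(label_stack[0].max())
    stage_counts["tracks"] = int(tracks["track_id"].nunique()) if len(tracks) else 0

    cell_rows = []
    cyc_assigned = []
    spb_assigned = []
    n_discarded = 0
    for f in range(n_frames):
        channels = {"cyclin": cyclin[f], "spb": spb[f]}
        meas = seg.measure_cells(
            label_stack[f], channels, frame=f, background={"cyclin": background}
        )
        cell_rows.append(meas)
        c_sp = spots_mod.detect_spots(cyclin[f], det_cyc, frame=f, channel="cyclin")
        s_sp = spots_mod.detect_spots(spb[f], det_spb, frame=f, channel="spb")
        c_sp, d1 = spots_mod.assign_spots_to_cells(c_sp, label_stack[f])
        s_sp, d2 = spots_mod.assign_spots_to_cells(s_sp, label_stack[f])
        n_discarded += d1 + d2
        cyc_assigned.append(c_sp)
        spb_assigned.append(s_sp)
    cells = pd.concat(cell_rows, ignore_index=True)
    cells = cells.merge(tracks, on=["frame", "label"], how="left")
    cyc_spots = pd.concat(cyc_assigned, ignore_index=True)
    spb_spots = pd.concat(spb_assigned, ignore_index=True)
    stage_counts["cyclin_spots"] = len(cyc_spots)
    stage_counts["spb_spots"] = len(spb_spots)
    stage_counts["spots_on_background"] = n_discarded

    if mode == "still":
        verdicts, fraction = spots_mod.score_still(
            label_stack[0],
            cyc_spots[cyc_spots["frame"] == 0],
            spb_spots[spb_spots["frame"] == 0],
        )
    else:
        verdicts, fraction = spots_mod.score_timelapse(tracks, cyc_spots, spb_spots)
    stage_counts["cells_scored"] = len(verdicts)

    cells.to_csv(out_dir / "cells.tsv", sep="\t", index=False, float_format="%.8g")
    pd.concat([cyc_spots, spb_spots], ignore_index=True).to_csv(
        out_dir / "spots.csv", index=False, float_format="%.8g"
    )
    verdicts.to_csv(out_dir / "verdicts.tsv", sep="\t", index=False)
    summary = {
        "mode": mode,
        "fraction_positive": fraction,
        "percent_positive": 100.0 * fraction if fraction == fraction else None,
        "n_cells": len(verdicts),
    }
    _write_json(summary, out_dir / "summary.json")
    provenance = _provenance(config, seed, stage_counts)
    _write_json(provenance, out_dir / "provenance.json")
    return {
        "labels": label_stack,
        "tracks": tracks,
        "cells": cells,
        "cyclin_spots": cyc_spots,
        "spb_spots": spb_spots,
        "verdicts": verdicts,
        "fraction_positive": fraction,
        "summary": summary,
        "provenance": provenance,
    }


def simulate_imaging(config: dict) -> Path:
    """Generate a synthetic field / time-lapse and write TIFFs + truth."""
    params_cfg = dict(config.get("params", {}))
    params_cfg["seed"] = int(config.get("seed", params_cfg.get("seed", 0)))
    for key in ("field_size_px", "cell_length_um_range"):
        if key in params_cfg:
            params_cfg[key] = tuple(params_cfg[key])
    sim_params = imaging_synth.ImagingSimParams(**params_cfg)
    out_dir = Path(config["paths"]["out"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = imaging_synth.generate_cell_field(sim_params)
    tifffile.imwrite(out_dir / "cyclin.tif", stack[:, imaging_synth.CHAN_CYCLIN])
    tifffile.imwrite(out_dir / "spb.tif", stack[:, imaging_synth.CHAN_SPB])
    tifffile.imwrite(out_dir / "edge.tif", stack[:, imaging_synth.CHAN_EDGE])
    tifffile.imwrite(out_dir / "masks.tif", truth.masks)
    _write_json(
        {
            "spb_position": truth.spb_position.tolist(),
            "cyclin_spot_present": truth.cyclin_spot_present.tolist(),
            "spb_rendered": truth.spb_rendered.tolist(),
            "cell_intensity": truth.cell_intensity.tolist(),
            "colocalized": truth.colocalized.tolist(),
            "rule_fired": truth.rule_fired,
        },
        out_dir / "truth.json",
    )
    return out_dir
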