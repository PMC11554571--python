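"""Recovery benchmarks run under the study conditions.

Each routine simulates data at the conditions the analyses are designed
for, runs the corresponding pipeline, and measures how well ground truth is
recovered.  They are used by the test suite and by the reproduction script;
problem sizes are the package's own desk-scale choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spbkit import (
    imaging_synth,
    phospho_io,
    phospho_normalize,
    phospho_stats,
    phospho_synth,
    segmentation_tracking,
    spot_colocalization,
)

# imaging benchmark conditions: 0.07 um/px keeps the 0.35 um spot well
# sampled (5 px FWHM) while halving pixel counts relative to 0.065
IMAGING_PX_UM = 0.07
SPOT_QUALITY_THRESHOLD = 5.9


def pipeline_ratios(sim: phospho_synth.SimulatedPhospho) -> pd.Series:
    """Filtered table -> normalization cascade -> per-event max ratio."""
    filt, _ = phospho_io.filter_events(sim.sites, sim.design)
    traj, _ = phospho_normalize.normalize_pipeline(filt, sim.proteins, sim.design)
    return phospho_stats.max_phospho_ratios(traj)


# ---------------------------------------------------------------------------
# phospho benchmarks
# ---------------------------------------------------------------------------


def mixing_invariance(n_events: int = 2000, seed: int = 0) -> float:
    """Max |delta P| after scaling every channel by an arbitrary factor in
    both the site and protein tables."""
    sim = phospho_synth.generate_phospho_dataset(
        phospho_synth.PhosphoSimParams(n_events=n_events, seed=seed)
    )
    filt, _ = phospho_io.filter_events(sim.sites, sim.design)
    base, _ = phospho_normalize.normalize_pipeline(filt, sim.proteins, sim.design)
    rng = np.random.default_rng(seed + 1)
    sites2 = sim.sites.copy()
    prot2 = sim.proteins.copy()
    for cid in sim.design.channel_ids:
        f = rng.uniform(0.1, 9.0)
        sites2[cid] = sites2[cid] * f
        prot2[cid] = prot2[cid] * f
    filt2, _ = phospho_io.filter_events(sites2, sim.design)
    pert, _ = phospho_normalize.normalize_pipeline(filt2, prot2, sim.design)
    return float(np.max(np.abs(base["P"].to_numpy() - pert["P"].to_numpy())))


def null_case(n_events: int = 2000, seed: int = 0) -> dict:
    """Noise-free, rescue-free data: R must be exactly 1 for every event."""
    sim = phospho_synth.generate_phospho_dataset(
        phospho_synth.PhosphoSimParams(
            n_events=n_events,
            noise_cv=0.0,
            channel_mixing_range=0.0,
            frac_rescued_within_sensitive=0.0,
            seed=seed,
        )
    )
    r = pipeline_ratios(sim)
    results = phospho_stats.classify_rescue(r)
    pct = 100.0 * float((results["rescue_class"] == "increased").mean())
    return {
        "max_abs_r_minus_1": float(np.max(np.abs(r.to_numpy() - 1.0))),
        "percent_increased": pct,
        "n_events": int(len(r)),
    }


def rescue_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Recovery of a 1.5x rescue on 200 of 1000 HP-sensitive events at 10%
    noise, over seeded replicates."""
    medians = []
    pvals = []
    for k in range(n_seeds):
        sim = phospho_synth.generate_phospho_dataset(
            phospho_synth.PhosphoSimParams(
                n_events=2000,
                frac_hp_sensitive=0.5,
                frac_rescued_within_sensitive=0.2,
                rescue_effect=1.5,
                noise_cv=0.1,
                seed=seed + k,
            )
        )
        r = pipeline_ratios(sim)
        rescued = r[r.index.isin(sim.truth.rescued_event_ids)]
        others = r[~r.index.isin(sim.truth.rescued_event_ids)]
        medians.append(float(rescued.median()))
        pvals.append(phospho_stats.rank_sum_test(rescued, others).p_two_sided)
    return {
        "median_r_rescued": medians,
        "p_values": pvals,
        "n_rescued": 200,
        "n_seeds": n_seeds,
    }


def bootstrap_coverage(
    n_rep: int = 200, n_events: int = 50, n_boot: int = 2000, seed: int = 0
) -> float:
    """Fraction of (replicate, timepoint) cells whose percentile-bootstrap
    95% CI covers the true median of the generating distribution."""
    rng = np.random.default_rng(seed)
    curve = np.array([1.0, 1.3, 1.8, 2.2, 2.4])
    covered = 0
    total = 0
    for _ in range(n_rep):
        factors = rng.lognormal(mean=0.0, sigma=0.25, size=(n_events, 1))
        data = curve[None, :] * factors  # true median = curve (median factor 1)
        ci = phospho_stats.median_trajectory_ci(
            data, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        hit = (ci["ci_low"].to_numpy() <= curve) & (curve <= ci["ci_high"].to_numpy())
        covered += int(hit.sum())
        total += len(curve)
    return covered / total


# ---------------------------------------------------------------------------
# imaging benchmarks
# ---------------------------------------------------------------------------


def spot_detection_benchmark(
    n_spots: int = 500,
    snr: float = 8.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    match_radius_px: float = 2.0,
) -> dict:
    """Precision / recall / localization RMSE on sparse synthetic spots.

    Spots of the configured diameter are placed on flat noisy fields with a
    minimum separation of 4 diameters; detection runs at the benchmark
    quality threshold (calibrated once on the simulator at SNR 8).
    """
    rng = np.random.default_rng(seed)
    params = spot_colocalization.SpotDetectionParams(
        pixel_size_um=IMAGING_PX_UM, quality_threshold=4.0
    )
    sigma_px = params.diameter_px * imaging_synth.FWHM_TO_SIGMA
    min_sep = 4 * params.diameter_px
    field = 512
    per_field = 25
    amplitude = snr * noise_sd

    n_true = 0
    n_detected = 0
    n_matched = 0
    sq_err = []
    while n_true < n_spots:
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < per_field and attempts < 10000:
            attempts += 1
            cand = rng.uniform(10, field - 10, size=2)
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
        img = np.zeros((field, field), dtype=np.float32)
        for p in pts:
            imaging_synth._add_gaussian_spot(img, p, sigma_px, amplitude)
        img += rng.standard_normal((field, field), dtype=np.float32) * np.float32(
            noise_sd
        )
        det = spot_colocalization.detect_spots(img, params)
        n_true += len(pts)
        n_detected += len(det)
        taken = set()
        for p in pts:
            if len(det) == 0:
                continue
            d = np.hypot(det["y"].to_numpy() - p[0], det["x"].to_numpy() - p[1])
            order = np.argsort(d)
            for j in order:
                if d[j] > match_radius_px:
                    break
                if j not in taken:
                    taken.add(j)
                    n_matched += 1
                    sq_err.append(float(d[j] ** 2))
                    break
    return {
        "precision": n_matched / n_detected if n_detected else 0.0,
        "recall": n_matched / n_true,
        "rmse_px": float(np.sqrt(np.mean(sq_err))) if sq_err else float("inf"),
        "n_spots": n_true,
    }


def _match_iou(labels: np.ndarray, truth_masks: np.ndarray) -> list[float]:
    out = []
    for t in range(1, int(truth_masks.max()) + 1):
        tm = truth_masks == t
        counts = np.bincount(labels[tm].ravel())
        counts[0] = 0
        if counts.sum() == 0:
            out.append(0.0)
            continue
        lm = labels == counts.argmax()
        out.append(float((tm & lm).sum() / (tm | lm).sum()))
    return out


def segmentation_benchmark(n_fields: int = 20, n_cells: int = 10, seed: int = 0) -> dict:
    """Cell-count recovery and IoU over seeded well-separated fields."""
    exact = 0
    ious: list[float] = []
    for k in range(n_fields):
        params = imaging_synth.ImagingSimParams(
            n_cells=n_cells,
            field_size_px=(1000, 1000),
            pixel_size_um=IMAGING_PX_UM,
            cell_length_um_range=(7.0, 10.0),
            seed=seed + k,
        )
        stack, truth = imaging_synth.generate_cell_field(params)
        labels = segmentation_tracking.segment_cells(
            stack[0, imaging_synth.CHAN_EDGE]
        )
        exact += int(labels.max() == n_cells)
        ious.extend(_match_iou(labels, truth.masks))
    return {
        "n_fields": n_fields,
        "n_exact_count": exact,
        "mean_iou": float(np.mean(ious)),
        "min_iou": float(np.min(ious)),
    }


@dataclass
class TimelapseRun:
    """Pipeline outputs of one simulated time-lapse, plus matched truth."""

    tracks: pd.DataFrame
    cyclin_spots: pd.DataFrame
    spb_spots: pd.DataFrame
    verdicts: pd.DataFrame
    truth_positive_by_track: dict[int, bool]
    fraction_positive: float
    truth_fraction: float


def run_timelapse_recovery(seed: int = 0, n_cells: int = 20, n_frames: int = 30) -> TimelapseRun:
    """Generate one time-lapse and run the scoring pipeline on it.

    Cells in the simulator are static, so the field is segmented once and
    the label image carried across frames by the overlap linker.
    """
    params = imaging_synth.ImagingSimParams(
        n_cells=n_cells,
        field_size_px=(1150, 1150),
        pixel_size_um=IMAGING_PX_UM,
        cell_length_um_range=(7.0, 10.0),
        spot_intensity=50.0,
        spb_marker_intensity=50.0,
        camera_noise_sd=5.0,  # SNR 10 foci
        n_frames=n_frames,
        spb_detectable_frac_frames=0.6,
        frac_cells_with_cyclin_spot=0.5,
        seed=seed,
    )
    stack, truth = imaging_synth.generate_cell_field(params)
    labels = segmentation_tracking.segment_cells(
        stack[0, imaging_synth.CHAN_EDGE]
    )
    det = spot_colocalization.SpotDetectionParams(
        pixel_size_um=IMAGING_PX_UM, quality_threshold=SPOT_QUALITY_THRESHOLD
    )
    cyc_frames = []
    spb_frames = []
    track_rows = []
    for f in range(n_frames):
        c = spot_colocalization.detect_spots(
            stack[f, imaging_synth.CHAN_CYCLIN], det, frame=f, channel="cyclin"
        )
        s = spot_colocalization.detect_spots(
            stack[f, imaging_synth.CHAN_SPB], det, frame=f, channel="spb"
        )
        c, _ = spot_colocalization.assign_spots_to_cells(c, labels)
        s, _ = spot_colocalization.assign_spots_to_cells(s, labels)
        cyc_frames.append(c)
        spb_frames.append(s)
        for lab in range(1, int(labels.max()) + 1):
            track_rows.append({"frame": f, "label": lab, "track_id": lab})
    tracks = pd.DataFrame(track_rows)
    cyc = pd.concat(cyc_frames, ignore_index=True)
    spb = pd.concat(spb_frames, ignore_index=True)
    verdicts, frac = spot_colocalization.score_timelapse(tracks, cyc, spb)

    truth_by_track = {}
    for lab in range(1, int(labels.max()) + 1):
        counts = np.bincount(truth.masks[labels == lab].ravel())
        counts[0] = 0
        truth_by_track[lab] = bool(truth.colocalized[int(counts.argmax()) - 1])
    return TimelapseRun(
        tracks=tracks,
        cyclin_spots=cyc,
        spb_spots=spb,
        verdicts=verdicts,
        truth_positive_by_track=truth_by_track,
        fraction_positive=frac,
        truth_fraction=float(truth.colocalized.mean()),
    )


def colocalization_benchmark(n_seeds: int = 10, seed: int = 0) -> dict:
    """Per-cell verdict agreement with generator truth over seeded lapses."""
    agree = 0
    total = 0
    fracs = []
    truth_fracs = []
    for k in range(n_seeds):
        run = run_timelapse_recovery(seed=seed + k)
        by = run.verdicts.set_index("track_id")["positive"]
        for tid, truth_pos in run.truth_positive_by_track.items():
            agree += int(bool(by.loc[tid]) == truth_pos)
            total += 1
        fracs.append(run.fraction_positive)
        truth_fracs.append(run.truth_fraction)
    return {
        "agreement": agree / total,
        "n_cells": total,
        "fraction_positive": fracs,
        "truth_fraction": truth_fracs,
    }
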