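"""DoG spot detection with sub-pixel localization, and SPB-colocalization
scoring of cyclin foci per cell.

The detector mirrors a TrackMate-style difference-of-Gaussians workflow:
optional 3x3 median prefilter, DoG response bracketing the configured spot
diameter, 8-connected local maxima above a quality threshold, quadratic
sub-pixel refinement, and non-maximum suppression at one spot radius.
Quality is the DoG response at the detected maximum; the threshold is an
empirical per-experiment setting and has no asserted default.

Scoring: a cell is positive in a still image iff one of its cyclin foci
intersects one of its SPB foci (center distance <= sum of radii,
inclusive).  In a time-lapse a cell track is positive iff that happens in
any frame (rule "intersection"), or -- accommodating an SPB marker close to
background -- iff some window of three consecutive frames contains a cyclin
focus in at least two frames and no detected SPB focus in the cell in any
of the three (rule "two_of_three").  Intersection takes precedence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

#: sigma bracket ratio of the DoG filter (kappa)
DOG_KAPPA = np.sqrt(2.0)

SPOT_COLUMNS = ["frame", "channel", "y", "x", "radius_px", "quality"]


@dataclass
class SpotDetectionParams:
    pixel_size_um: float
    quality_threshold: float
    estimated_diameter_um: float = 0.35
    use_median_prefilter: bool = True
    use_subpixel: bool = True

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.estimated_diameter_um / self.pixel_size_um < 2.0:
            raise ValueError("spot diameter must be >= 2 px at this pixel size")

    @property
    def diameter_px(self) -> float:
        return self.estimated_diameter_um / self.pixel_size_um

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    def sigmas(self) -> tuple[float, float]:
        """DoG sigma bracket peaking at the configured blob scale.

        For a 2-D blob of radius r the LoG response peaks at sigma = r /
        sqrt(2); the DoG brackets that center sigma by sqrt(kappa) on each
        side.
        """
        sigma_c = self.radius_px / np.sqrt(2.0)
        return sigma_c / np.sqrt(DOG_KAPPA), sigma_c * np.sqrt(DOG_KAPPA)


@dataclass(frozen=True)
class Spot:
    frame: int
    channel: str
    y: float
    x: float
    radius_px: float
    quality: float


def _median3x3(img: np.ndarray) -> np.ndarray:
    """3x3 median filter (edge-replicated) via a median-of-9 sorting
    network: 19 elementwise min/max passes, much faster than a generic
    rank filter on large frames."""
    padded = np.pad(img, 1, mode="edge")
    H, W = img.shape
    p = [padded[dy : dy + H, dx : dx + W].copy() for dy in range(3) for dx in range(3)]

    def cex(i: int, j: int) -> None:
        lo = np.minimum(p[i], p[j])
        hi = np.maximum(p[i], p[j])
        p[i], p[j] = lo, hi

    for i, j in (
        (1, 2), (4, 5), (7, 8), (0, 1), (3, 4), (6, 7), (1, 2), (4, 5),
        (7, 8), (0, 3), (5, 8), (4, 7), (3, 6), (1, 4), (2, 5), (4, 7),
        (4, 2), (6, 4), (4, 2),
    ):
        cex(i, j)
    return p[4]


def dog_response(image: np.ndarray, params: SpotDetectionParams) -> np.ndarray:
    """The filtered response the detector thresholds (after prefiltering).

    Single precision is preserved (camera frames are float32); the DoG
    difference is well within float32 range.
    """
    image = np.asarray(image)
    dtype = np.float32 if image.dtype == np.float32 else np.float64
    img = image.astype(dtype, copy=False)
    if params.use_median_prefilter:
        img = _median3x3(img)
    s1, s2 = params.sigmas()
    return ndi.gaussian_filter(img, s1) - ndi.gaussian_filter(img, s2)


def _subpixel_offset(patch3: np.ndarray) -> tuple[float, float]:
    """Quadratic vertex of a 3x3 response neighborhood, per axis."""

    def axis_offset(fm: float, f0: float, fp: float) -> float:
        denom = fm - 2.0 * f0 + fp
        if denom >= 0:  # not a local max along this axis; keep the pixel
            return 0.0
        return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))

    dy = axis_offset(patch3[0, 1], patch3[1, 1], patch3[2, 1])
    dx = axis_offset(patch3[1, 0], patch3[1, 1], patch3[1, 2])
    return dy, dx


def detect_spots(
    image: np.ndarray,
    params: SpotDetectionParams,
    frame: int = 0,
    channel: str = "",
) -> pd.DataFrame:
    """Detect diffraction-limited spots in one 2-D frame.

    Returns a DataFrame with columns frame, channel, y, x, radius_px,
    quality, sorted by descending quality.  May be empty.
    """
    params.validate()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    resp = dog_response(img, params)

    is_max = resp == ndi.maximum_filter(resp, size=3, mode="nearest")
    is_max &= resp >= params.quality_threshold
    # 1-px border excluded: the sub-pixel fit needs a full 3x3 neighborhood
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False
    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)

    qualities = resp[ys, xs]
    positions = np.empty((len(ys), 2))
    for i, (r, c) in enumerate(zip(ys, xs)):
        if params.use_subpixel:
            dy, dx = _subpixel_offset(resp[r - 1 : r + 2, c - 1 : c + 2])
        else:
            dy = dx = 0.0
        positions[i] = (r + dy, c + dx)

    # non-maximum suppression at one spot radius, strongest first
    order = np.argsort(-qualities)
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if np.hypot(*(positions[i] - positions[j])) < params.radius_px:
                ok = False
                break
        if ok:
            kept.append(i)

    out = pd.DataFrame(
        {
            "frame": frame,
            "channel": channel,
            "y": positions[kept, 0],
            "x": positions[kept, 1],
            "radius_px": params.radius_px,
            "quality": qualities[kept],
        }
    )
    return out.sort_values("quality", ascending=False, ignore_index=True)


def spots_intersect(a: Spot | pd.Series, b: Spot | pd.Series) -> bool:
    """True iff the two same-frame spots' circles touch or overlap.

    Center distance <= radius_a + radius_b, inclusive.
    """
    if int(a.frame) != int(b.frame):
        raise ValueError("spots are from different frames")
    d = np.hypot(a.y - b.y, a.x - b.x)
    return bool(d <= a.radius_px + b.radius_px)


def assign_spots_to_cells(
    spots: pd.DataFrame, labels: np.ndarray
) -> tuple[pd.DataFrame, int]:
    """Assign each spot the cell label at its rounded position.

    Spots falling on background (label 0) are discarded; returns
    (assigned spots with a ``label`` column, number discarded).
    """
    if len(spots) == 0:
        out = spots.copy()
        out["label"] = pd.Series(dtype=int)
        return out, 0
    H, W = labels.shape
    rr = np.clip(np.rint(spots["y"].to_numpy()).astype(int), 0, H - 1)
    cc = np.clip(np.rint(spots["x"].to_numpy()).astype(int), 0, W - 1)
    lab = labels[rr, cc].astype(int)
    out = spots.copy()
    out["label"] = lab
    n_discarded = int((lab == 0).sum())
    return out[out["label"] > 0].reset_index(drop=True), n_discarded


@dataclass
class LocalizationVerdict:
    track_id: int
    positive: bool
    rule_fired: str  # "intersection" | "two_of_three" | "none"


def _frame_flags(
    cyclin: pd.DataFrame, spb: pd.DataFrame
) -> tuple[bool, bool, bool]:
    """(any intersecting pair, any cyclin spot, any spb spot) in one
    cell-frame."""
    has_c = len(cyclin) > 0
    has_s = len(spb) > 0
    inter = False
    if has_c and has_s:
        dy = cyclin["y"].to_numpy()[:, None] - spb["y"].to_numpy()[None, :]
        dx = cyclin["x"].to_numpy()[:, None] - spb["x"].to_numpy()[None, :]
        rad = (
            cyclin["radius_px"].to_numpy()[:, None]
            + spb["radius_px"].to_numpy()[None, :]
        )
        inter = bool((np.hypot(dy, dx) <= rad).any())
    return inter, has_c, has_s


def score_still(
    labels: np.ndarray,
    cyclin_spots: pd.DataFrame,
    spb_spots: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Score one frame: a cell is positive iff a cyclin focus assigned to it
    intersects an SPB focus assigned to it.

    Returns (verdicts table with columns track_id, positive, rule_fired;
    fraction of positive cells).  track_id equals the cell label in still
    mode.
    """
    cyc, _ = assign_spots_to_cells(cyclin_spots, labels)
    spb, _ = assign_spots_to_cells(spb_spots, labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for lab in ids:
        inter, _, _ = _frame_flags(
            cyc[cyc["label"] == lab], spb[spb["label"] == lab]
        )
        rows.append(
            {
                "track_id": int(lab),
                "positive": inter,
                "rule_fired": "intersection" if inter else "none",
            }
        )
    verdicts = pd.DataFrame(rows, columns=["track_id", "positive", "rule_fired"])
    frac = float(verdicts["positive"].mean()) if len(verdicts) else float("nan")
    return verdicts, frac


def score_timelapse(
    tracks: pd.DataFrame,
    cyclin_spots: pd.DataFrame,
    spb_spots: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Score cell tracks over a time-lapse.

    ``tracks`` has columns (frame, label, track_id); the spot tables carry
    per-frame positions already assigned to labels (columns frame, y, x,
    radius_px, label).  A track is positive iff rule A (an intersecting
    cyclin/SPB pair in its cell in any frame) or rule B (a window of 3
    consecutive track frames with a cyclin focus in >= 2 and no SPB focus
    detected in the cell in any of the 3).  "No detected SPB focus" is
    evaluated per cell, not per field.  Tracks shorter than 3 frames are
    scored by rule A only (logged).
    """
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        inter = np.zeros(len(grp), dtype=bool)
        has_c = np.zeros(len(grp), dtype=bool)
        has_s = np.zeros(len(grp), dtype=bool)
        for i, (_, rec) in enumerate(grp.iterrows()):
            f, lab = int(rec["frame"]), int(rec["label"])
            cyc = cyclin_spots[
                (cyclin_spots["frame"] == f) & (cyclin_spots["label"] == lab)
            ]
            spb = spb_spots[
                (spb_spots["frame"] == f) & (spb_spots["label"] == lab)
            ]
            inter[i], has_c[i], has_s[i] = _frame_flags(cyc, spb)
        positive, rule = False, "none"
        if inter.any():
            positive, rule = True, "intersection"
        elif len(grp) >= 3:
            for i in range(len(grp) - 2):
                if has_c[i : i + 3].sum() >= 2 and not has_s[i : i + 3].any():
                    positive, rule = True, "two_of_three"
                    break
        else:
            logger.info(
                "track %s spans %d frame(s); two-of-three rule not evaluable",
                tid,
                len(grp),
            )
        rows.append({"track_id": int(tid), "positive": positive, "rule_fired": rule})
    verdicts = pd.DataFrame(rows, columns=["track_id", "positive", "rule_fired"])
    frac = float(verdicts["positive"].mean()) if len(verdicts) else float("nan")
    return verdicts, frac


def expression_matched_subset(
    cells: pd.DataFrame,
    intensity_column: str,
    low: float,
    high: float,
) -> pd.DataFrame:
    """Cells whose (background-subtracted) whole-cell mean intensity lies in
    the closed interval [low, high]."""
    if low > high:
        raise ValueError("low must be <= high")
    vals = cells[intensity_column]
    return cells[(vals >= low) & (vals <= high)].reset_index(drop=True)
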