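"""Synthetic two-channel fluorescence fields of rod-shaped yeast cells.

Generates still images or time-lapses emulating the SPB-colocalization
experiments: a cyclin-reporter channel (uniform cytoplasmic fill plus an
optional diffraction-limited focus at the spindle pole body), an SPB-marker
channel (one focus per cell, rendered only in a configurable fraction of
frames to mimic a marker close to background), and an auxiliary "edge"
channel emulating the off-focus plane used for segmentation (bright cell
interior, darker boundary rim).  Ground truth -- label masks, sub-pixel SPB
coordinates, per-frame spot presence and the per-cell colocalization verdict
under the scoring rules -- is returned alongside the image stack.

Cells are 2-D spherocylinders (rectangles with semicircular caps) placed
without overlap by rejection sampling; they neither move nor grow during a
time-lapse.  Foci are isotropic Gaussians whose FWHM equals the configured
spot diameter.  Camera noise is additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: channel indices of the generated stack
CHAN_CYCLIN = 0
CHAN_SPB = 1
CHAN_EDGE = 2


class PlacementError(RuntimeError):
    """Could not place the requested number of cells without overlap."""


@dataclass
class ImagingSimParams:
    """Study conditions for one simulated field / time-lapse."""

    field_size_px: tuple[int, int] = (1200, 1200)
    pixel_size_um: float = 0.065
    n_cells: int = 10
    cell_length_um_range: tuple[float, float] = (7.0, 12.0)
    cell_width_um: float = 3.5
    frac_cells_with_cyclin_spot: float = 0.5
    spot_diameter_um: float = 0.35
    spot_intensity: float = 150.0
    spb_marker_intensity: float = 150.0
    cell_background_intensity: float = 100.0
    camera_noise_sd: float = 5.0
    n_frames: int = 1
    spb_detectable_frac_frames: float = 1.0
    seed: int = 0
    # rendering details of the off-focus segmentation plane
    edge_interior_intensity: float = 300.0
    edge_rim_fraction: float = 0.35
    edge_rim_width_um: float = 0.2
    edge_background_intensity: float = 10.0
    cell_gap_um: float = 1.0
    cell_intensity_cv: float = 0.2

    def validate(self) -> None:
        problems = []
        if self.pixel_size_um <= 0:
            problems.append("pixel_size_um must be > 0")
        elif self.spot_diameter_um / self.pixel_size_um < 2.0:
            problems.append("spot diameter must be >= 2 px at this pixel size")
        if self.n_cells < 0:
            problems.append("n_cells must be >= 0")
        if not 0 <= self.frac_cells_with_cyclin_spot <= 1:
            problems.append("frac_cells_with_cyclin_spot must be in [0, 1]")
        if not 0 <= self.spb_detectable_frac_frames <= 1:
            problems.append("spb_detectable_frac_frames must be in [0, 1]")
        if self.n_frames < 1:
            problems.append("n_frames must be >= 1")
        if self.cell_length_um_range[0] > self.cell_length_um_range[1]:
            problems.append("cell_length_um_range must be (low, high)")
        if self.cell_width_um <= 0:
            problems.append("cell_width_um must be > 0")
        if self.camera_noise_sd < 0:
            problems.append("camera_noise_sd must be >= 0")
        if problems:
            raise ValueError("invalid ImagingSimParams: " + "; ".join(problems))


@dataclass
class SyntheticImagingTruth:
    """Ground truth for one generated field.

    Cells are static, so one label mask describes every frame
    (``masks_for_frame`` returns it for any frame index).
    """

    masks: np.ndarray  # (H, W) uint16, labels 1..n_cells
    spb_position: np.ndarray  # (n_cells, 2) float, (row, col) sub-pixel
    cyclin_spot_present: np.ndarray  # (n_cells, n_frames) bool
    spb_rendered: np.ndarray  # (n_cells, n_frames) bool
    cell_intensity: np.ndarray  # (n_cells,) cyclin-channel fill level
    colocalized: np.ndarray  # (n_cells,) bool, verdict under scoring rules
    rule_fired: list[str]  # per cell: "intersection" | "two_of_three" | "none"

    def masks_for_frame(self, frame: int) -> np.ndarray:
        return self.masks


def colocalization_rules(
    cyclin_present: np.ndarray, spb_present: np.ndarray
) -> tuple[bool, str]:
    """Apply the per-cell scoring rules to per-frame presence booleans.

    Rule A (intersection): some frame has both a cyclin focus and an SPB
    focus in the cell.  Rule B (two-of-three): some window of 3 consecutive
    frames has a cyclin focus in >= 2 frames and no SPB focus in any of the
    3.  Rule A takes precedence; rule B needs >= 3 frames.
    """
    c = np.asarray(cyclin_present, dtype=bool)
    s = np.asarray(spb_present, dtype=bool)
    if np.any(c & s):
        return True, "intersection"
    for i in range(len(c) - 2):
        if c[i : i + 3].sum() >= 2 and not s[i : i + 3].any():
            return True, "two_of_three"
    return False, "none"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2-D segments."""
    p0, p1, q0, q1 = (np.asarray(v, dtype=float) for v in (p0, p1, q0, q1))

    def point_seg(pt, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((pt - a) @ ab / denom, 0.0, 1.0))
        return float(np.linalg.norm(pt - (a + t * ab)))

    # segments in the plane: if they intersect the distance is 0
    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    if (
        orient(p0, p1, q0) * orient(p0, p1, q1) < 0
        and orient(q0, q1, p0) * orient(q0, q1, p1) < 0
    ):
        return 0.0
    return min(
        point_seg(q0, p0, p1),
        point_seg(q1, p0, p1),
        point_seg(p0, q0, q1),
        point_seg(p1, q0, q1),
    )


@dataclass
class _Cell:
    center: np.ndarray  # (row, col)
    theta: float
    half_axis_px: float  # half length of the central segment
    radius_px: float

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([np.sin(self.theta), np.cos(self.theta)])
        return self.center - self.half_axis_px * d, self.center + self.half_axis_px * d


def _place_cells(
    rng: np.random.Generator, params: ImagingSimParams
) -> list[_Cell]:
    H, W = params.field_size_px
    px = params.pixel_size_um
    r = params.cell_width_um / 2.0 / px
    gap = params.cell_gap_um / px
    cells: list[_Cell] = []
    attempts = 0
    max_attempts = 400 * max(params.n_cells, 1)
    while len(cells) < params.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {params.n_cells} cells in a "
                f"{H}x{W} field; use a larger field or fewer cells"
            )
        length = rng.uniform(*params.cell_length_um_range) / px
        a = max(length / 2.0 - r, 1.0)
        theta = rng.uniform(0, np.pi)
        margin = a + r + 3
        if 2 * margin >= min(H, W):
            raise PlacementError("field too small for a single cell")
        center = np.array(
            [rng.uniform(margin, H - margin), rng.uniform(margin, W - margin)]
        )
        cand = _Cell(center, theta, a, r)
        c0, c1 = cand.endpoints
        ok = True
        for other in cells:
            o0, o1 = other.endpoints
            if _segment_distance(c0, c1, o0, o1) < 2 * r + gap:
                ok = False
                break
        if ok:
            cells.append(cand)
    return cells


def _cell_depth(cell: _Cell, H: int, W: int) -> tuple[slice, slice, np.ndarray]:
    """Depth-inside-cell map (pixels) over the cell's bounding box."""
    c0, c1 = cell.endpoints
    pad = cell.radius_px + 2
    r0 = int(max(0, np.floor(min(c0[0], c1[0]) - pad)))
    r1 = int(min(H, np.ceil(max(c0[0], c1[0]) + pad) + 1))
    q0 = int(max(0, np.floor(min(c0[1], c1[1]) - pad)))
    q1 = int(min(W, np.ceil(max(c0[1], c1[1]) + pad) + 1))
    yy, xx = np.mgrid[r0:r1, q0:q1]
    pts = np.stack([yy, xx], axis=-1).astype(float)
    ab = c1 - c0
    denom = float(ab @ ab)
    t = np.clip(((pts - c0) @ ab) / denom, 0.0, 1.0) if denom else np.zeros(yy.shape)
    closest = c0 + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    return slice(r0, r1), slice(q0, q1), cell.radius_px - dist


def _add_gaussian_spot(
    img: np.ndarray, pos: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    H, W = img.shape
    half = int(np.ceil(5 * sigma_px))
    r0 = int(max(0, np.floor(pos[0]) - half))
    r1 = int(min(H, np.floor(pos[0]) + half + 1))
    q0 = int(max(0, np.floor(pos[1]) - half))
    q1 = int(min(W, np.floor(pos[1]) + half + 1))
    yy, xx = np.mgrid[r0:r1, q0:q1]
    img[r0:r1, q0:q1] += amplitude * np.exp(
        -((yy - pos[0]) ** 2 + (xx - pos[1]) ** 2) / (2 * sigma_px**2)
    )


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def generate_cell_field(
    params: ImagingSimParams,
) -> tuple[np.ndarray, SyntheticImagingTruth]:
    """Generate an image stack and its ground truth.

    Returns ``(stack, truth)`` with ``stack`` of shape
    ``(n_frames, 3, H, W)`` float32; channels are cyclin (0), SPB marker
    (1), and the off-focus edge plane used for segmentation (2).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.field_size_px
    px = params.pixel_size_um
    cells = _place_cells(rng, params)
    n = len(cells)

    masks = np.zeros((H, W), dtype=np.uint16)
    edge_base = np.full((H, W), params.edge_background_intensity, dtype=np.float64)
    rim_w = max(params.edge_rim_width_um / px, 1.0)
    depth_maps = []
    for i, cell in enumerate(cells):
        rs, qs, depth = _cell_depth(cell, H, W)
        inside = depth >= 0
        masks[rs, qs][inside] = i + 1
        profile = params.edge_rim_fraction + (1 - params.edge_rim_fraction) * np.clip(
            depth / rim_w, 0.0, 1.0
        )
        patch = edge_base[rs, qs]
        patch[inside] = params.edge_interior_intensity * profile[inside]
        edge_base[rs, qs] = patch
        depth_maps.append((rs, qs, inside))

    # SPB near one cell tip, on the axis (guaranteed inside the mask)
    spb_pos = np.empty((n, 2))
    for i, cell in enumerate(cells):
        c0, c1 = cell.endpoints
        end = c1 if rng.random() < 0.5 else c0
        u = rng.uniform(0.75, 0.95)
        spb_pos[i] = cell.center + u * (end - cell.center)

    cell_int = params.cell_background_intensity * np.exp(
        rng.normal(0.0, params.cell_intensity_cv, size=n)
    )
    has_cyclin = rng.random(n) < params.frac_cells_with_cyclin_spot
    # static foci: a cyclin-positive cell shows its focus in every frame
    cyclin_present = np.repeat(has_cyclin[:, None], params.n_frames, axis=1)
    spb_rendered = rng.random((n, params.n_frames)) < params.spb_detectable_frac_frames

    sigma_px = params.spot_diameter_um / px * FWHM_TO_SIGMA

    cyclin_base = np.zeros((H, W))
    for i in range(n):
        rs, qs, inside = depth_maps[i]
        patch = cyclin_base[rs, qs]
        patch[inside] += cell_int[i]
        cyclin_base[rs, qs] = patch
    # the cytoplasmic fill is imaged through the same diffraction-limited
    # optics as the foci: blur it with the PSF so cell outlines are not
    # artificially sharp
    cyclin_base = ndi.gaussian_filter(cyclin_base, sigma_px)

    stack = np.empty((params.n_frames, 3, H, W), dtype=np.float32)
    for f in range(params.n_frames):
        cyc = cyclin_base.copy()
        spb = np.zeros((H, W))
        for i in range(n):
            if cyclin_present[i, f]:
                _add_gaussian_spot(cyc, spb_pos[i], sigma_px, params.spot_intensity)
            if spb_rendered[i, f]:
                _add_gaussian_spot(
                    spb, spb_pos[i], sigma_px, params.spb_marker_intensity
                )
        for c, img in ((CHAN_CYCLIN, cyc), (CHAN_SPB, spb), (CHAN_EDGE, edge_base)):
            out = img.astype(np.float32)
            if params.camera_noise_sd > 0:
                out = out + rng.standard_normal(
                    size=(H, W), dtype=np.float32
                ) * np.float32(params.camera_noise_sd)
            stack[f, c] = out

    verdicts = []
    rules = []
    for i in range(n):
        pos, rule = colocalization_rules(cyclin_present[i], spb_rendered[i])
        verdicts.append(pos)
        rules.append(rule)

    truth = SyntheticImagingTruth(
        masks=masks,
        spb_position=spb_pos,
        cyclin_spot_present=cyclin_present,
        spb_rendered=spb_rendered,
        cell_intensity=cell_int,
        colocalized=np.array(verdicts, dtype=bool),
        rule_fired=rules,
    )
    return stack, truth
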