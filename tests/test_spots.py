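"""DoG spot detection and colocalization scoring rules."""

import numpy as np
import pandas as pd
import pytest

from spbkit.imaging_synth import FWHM_TO_SIGMA
from spbkit.spot_colocalization import (
    Spot,
    SpotDetectionParams,
    assign_spots_to_cells,
    detect_spots,
    expression_matched_subset,
    score_still,
    score_timelapse,
    spots_intersect,
)

PX = 0.065
SIGMA_PX = 0.35 / PX * FWHM_TO_SIGMA


def render_spots(shape, positions, amplitude, noise_sd, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for y, x in positions:
        img += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * SIGMA_PX**2)
        )
    if noise_sd:
        img = img + rng.normal(0, noise_sd, shape)
    return img


def params(quality=4.0, **kw):
    return SpotDetectionParams(
        pixel_size_um=PX, quality_threshold=quality, **kw
    )


class TestDetectSpots:
    def test_blank_image_no_spots(self):
        out = detect_spots(np.zeros((64, 64)), params())
        assert len(out) == 0

    def test_single_spot_subpixel_accuracy(self):
        truth = (30.3, 41.7)
        img = render_spots((80, 80), [truth], amplitude=50, noise_sd=5, seed=1)
        out = detect_spots(img, params())
        assert len(out) == 1
        err = np.hypot(out.loc[0, "y"] - truth[0], out.loc[0, "x"] - truth[1])
        assert err <= 0.5

    def test_two_far_spots_detected_close_pair_suppressed(self):
        d_px = 0.35 / PX
        far = [(20.0, 20.0), (20.0, 20.0 + 3 * d_px)]
        out = detect_spots(
            render_spots((60, 80), far, 50, 0), params()
        )
        assert len(out) == 2
        near = [(20.0, 20.0), (20.0, 20.0 + 0.5 * d_px / 2)]
        out2 = detect_spots(
            render_spots((60, 80), near, 50, 0), params()
        )
        assert len(out2) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        pos = [(rng.uniform(10, 110), rng.uniform(10, 110)) for _ in range(6)]
        img = render_spots((128, 128), pos, 40, 5, seed=3)
        counts = [
            len(detect_spots(img, params(quality=q))) for q in (2.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_subpixel_disabled_gives_integer_positions(self):
        img = render_spots((64, 64), [(30.3, 41.7)], 50, 0)
        out = detect_spots(img, params(use_subpixel=False))
        assert float(out.loc[0, "y"]).is_integer()

    def test_undersampled_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(
                np.zeros((32, 32)),
                SpotDetectionParams(pixel_size_um=0.3, quality_threshold=1.0),
            )


class TestSpotsIntersect:
    def _spot(self, y, x, r=2.7, frame=0):
        return Spot(frame=frame, channel="c", y=y, x=x, radius_px=r, quality=1.0)

    def test_coincident_and_boundary_inclusive(self):
        a = self._spot(10, 10)
        assert spots_intersect(a, self._spot(10, 10))
        b = self._spot(10, 10 + 2 * 2.7)  # distance == r_a + r_b
        assert spots_intersect(a, b)
        c = self._spot(10, 10 + 4 * 2.7)
        assert not spots_intersect(a, c)

    def test_cross_frame_rejected(self):
        with pytest.raises(ValueError):
            spots_intersect(self._spot(0, 0), self._spot(0, 0, frame=1))


class TestAssignment:
    def test_conservation_and_background_discard(self):
        labels = np.zeros((40, 40), dtype=np.uint16)
        labels[5:15, 5:15] = 1
        labels[20:30, 20:30] = 2
        spots = pd.DataFrame(
            {
                "frame": [0, 0, 0],
                "y": [10.0, 25.0, 0.0],
                "x": [10.0, 25.0, 0.0],
                "radius_px": 2.7,
                "quality": 1.0,
            }
        )
        assigned, discarded = assign_spots_to_cells(spots, labels)
        assert list(assigned["label"]) == [1, 2]
        assert discarded == 1
        assert len(assigned) + discarded == len(spots)


def _spot_row(frame, y, x, label, r=2.7):
    return {
        "frame": frame, "channel": "c", "y": y, "x": x,
        "radius_px": r, "quality": 1.0, "label": label,
    }


class TestScoreStill:
    def test_intersection_positive_and_fraction(self):
        labels = np.zeros((60, 60), dtype=np.uint16)
        labels[5:25, 5:25] = 1
        labels[30:50, 5:25] = 2
        labels[30:50, 30:50] = 3
        cyc = pd.DataFrame([_spot_row(0, 10.0, 10.0, None),
                            _spot_row(0, 40.0, 10.0, None)])
        spb = pd.DataFrame([_spot_row(0, 11.0, 10.0, None)])
        verdicts, frac = score_still(labels, cyc, spb)
        by = verdicts.set_index("track_id")
        assert bool(by.loc[1, "positive"]) and by.loc[1, "rule_fired"] == "intersection"
        assert not by.loc[2, "positive"]  # cyclin focus but no SPB focus
        assert not by.loc[3, "positive"]
        assert frac == pytest.approx(1 / 3)


class TestScoreTimelapse:
    def _tracks(self, n_frames, labels=(1,)):
        return pd.DataFrame(
            [
                {"frame": f, "label": l, "track_id": l}
                for f in range(n_frames)
                for l in labels
            ]
        )

    def _empty(self):
        return pd.DataFrame(
            columns=["frame", "channel", "y", "x", "radius_px", "quality", "label"]
        )

    def test_two_of_three_rule(self):
        cyc = pd.DataFrame([_spot_row(0, 5, 5, 1), _spot_row(2, 5, 5, 1)])
        verdicts, _ = score_timelapse(self._tracks(3), cyc, self._empty())
        row = verdicts.iloc[0]
        assert bool(row["positive"]) and row["rule_fired"] == "two_of_three"

    def test_single_cyclin_frame_negative(self):
        cyc = pd.DataFrame([_spot_row(1, 5, 5, 1)])
        verdicts, _ = score_timelapse(self._tracks(5), cyc, self._empty())
        assert not bool(verdicts.iloc[0]["positive"])

    def test_intersection_takes_precedence(self):
        cyc = pd.DataFrame([_spot_row(f, 5, 5, 1) for f in range(4)])
        spb = pd.DataFrame([_spot_row(2, 5.5, 5, 1)])
        verdicts, _ = score_timelapse(self._tracks(4), cyc, spb)
        assert verdicts.iloc[0]["rule_fired"] == "intersection"

    def test_spb_anywhere_in_window_blocks_rule_b(self):
        cyc = pd.DataFrame([_spot_row(0, 5, 5, 1), _spot_row(1, 5, 5, 1)])
        spb = pd.DataFrame([_spot_row(2, 50, 50, 1)])  # same cell, far away
        verdicts, _ = score_timelapse(self._tracks(3), cyc, spb)
        assert not bool(verdicts.iloc[0]["positive"])

    def test_short_track_rule_a_only(self, caplog):
        cyc = pd.DataFrame([_spot_row(0, 5, 5, 1), _spot_row(1, 5, 5, 1)])
        with caplog.at_level("INFO"):
            verdicts, _ = score_timelapse(self._tracks(2), cyc, self._empty())
        assert not bool(verdicts.iloc[0]["positive"])

    def test_single_frame_reduces_to_still_semantics(self):
        labels = np.zeros((60, 60), dtype=np.uint16)
        labels[5:25, 5:25] = 1
        labels[30:50, 30:50] = 2
        cyc = pd.DataFrame([_spot_row(0, 10.0, 10.0, 1)])
        spb = pd.DataFrame([_spot_row(0, 11.0, 10.0, 1)])
        still, frac_still = score_still(labels, cyc.drop(columns="label"),
                                        spb.drop(columns="label"))
        lapse, frac_lapse = score_timelapse(self._tracks(1, (1, 2)), cyc, spb)
        assert frac_still == frac_lapse
        pd.testing.assert_frame_equal(
            still.sort_values("track_id").reset_index(drop=True),
            lapse.sort_values("track_id").reset_index(drop=True),
        )


class TestExpressionMatching:
    def test_bounds(self):
        cells = pd.DataFrame({"mean_cyclin": [1.0, 2.0, 3.0, 4.0]})
        assert len(
            expression_matched_subset(cells, "mean_cyclin", -np.inf, np.inf)
        ) == 4
        assert len(expression_matched_subset(cells, "mean_cyclin", 10, 20)) == 0
        out = expression_matched_subset(cells, "mean_cyclin", 2.0, 3.0)
        assert list(out["mean_cyclin"]) == [2.0, 3.0]
        with pytest.raises(ValueError):
            expression_matched_subset(cells, "mean_cyclin", 3.0, 2.0)
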