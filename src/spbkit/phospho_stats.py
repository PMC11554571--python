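"""Rescue statistics on normalized phosphorylation trajectories.

The core quantity is the *maximum phosphorylation ratio*

    R = max_t P_tethered(t) / max_t P_control(t)

computed per phosphorylation event over all timepoints of the time course
(including T0, where P = 1 by construction).  R >= 1.2 -- the tethered
strain's peak at least 20% above the control's -- classifies an event as
having increased ("rescued") phosphorylation.  Group comparisons between
HP-sensitive and HP-insensitive events use the Mann-Whitney rank-sum test;
trajectory summaries use per-timepoint medians with percentile-bootstrap
95% confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from spbkit.phospho_io import STRAIN_CONTROL, STRAIN_TETHERED
from spbkit.phospho_normalize import trajectory_matrix

logger = logging.getLogger(__name__)

RESCUE_THRESHOLD_DEFAULT = 1.2
RESCUE_INCREASED = "increased"
RESCUE_NOT_INCREASED = "not_increased"

#: largest n_A + n_B for which the tie-free exact null is enumerated
EXACT_LIMIT = 12


def max_phospho_ratio(
    traj_tethered: np.ndarray | pd.Series,
    traj_control: np.ndarray | pd.Series,
) -> float:
    """Ratio of the peak normalized phosphorylation, tethered over control.

    Both trajectories must cover the same timepoints and be positive.
    """
    a = np.asarray(traj_tethered, dtype=float)
    b = np.asarray(traj_control, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trajectories cover different timepoint sets")
    if a.size == 0:
        raise ValueError("empty trajectory")
    if not (np.all(a > 0) and np.all(b > 0)):
        raise ValueError("trajectories must be positive")
    return float(a.max() / b.max())


def max_phospho_ratios(traj: pd.DataFrame) -> pd.Series:
    """Per-event maximum phosphorylation ratio from a long trajectory table.

    Events lacking either strain's trajectory are dropped.
    """
    teth, _ = trajectory_matrix(traj, STRAIN_TETHERED)
    ctrl, _ = trajectory_matrix(traj, STRAIN_CONTROL)
    common = teth.index.intersection(ctrl.index)
    if list(teth.columns) != list(ctrl.columns):
        raise ValueError("strains cover different timepoint sets")
    r = teth.loc[common].max(axis=1) / ctrl.loc[common].max(axis=1)
    r.name = "R"
    return r


def classify_rescue(
    ratios: pd.Series,
    annotated: pd.DataFrame | None = None,
    rescue_threshold: float = RESCUE_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Classify each event as increased / not_increased at the threshold.

    The boundary is inclusive: R exactly equal to the threshold counts as
    increased.  If ``annotated`` (an event table carrying ``hp_class`` and
    ``localization``) is given, those labels are joined onto the result;
    otherwise events are unclassified/unknown.
    """
    res = pd.DataFrame({"event_id": ratios.index, "R": ratios.to_numpy()})
    res["rescue_class"] = np.where(
        res["R"] >= rescue_threshold, RESCUE_INCREASED, RESCUE_NOT_INCREASED
    )
    if annotated is not None and "hp_class" in annotated.columns:
        ann = annotated.set_index("event_id")
        res["hp_class"] = (
            ann["hp_class"].reindex(res["event_id"]).fillna("unclassified").values
        )
        if "localization" in annotated.columns:
            res["localization"] = (
                ann["localization"].reindex(res["event_id"]).fillna("unknown").values
            )
        else:
            res["localization"] = "unknown"
    else:
        res["hp_class"] = "unclassified"
        res["localization"] = "unknown"
    return res.reset_index(drop=True)


def rescue_percentages(results: pd.DataFrame) -> dict[str, float]:
    """Percent of events classified as increased, within each hp_class."""
    out: dict[str, float] = {}
    for hp, grp in results.groupby("hp_class"):
        out[hp] = 100.0 * float((grp["rescue_class"] == RESCUE_INCREASED).mean())
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum comparison
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    U: float
    p_two_sided: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    method: str  # "exact" or "normal"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def rank_sum_test(
    values_a,
    values_b,
    mode: str = "auto",
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two groups.

    ``mode``:
      * ``"auto"``  -- exact null when n_A + n_B <= 12 and there are no
        ties, otherwise the normal approximation with tie correction and
        continuity correction;
      * ``"exact"`` / ``"normal"`` force either path (exact requires no
        ties).

    U is the number of (a, b) pairs with a > b (ties counted 1/2), so
    swapping the groups maps U -> n_A * n_B - U and leaves p unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return GroupComparison(
            U=a.size * b.size / 2.0,
            p_two_sided=1.0,
            n_a=a.size,
            n_b=b.size,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            method="degenerate",
        )

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and has_ties:
        raise ValueError("exact mode is undefined with ties")
    if mode == "auto":
        use_exact = (a.size + b.size <= EXACT_LIMIT) and not has_ties
    else:
        use_exact = mode == "exact"

    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        U=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method="exact" if use_exact else "normal",
    )


# ---------------------------------------------------------------------------
# trajectory summaries
# ---------------------------------------------------------------------------


def median_trajectory_ci(
    trajectories: pd.DataFrame | np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    ci: float = 95.0,
) -> pd.DataFrame:
    """Per-timepoint median with a percentile-bootstrap confidence interval.

    ``trajectories`` is either an events x timepoints matrix or a long
    trajectory table restricted to one strain (columns event_id,
    timepoint_index, P).  Events are resampled with replacement; the
    [2.5%, 97.5%] percentiles of the bootstrap median form the default CI.
    Fully reproducible for a fixed seed.
    """
    if isinstance(trajectories, pd.DataFrame) and "P" in trajectories.columns:
        if trajectories["strain"].nunique() > 1:
            raise ValueError("pass trajectories of a single strain")
        mat = trajectories.pivot(
            index="event_id", columns="timepoint_index", values="P"
        ).sort_index(axis=1)
        timepoints = list(mat.columns)
        data = mat.to_numpy(dtype=float)
    else:
        data = np.asarray(trajectories, dtype=float)
        timepoints = list(range(data.shape[1])) if data.ndim == 2 else []
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 trajectories")

    rng = np.random.default_rng(seed)
    n = data.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_medians = np.median(data[idx, :], axis=1)  # (n_boot, n_t)
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boot_medians, [alpha, 100.0 - alpha], axis=0)
    return pd.DataFrame(
        {
            "timepoint_index": timepoints,
            "median": np.median(data, axis=0),
            "ci_low": lo,
            "ci_high": hi,
        }
    )


def localization_breakdown(results: pd.DataFrame) -> pd.DataFrame:
    """Group per-event ratios by reported localization.

    Returns one row per non-empty localization category with the event
    count, the median R, and the list of R values (as an object column for
    plotting or export).  Categories form a partition of the input.
    """
    rows = []
    for loc, grp in results.groupby("localization"):
        rows.append(
            {
                "localization": loc,
                "n": len(grp),
                "median_R": float(grp["R"].median()),
                "R_values": grp["R"].tolist(),
            }
        )
    return pd.DataFrame(rows)
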