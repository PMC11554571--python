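"""The three-step normalization cascade for TMT time-course phospho data.

Order is fixed: per-channel median normalization (mixing-error correction),
then T0 normalization within each strain, then division by the protein's own
median- and T0-normalized trajectory from the flow-through proteome.  The
result, P(event, strain, t), is the "normalized phosphorylation" plotted in
rescue analyses: dimensionless, with P(T0) = 1 exactly.

Mixing errors: because each channel is divided by the median intensity of
that channel, multiplying every intensity of any channel (in both the site
and protein tables) by a positive constant leaves P unchanged to floating
round-off.  That invariance is the testable content of the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spbkit.phospho_io import STRAINS, ChannelDesign

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationReport:
    """Per-stage exclusion accounting for the cascade."""

    n_events_in: int = 0
    n_dropped_t0: int = 0
    n_excluded_no_protein: int = 0
    n_events_out: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_events_in": self.n_events_in,
            "n_dropped_t0": self.n_dropped_t0,
            "n_excluded_no_protein": self.n_excluded_no_protein,
            "n_events_out": self.n_events_out,
            "notes": list(self.notes),
        }


def median_normalize(table: pd.DataFrame, design: ChannelDesign) -> pd.DataFrame:
    """Divide each channel column by its median over all rows of the table.

    The median is taken over quantified (non-missing) rows; the per-channel
    median of the output is therefore 1.  Raises if a channel has no
    quantified rows at all.  Applied identically to site and protein tables,
    each over its own rows: the flow-through proteome is a separate
    quantification with its own mixing errors.
    """
    out = table.copy()
    for cid in design.channel_ids:
        col = out[cid].to_numpy(dtype=float)
        if np.all(np.isnan(col)):
            raise NormalizationError(f"channel {cid!r} has no quantified events")
        med = np.nanmedian(col)
        if not np.isfinite(med) or med <= 0:
            raise NormalizationError(f"channel {cid!r} has non-positive median")
        out[cid] = col / med
    return out


def t0_normalize(
    table: pd.DataFrame,
    design: ChannelDesign,
    report: NormalizationReport | None = None,
) -> pd.DataFrame:
    """Divide each strain's channels by that strain's T0 channel, per row.

    Rows whose T0 value is missing (or zero) in either strain cannot be
    expressed relative to T0 and are dropped with a logged count.
    """
    out = table.copy()
    t0_cols = [design.t0_channel(s).channel_id for s in STRAINS]
    t0 = out[t0_cols].to_numpy(dtype=float)
    ok = np.isfinite(t0).all(axis=1) & (t0 > 0).all(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("t0_normalize: dropping %d row(s) with missing/zero T0", n_drop)
    if report is not None:
        report.n_dropped_t0 += n_drop
    out = out.loc[ok].reset_index(drop=True)
    for strain in STRAINS:
        cols = design.channel_ids_for(strain)
        t0_col = out[cols[0]].to_numpy(dtype=float).copy()
        for cid in cols:
            out[cid] = out[cid].to_numpy(dtype=float) / t0_col
    return out


def protein_normalize(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    design: ChannelDesign,
    report: NormalizationReport | None = None,
) -> pd.DataFrame:
    """Divide each site trajectory by its protein's normalized trajectory.

    ``sites`` and ``proteins`` must both already be median- and
    T0-normalized.  Events whose protein is absent from the proteome table,
    or whose protein lacks any design channel, are excluded and counted
    (sites without proteome data for all timepoints cannot be corrected for
    protein-abundance change).

    Returns the long-format trajectory table with columns
    ``event_id, strain, timepoint_index, timepoint_minutes, P``.
    """
    prot = proteins.set_index("protein_id")
    complete = prot[design.channel_ids].notna().all(axis=1)
    prot = prot.loc[complete]
    have = sites["protein_id"].isin(prot.index)
    n_excl = int((~have).sum())
    if n_excl:
        logger.info(
            "protein_normalize: excluding %d event(s) without complete proteome data",
            n_excl,
        )
    if report is not None:
        report.n_excluded_no_protein += n_excl
    kept = sites.loc[have].reset_index(drop=True)

    frames = []
    for strain in STRAINS:
        for ch in design.channels_for(strain):
            site_vals = kept[ch.channel_id].to_numpy(dtype=float)
            prot_vals = prot.loc[
                kept["protein_id"], ch.channel_id
            ].to_numpy(dtype=float)
            frames.append(
                pd.DataFrame(
                    {
                        "event_id": kept["event_id"],
                        "strain": strain,
                        "timepoint_index": ch.timepoint_index,
                        "timepoint_minutes": ch.timepoint_minutes,
                        "P": site_vals / prot_vals,
                    }
                )
            )
    traj = pd.concat(frames, ignore_index=True)
    bad = ~np.isfinite(traj["P"].to_numpy()) | (traj["P"].to_numpy() <= 0)
    if bad.any():
        # should not happen on filtered complete tables; guard anyway
        bad_events = set(traj.loc[bad, "event_id"])
        logger.warning(
            "protein_normalize: dropping %d event(s) with non-positive P",
            len(bad_events),
        )
        traj = traj.loc[~traj["event_id"].isin(bad_events)].reset_index(drop=True)
    if report is not None:
        report.n_events_out = traj["event_id"].nunique()
    return traj


def normalize_pipeline(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    design: ChannelDesign,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Run median -> T0 -> protein normalization end to end.

    ``sites`` should be the filtered event table; ``proteins`` the raw
    protein table (it receives the same median and T0 steps, computed over
    its own rows).
    """
    report = NormalizationReport(n_events_in=len(sites))
    s = median_normalize(sites, design)
    s = t0_normalize(s, design, report)
    p = median_normalize(proteins, design)
    p = t0_normalize(p, design)
    traj = protein_normalize(s, p, design, report)
    return traj, report


def trajectory_matrix(
    traj: pd.DataFrame, strain: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot the long trajectory table to an events x timepoints matrix.

    Returns (wide DataFrame indexed by event_id with timepoint_index
    columns, timepoint_minutes array aligned to the columns).
    """
    sub = traj[traj["strain"] == strain]
    wide = sub.pivot(index="event_id", columns="timepoint_index", values="P")
    wide = wide.sort_index(axis=1)
    minutes = (
        sub.drop_duplicates("timepoint_index")
        .set_index("timepoint_index")["timepoint_minutes"]
        .sort_index()
        .to_numpy()
    )
    return wide, minutes


def write_trajectories(traj: pd.DataFrame, path) -> None:
    traj.to_csv(path, sep="\t", index=False, float_format="%.12g")
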