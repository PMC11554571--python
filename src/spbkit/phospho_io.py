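"""Reading, validation and filtering of phospho-site / protein tables.

The input format follows MaxQuant-style "Phospho (STY) Sites" output reduced
to the columns this analysis consumes: one row per phosphorylation event
(site x multiplicity), per-channel reporter intensities, a localization
probability, and contaminant / reverse (decoy) flags.  A channel-design table
maps each TMT channel to a (strain, timepoint) of the two-strain time course.

Conventions
-----------
* An *event* is identified by (protein_id, site_position, residue,
  multiplicity); different multiplicities of the same site are distinct
  events.
* A reporter intensity of 0 or an empty cell is treated as *missing*: a zero
  reporter intensity is not quantifiable and would break ratio formation.
* All threshold comparisons are inclusive (localization probability >= 0.7
  is retained at exactly 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRAIN_TETHERED = "tethered"
STRAIN_CONTROL = "control"
STRAINS = (STRAIN_TETHERED, STRAIN_CONTROL)

HP_SENSITIVE = "HP_sensitive"
HP_INSENSITIVE = "HP_insensitive"
HP_UNCLASSIFIED = "unclassified"
HP_CLASSES = (HP_SENSITIVE, HP_INSENSITIVE, HP_UNCLASSIFIED)

LOCALIZATIONS = ("SPB_MT", "cytoplasm", "nucleus", "other", "unknown")

#: canonical metadata columns of a sites table, with accepted input aliases
SITE_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "protein_id": ("protein_id", "Protein", "Proteins"),
    "site_position": ("site_position", "Position"),
    "residue": ("residue", "Amino acid", "Amino Acid"),
    "multiplicity": ("multiplicity", "Multiplicity"),
    "localization_prob": (
        "localization_prob",
        "Localization prob",
        "Localisation prob",
    ),
    "is_contaminant": ("is_contaminant", "Potential contaminant", "Contaminant"),
    "is_reverse": ("is_reverse", "Reverse"),
}

SITE_METADATA_COLUMNS = tuple(SITE_COLUMN_ALIASES)


class FormatError(ValueError):
    """Input file does not have the expected columns / layout."""


class ValidationError(ValueError):
    """Input parsed but violates a structural invariant."""


@dataclass(frozen=True)
class Channel:
    """One TMT channel of the shared 10-plex: a (strain, timepoint) sample."""

    channel_id: str
    strain: str
    timepoint_index: int
    timepoint_minutes: float


class ChannelDesign:
    """The two-strain x timepoints layout of one TMT plex.

    Invariants: exactly one channel per (strain, timepoint_index); both
    strains carry the same ordered timepoint_index set; each strain includes
    index 0 (the T0 reference sample taken at inhibitor washout).
    """

    def __init__(self, channels: Iterable[Channel]):
        self.channels: tuple[Channel, ...] = tuple(channels)
        self._validate()

    def _validate(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate channel_id in design")
        keys = [(c.strain, c.timepoint_index) for c in self.channels]
        if len(set(keys)) != len(keys):
            raise ValidationError("more than one channel per (strain, timepoint)")
        bad = sorted({c.strain for c in self.channels} - set(STRAINS))
        if bad:
            raise ValidationError(f"unknown strain(s) in design: {bad}")
        per_strain = {
            s: sorted(c.timepoint_index for c in self.channels if c.strain == s)
            for s in STRAINS
        }
        if per_strain[STRAIN_TETHERED] != per_strain[STRAIN_CONTROL]:
            raise ValidationError("strains do not share the same timepoint set")
        for s, idx in per_strain.items():
            if 0 not in idx:
                raise ValidationError(f"strain {s!r} lacks a T0 channel")

    # -- accessors ---------------------------------------------------------
    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    @property
    def timepoint_indices(self) -> list[int]:
        return sorted(
            {c.timepoint_index for c in self.channels if c.strain == STRAINS[0]}
        )

    def minutes_of(self, timepoint_index: int) -> float:
        for c in self.channels:
            if c.timepoint_index == timepoint_index:
                return c.timepoint_minutes
        raise KeyError(timepoint_index)

    def channels_for(self, strain: str) -> list[Channel]:
        return sorted(
            (c for c in self.channels if c.strain == strain),
            key=lambda c: c.timepoint_index,
        )

    def channel_ids_for(self, strain: str) -> list[str]:
        return [c.channel_id for c in self.channels_for(strain)]

    def t0_channel(self, strain: str) -> Channel:
        return self.channels_for(strain)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "strain": [c.strain for c in self.channels],
                "timepoint_index": [c.timepoint_index for c in self.channels],
                "timepoint_minutes": [c.timepoint_minutes for c in self.channels],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()[["channel_id", "strain", "timepoint_minutes"]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelDesign":
        required = {"channel_id", "strain", "timepoint_minutes"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"design table missing column(s): {sorted(missing)}")
        channels = []
        for strain, grp in df.groupby("strain", sort=False):
            order = grp.sort_values("timepoint_minutes")
            for i, row in enumerate(order.itertuples(index=False)):
                channels.append(
                    Channel(
                        channel_id=str(row.channel_id),
                        strain=str(strain),
                        timepoint_index=i,
                        timepoint_minutes=float(row.timepoint_minutes),
                    )
                )
        return cls(channels)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ChannelDesign":
        """Read a 3-column design TSV (channel_id, strain, timepoint_minutes).

        timepoint_index is assigned per strain by ascending minutes, so T0 is
        the earliest sample of each strain (which must be minute 0 for the
        normalization to mean anything; validated downstream by usage).
        """
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.channels)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ChannelDesign({len(self.channels)} channels, "
            f"timepoints={self.timepoint_indices})"
        )


# ---------------------------------------------------------------------------
# sites / protein tables
# ---------------------------------------------------------------------------


def make_event_id(
    protein_id: str, site_position: int, residue: str, multiplicity: int
) -> str:
    return f"{protein_id}_{residue}{int(site_position)}_M{int(multiplicity)}"


def _resolve_columns(
    columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    """Map canonical names to whichever alias the file used."""
    out: dict[str, str] = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in columns:
                out[canonical] = name
                break
        else:
            raise FormatError(f"missing required column: {names[0]!r}")
    return out


def _parse_flag(series: pd.Series) -> pd.Series:
    """MaxQuant marks decoy/contaminant rows with '+'; accept booleans too."""
    truthy = {"+", "true", "yes", "1"}

    def one(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return False
        return str(v).strip().lower() in truthy

    return series.map(one).astype(bool)


def _parse_intensities(df: pd.DataFrame, channel_ids: Sequence[str]) -> pd.DataFrame:
    """Coerce channel columns to float; 0, empty and unparseable -> NaN."""
    out = {}
    for cid in channel_ids:
        vals = pd.to_numeric(df[cid], errors="coerce").astype(float)
        if (vals < 0).any():
            raise ValidationError(f"negative intensity in channel {cid!r}")
        vals = vals.mask(vals == 0.0)
        out[cid] = vals
    return pd.DataFrame(out, index=df.index)


def read_sites_table(path: str | Path, design: ChannelDesign) -> pd.DataFrame:
    """Read a phospho-site TSV into the canonical event table.

    Returns a DataFrame with columns ``event_id, protein_id, site_position,
    residue, multiplicity, localization_prob, is_contaminant, is_reverse``
    followed by one float column per design channel (NaN = missing).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    colmap = _resolve_columns(raw.columns, SITE_COLUMN_ALIASES)
    missing_ch = [c for c in design.channel_ids if c not in raw.columns]
    if missing_ch:
        raise FormatError(f"missing intensity column(s) for channels: {missing_ch}")

    table = pd.DataFrame(
        {
            "protein_id": raw[colmap["protein_id"]].astype(str),
            "site_position": pd.to_numeric(raw[colmap["site_position"]]).astype(int),
            "residue": raw[colmap["residue"]].astype(str),
            "multiplicity": pd.to_numeric(raw[colmap["multiplicity"]]).astype(int),
            "localization_prob": pd.to_numeric(
                raw[colmap["localization_prob"]]
            ).astype(float),
            "is_contaminant": _parse_flag(raw[colmap["is_contaminant"]]),
            "is_reverse": _parse_flag(raw[colmap["is_reverse"]]),
        }
    )
    bad_res = sorted(set(table["residue"]) - {"S", "T", "Y"})
    if bad_res:
        raise ValidationError(f"unexpected residue(s): {bad_res}")
    table.insert(
        0,
        "event_id",
        [
            make_event_id(p, s, r, m)
            for p, s, r, m in zip(
                table["protein_id"],
                table["site_position"],
                table["residue"],
                table["multiplicity"],
            )
        ],
    )
    dup = table["event_id"][table["event_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate event_id(s): {sorted(set(dup))[:5]}")
    intensities = _parse_intensities(raw, design.channel_ids)
    return pd.concat([table, intensities], axis=1)


def write_sites_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a sites table back to TSV (lossless round-trip with reader)."""
    out = table.drop(columns=["event_id"]).copy()
    out["is_contaminant"] = np.where(out["is_contaminant"], "+", "")
    out["is_reverse"] = np.where(out["is_reverse"], "+", "")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_protein_table(path: str | Path, design: ChannelDesign) -> pd.DataFrame:
    """Read the flow-through proteome table: protein_id + channel columns."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    name = None
    for cand in ("protein_id", "Protein", "Proteins", "Majority protein IDs"):
        if cand in raw.columns:
            name = cand
            break
    if name is None:
        raise FormatError("missing required column: 'protein_id'")
    missing_ch = [c for c in design.channel_ids if c not in raw.columns]
    if missing_ch:
        raise FormatError(f"missing intensity column(s) for channels: {missing_ch}")
    table = pd.DataFrame({"protein_id": raw[name].astype(str)})
    if table["protein_id"].duplicated().any():
        raise ValidationError("duplicate protein_id in protein table")
    return pd.concat([table, _parse_intensities(raw, design.channel_ids)], axis=1)


def write_protein_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the site-annotation TSV (event_id, hp_class, localization)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"event_id", "hp_class", "localization"} - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing column(s): {sorted(missing)}")
    if df["event_id"].duplicated().any():
        raise ValidationError("duplicate event_id in annotations")
    bad = sorted(set(df["hp_class"]) - set(HP_CLASSES))
    if bad:
        raise ValidationError(f"unknown hp_class value(s): {bad}")
    return df


# ---------------------------------------------------------------------------
# filtering and annotation
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Counts of events removed per filtering rule (rules applied jointly)."""

    n_input: int
    n_contaminant: int
    n_reverse: int
    n_low_localization: int
    n_incomplete: int
    n_retained: int

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_events(
    table: pd.DataFrame,
    design: ChannelDesign,
    min_loc_prob: float = 0.7,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep events that are clean, confidently localized, and complete.

    An event survives iff it is not a contaminant, not a reverse (decoy) hit,
    has localization probability >= ``min_loc_prob`` (inclusive), and has a
    quantified intensity in *every* channel of the design -- i.e. appears in
    all timepoints of both strains, which share one plex.  Ordering is
    preserved; filtering is idempotent.
    """
    intens = table[design.channel_ids]
    ok_contaminant = ~table["is_contaminant"]
    ok_reverse = ~table["is_reverse"]
    ok_loc = table["localization_prob"] >= min_loc_prob
    ok_complete = intens.notna().all(axis=1)
    keep = ok_contaminant & ok_reverse & ok_loc & ok_complete
    report = FilterReport(
        n_input=len(table),
        n_contaminant=int((~ok_contaminant).sum()),
        n_reverse=int((~ok_reverse).sum()),
        n_low_localization=int((~ok_loc).sum()),
        n_incomplete=int((~ok_complete).sum()),
        n_retained=int(keep.sum()),
    )
    return table.loc[keep].reset_index(drop=True), report


def join_annotations(
    table: pd.DataFrame, annotations: pd.DataFrame | None
) -> pd.DataFrame:
    """Attach hp_class / localization to each event.

    Events without an annotation get ``unclassified`` / ``unknown``.
    Annotations referencing an event_id absent from the table are logged as a
    warning and ignored.
    """
    out = table.copy()
    out["hp_class"] = HP_UNCLASSIFIED
    out["localization"] = "unknown"
    if annotations is None or len(annotations) == 0:
        return out
    known = set(out["event_id"])
    stray = [e for e in annotations["event_id"] if e not in known]
    if stray:
        logger.warning(
            "%d annotation(s) reference unknown event_ids (e.g. %s)",
            len(stray),
            stray[:3],
        )
    ann = annotations.set_index("event_id")
    hits = out["event_id"].isin(ann.index)
    out.loc[hits, "hp_class"] = ann.loc[out.loc[hits, "event_id"], "hp_class"].values
    out.loc[hits, "localization"] = ann.loc[
        out.loc[hits, "event_id"], "localization"
    ].values
    return out


def class_counts(annotated: pd.DataFrame) -> dict[str, int]:
    """Number of events per hp_class after annotation."""
    return annotated["hp_class"].value_counts().to_dict()
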