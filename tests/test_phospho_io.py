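"""Reading, filtering and annotation of phospho-site tables."""

import numpy as np
import pandas as pd
import pytest

from spbkit import phospho_io, phospho_synth
from spbkit.phospho_io import (
    Channel,
    ChannelDesign,
    FormatError,
    ValidationError,
    filter_events,
    join_annotations,
    read_sites_table,
    write_sites_table,
)


def _toy_design():
    chans = []
    k = 1
    for strain in ("tethered", "control"):
        for i, minutes in enumerate((0.0, 15.0)):
            chans.append(Channel(f"c{k}", strain, i, minutes))
            k += 1
    return ChannelDesign(chans)


def _toy_tsv(tmp_path, rows, channels=("c1", "c2", "c3", "c4"), drop_col=None):
    header = [
        "protein_id", "site_position", "residue", "multiplicity",
        "localization_prob", "is_contaminant", "is_reverse", *channels,
    ]
    if drop_col:
        header.remove(drop_col)
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in header))
    p = tmp_path / "toy.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p


def _row(protein="P1", pos=10, res="S", mult=1, loc=0.99, cont="", rev="", **intens):
    base = {
        "protein_id": protein, "site_position": pos, "residue": res,
        "multiplicity": mult, "localization_prob": loc,
        "is_contaminant": cont, "is_reverse": rev,
    }
    base.update(intens)
    return base


class TestChannelDesign:
    def test_roundtrip_and_indexing(self, tmp_path, design10):
        p = tmp_path / "design.tsv"
        design10.write_tsv(p)
        loaded = ChannelDesign.read_tsv(p)
        assert loaded.channel_ids == design10.channel_ids
        assert loaded.timepoint_indices == [0, 1, 2, 3, 4]
        assert loaded.t0_channel("control").timepoint_minutes == 0.0

    @pytest.mark.parametrize(
        "mutation",
        ["duplicate_channel", "missing_t0", "asymmetric"],
    )
    def test_invalid_designs_rejected(self, mutation):
        chans = [
            Channel("c1", "tethered", 0, 0.0),
            Channel("c2", "tethered", 1, 15.0),
            Channel("c3", "control", 0, 0.0),
            Channel("c4", "control", 1, 15.0),
        ]
        if mutation == "duplicate_channel":
            chans[1] = Channel("c2", "tethered", 0, 0.0)
        elif mutation == "missing_t0":
            chans = [c for c in chans if not (c.strain == "control" and c.timepoint_index == 0)]
            chans.append(Channel("c5", "control", 2, 30.0))
        elif mutation == "asymmetric":
            chans.append(Channel("c5", "control", 2, 30.0))
        with pytest.raises(ValidationError):
            ChannelDesign(chans)


class TestReadSitesTable:
    def test_parses_toy_table(self, tmp_path):
        design = _toy_design()
        rows = [
            _row(pos=1, c1=100, c2=200, c3=150, c4=50),
            _row(pos=2, c1=1.5, c2=2.5, c3=3.5, c4=4.5),
            _row(pos=3, res="T", c1=10, c2=10, c3=10, c4=10),
        ]
        table = read_sites_table(_toy_tsv(tmp_path, rows), design)
        assert len(table) == 3
        assert table[design.channel_ids].notna().all().all()
        assert table.loc[0, "event_id"] == "P1_S1_M1"

    def test_empty_and_zero_intensity_are_missing(self, tmp_path):
        design = _toy_design()
        rows = [_row(pos=1, c1="", c2=0, c3=5, c4=5)]
        table = read_sites_table(_toy_tsv(tmp_path, rows), design)
        assert np.isnan(table.loc[0, "c1"])
        assert np.isnan(table.loc[0, "c2"])
        assert table.loc[0, "c3"] == 5.0

    def test_missing_required_column_is_format_error(self, tmp_path):
        design = _toy_design()
        p = _toy_tsv(tmp_path, [_row(c1=1, c2=1, c3=1, c4=1)],
                     drop_col="localization_prob")
        with pytest.raises(FormatError, match="localization_prob"):
            read_sites_table(p, design)

    def test_missing_channel_column_is_format_error(self, tmp_path):
        design = _toy_design()
        p = _toy_tsv(tmp_path, [_row(c1=1, c2=1, c3=1)],
                     channels=("c1", "c2", "c3"))
        with pytest.raises(FormatError, match="c4"):
            read_sites_table(p, design)

    def test_duplicate_event_id_rejected(self, tmp_path):
        design = _toy_design()
        rows = [_row(pos=1, c1=1, c2=1, c3=1, c4=1)] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            read_sites_table(_toy_tsv(tmp_path, rows), design)

    def test_maxquant_style_aliases_accepted(self, tmp_path):
        design = _toy_design()
        header = ("Protein\tPosition\tAmino acid\tMultiplicity\t"
                  "Localization prob\tPotential contaminant\tReverse\t"
                  "c1\tc2\tc3\tc4\n")
        p = tmp_path / "mq.tsv"
        p.write_text(header + "P9\t44\tS\t2\t0.95\t\t+\t1\t2\t3\t4\n")
        table = read_sites_table(p, design)
        assert bool(table.loc[0, "is_reverse"])
        assert not bool(table.loc[0, "is_contaminant"])
        assert table.loc[0, "multiplicity"] == 2

    def test_roundtrip_write_read(self, tmp_path, small_sim):
        p = tmp_path / "rt.tsv"
        write_sites_table(small_sim.sites, p)
        back = read_sites_table(p, small_sim.design)
        pd.testing.assert_frame_equal(
            back, small_sim.sites, check_exact=False, rtol=1e-9
        )


class TestFilterEvents:
    def test_joint_rules(self, tmp_path):
        design = _toy_design()
        rows = [
            _row(pos=1, cont="+", c1=1, c2=1, c3=1, c4=1),
            _row(pos=2, rev="+", c1=1, c2=1, c3=1, c4=1),
            _row(pos=3, loc=0.6, c1=1, c2=1, c3=1, c4=1),
            _row(pos=4, c1="", c2=1, c3=1, c4=1),
            _row(pos=5, c1=1, c2=1, c3=1, c4=1),
        ]
        table = read_sites_table(_toy_tsv(tmp_path, rows), design)
        kept, report = filter_events(table, design)
        assert list(kept["site_position"]) == [5]
        assert report.n_retained == 1
        assert report.n_contaminant == 1 and report.n_reverse == 1
        assert report.n_low_localization == 1 and report.n_incomplete == 1

    def test_localization_boundary_inclusive(self, tmp_path):
        design = _toy_design()
        rows = [_row(pos=1, loc=0.70, c1=1, c2=1, c3=1, c4=1)]
        table = read_sites_table(_toy_tsv(tmp_path, rows), design)
        kept, _ = filter_events(table, design)
        assert len(kept) == 1

    def test_multiplicities_are_separate_events(self, tmp_path):
        design = _toy_design()
        rows = [
            _row(pos=7, mult=1, c1=1, c2=1, c3=1, c4=1),
            _row(pos=7, mult=2, c1=1, c2=1, c3=1, c4=1),
        ]
        table = read_sites_table(_toy_tsv(tmp_path, rows), design)
        kept, _ = filter_events(table, design)
        assert len(kept) == 2
        assert set(kept["event_id"]) == {"P1_S7_M1", "P1_S7_M2"}

    def test_idempotent_and_never_grows(self, small_sim):
        once, _ = filter_events(small_sim.sites, small_sim.design)
        twice, rep2 = filter_events(once, small_sim.design)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(small_sim.sites)
        assert rep2.n_retained == rep2.n_input

    def test_identity_on_clean_complete_table(self):
        params = phospho_synth.PhosphoSimParams(
            n_events=50, n_decoys=0, n_contaminants=0,
            loc_prob_below_frac=0.0, seed=3,
        )
        sim = phospho_synth.generate_phospho_dataset(params)
        kept, _ = filter_events(sim.sites, sim.design, min_loc_prob=0.0)
        pd.testing.assert_frame_equal(
            kept, sim.sites.reset_index(drop=True)
        )


class TestJoinAnnotations:
    def test_counts_and_defaults(self, small_sim):
        filt, _ = filter_events(small_sim.sites, small_sim.design)
        sub_ann = small_sim.annotations.iloc[:2]
        out = join_annotations(filt, sub_ann)
        counts = phospho_io.class_counts(out)
        annotated_present = sub_ann["event_id"].isin(filt["event_id"]).sum()
        assert counts.get("unclassified", 0) == len(filt) - annotated_present

    def test_empty_annotations_all_unclassified(self, small_sim):
        filt, _ = filter_events(small_sim.sites, small_sim.design)
        out = join_annotations(filt, None)
        assert (out["hp_class"] == "unclassified").all()
        assert (out["localization"] == "unknown").all()

    def test_unknown_event_warns_not_errors(self, small_sim, caplog):
        filt, _ = filter_events(small_sim.sites, small_sim.design)
        stray = pd.DataFrame(
            {"event_id": ["NOPE_S1_M1"], "hp_class": ["HP_sensitive"],
             "localization": ["nucleus"]}
        )
        with caplog.at_level("WARNING"):
            out = join_annotations(filt, stray)
        assert "unknown event_id" in caplog.text
        assert (out["hp_class"] == "unclassified").all()
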