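import numpy as np
import pytest

from spbkit import imaging_synth, phospho_io, phospho_synth


@pytest.fixture(scope="session")
def design10():
    """Two strains x 5 timepoints sharing one 10-plex."""
    return phospho_synth.make_design()


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulated dataset shared by read-only tests."""
    params = phospho_synth.PhosphoSimParams(n_events=300, seed=11)
    return phospho_synth.generate_phospho_dataset(params)


@pytest.fixture(scope="session")
def still_field():
    """A small noisy still field with spots, shared by read-only tests."""
    params = imaging_synth.ImagingSimParams(
        n_cells=5,
        field_size_px=(900, 900),
        seed=7,
        frac_cells_with_cyclin_spot=0.6,
    )
    return imaging_synth.generate_cell_field(params)


def write_design_tsv(path, design):
    design.write_tsv(path)
    return path


@pytest.fixture()
def sites_tsv(tmp_path, small_sim):
    p = tmp_path / "sites.tsv"
    phospho_io.write_sites_table(small_sim.sites, p)
    return p


def iou_per_truth_cell(labels: np.ndarray, truth_masks: np.ndarray) -> list[float]:
    """Best-overlap IoU of each ground-truth cell against predicted labels."""
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
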