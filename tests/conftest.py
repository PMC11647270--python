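import numpy as np
import pytest

import spotsim as s


@pytest.fixture(scope="session")
def small_prior():
    return s.make_sc_prior(300, 3, seed=7)


@pytest.fixture(scope="session")
def small_cfg():
    return s.SimConfig(
        n_genes=300,
        n_cell_types=3,
        n_spots=80,
        array_rows=30,
        array_cols=30,
        n_cells_per_type=500,
        p_de=0.1,
    )


@pytest.fixture(scope="session")
def tissue_run(small_prior, small_cfg):
    """One simulated tissue shared by read-only tests."""
    sc, gt, qc, st_m = s.simulate_tissue(small_prior, small_cfg, seed=42)
    return {"sc": sc, "gt": gt, "qc": qc, "st_m": st_m}


@pytest.fixture()
def toy_spots():
    """A 3-spot, 3-gene dataset with one background and one empty spot."""
    positions = np.array([[0, 0], [0, 2], [1, 1], [2, 0]])
    counts = np.array(
        [
            [5, 0, 2],
            [0, 0, 0],  # occupied but empty
            [1, 3, 0],
            [0, 0, 0],  # background
        ]
    )
    is_tissue = np.array([True, True, True, False])
    condition = np.array(["A", "A", "B", ""], dtype=object)
    composition = np.array([[2, 0], [1, 0], [0, 3], [0, 0]])
    return s.SpotDataset(
        counts,
        np.array(["g0", "g1", "g2"], dtype=object),
        np.array(["ct0", "ct1"], dtype=object),
        positions,
        is_tissue,
        condition,
        composition,
        stage="ST-M",
    )
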