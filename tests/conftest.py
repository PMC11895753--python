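import logging

import numpy as np
import pandas as pd
import pytest

from paleopairs.occurrences import Dataset, OccurrenceMatrix, Site

logging.getLogger("paleopairs").setLevel(logging.ERROR)


@pytest.fixture
def tiny_sites():
    return [
        Site("m1", 44.5, -108.5, "Cf3", "mammal"),
        Site("m2", 44.6, -108.4, "Cf3", "mammal"),
        Site("m3", 45.0, -108.2, "Wa0", "mammal"),
        Site("f1", 44.5, -108.6, "Cf3", "palynofloral"),
        Site("f2", 45.1, -108.1, "Wa0", "palynofloral"),
        Site("f3", 44.9, -109.0, "Wa1_2", "palynofloral"),
    ]


@pytest.fixture
def tiny_matrix():
    """3 species x 4 sites, hand-checkable."""
    cells = np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    return OccurrenceMatrix(["a", "b", "c"], ["s1", "s2", "s3", "s4"], cells, "Cf3")


@pytest.fixture
def hand_dataset(tiny_sites):
    """Fully consistent miniature dataset spanning all three biozones."""
    mam_cf3 = OccurrenceMatrix(
        ["spA", "spB"], ["m1", "m2"], np.array([[1, 1], [1, 0]]), "Cf3"
    )
    mam_wa0 = OccurrenceMatrix(["spA"], ["m3"], np.array([[1]]), "Wa0")
    flo_cf3 = OccurrenceMatrix(["tX", "tY"], ["f1"], np.array([[1], [1]]), "Cf3")
    flo_wa0 = OccurrenceMatrix(["tY"], ["f2"], np.array([[1]]), "Wa0")
    flo_wa12 = OccurrenceMatrix(["tZ"], ["f3"], np.array([[1]]), "Wa1_2")
    traits = pd.DataFrame({"species_id": ["spA", "spB"], "ln_mass": [2.0, 5.0]})
    return Dataset(
        sites=tiny_sites,
        mammal_matrices={"Cf3": mam_cf3, "Wa0": mam_wa0},
        floral_matrices={"Cf3": flo_cf3, "Wa0": flo_wa0, "Wa1_2": flo_wa12},
        traits=traits,
    )


def random_binary_matrix(rng, n_rows, n_cols, fill=0.4, biozone="Cf3"):
    """A validated random occurrence matrix (no empty rows/columns)."""
    cells = (rng.random((n_rows, n_cols)) < fill).astype(np.int8)
    for i in np.nonzero(cells.sum(axis=1) == 0)[0]:
        cells[i, rng.integers(n_cols)] = 1
    for j in np.nonzero(cells.sum(axis=0) == 0)[0]:
        cells[rng.integers(n_rows), j] = 1
    species = [f"sp{i:03d}" for i in range(n_rows)]
    sites = [f"s{j:03d}" for j in range(n_cols)]
    return OccurrenceMatrix(species, sites, cells, biozone)
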