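import numpy as np
import pandas as pd
import pytest

from enterotools import io, simulate
from enterotools.io import AbundanceTable


@pytest.fixture
def small_table():
    """3 taxa x 2 samples with lineages (two OTUs share a genus)."""
    return AbundanceTable(
        taxon_ids=["OTU1", "OTU2", "OTU3"],
        sample_ids=["A", "B"],
        counts=np.array([[5, 0], [3, 2], [0, 7]]),
        lineages=[
            "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Segatella",
            "Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;Bacteroidaceae;Segatella",
            "Bacteria;Bacillota;Clostridia;Eubacteriales;Lachnospiraceae;Blautia",
        ],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic cohort at the default study scale (n=95)."""
    return simulate.generate(simulate.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_profiles(default_dataset):
    return io.to_relative(default_dataset.table)


def random_probability_vector(rng, size):
    v = rng.dirichlet(np.ones(size))
    return v / v.sum()
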