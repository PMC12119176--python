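import numpy as np
import pytest

from kelpniche import GridGeoref, default_world


@pytest.fixture(scope="session")
def world():
    """The default synthetic study system (seed 1), shared read-only."""
    return default_world(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240923)


@pytest.fixture
def small_georef():
    return GridGeoref(west=0.0, north=10.0, dx=1.0, dy=1.0, n_rows=10, n_cols=10)


def write_occurrence_csv(path, rows, header="species,genus,order,decimalLatitude,decimalLongitude,year"):
    """Write a raw GBIF-style CSV from a list of row strings."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(row + "\n")
    return path
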