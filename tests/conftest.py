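import io

import numpy as np
import pandas as pd
import pytest

from ipdmeta import dataio, synthdata


@pytest.fixture(scope="session")
def example_data():
    """The frozen 15-study synthetic dataset shipped with the package."""
    return synthdata.load_example()


@pytest.fixture(scope="session")
def example_csv_path():
    from importlib.resources import files

    return str(files("ipdmeta") / "data" / "synthetic_ipd.csv")


def make_dataset(rows, **kwargs):
    """Build a validated dataset from (study, test, disease, *covs) tuples."""
    columns = kwargs.pop("columns", ["Study", "test.results", "disease"])
    return dataio.from_frame(pd.DataFrame(rows, columns=columns), **kwargs)


@pytest.fixture
def tiny_data():
    """Two studies with clean separation structure for threshold tests."""
    rows = []
    for study, vals, dis in [
        ("A", [1, 2, 3], 0),
        ("A", [4, 5, 6], 1),
        ("B", [1, 3, 5], 0),
        ("B", [2, 4, 6], 1),
    ]:
        rows += [(study, v, dis) for v in vals]
    return make_dataset(rows)


def csv_buffer(text: str) -> io.StringIO:
    return io.StringIO(text)
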