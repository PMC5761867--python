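import io

import numpy as np
import pandas as pd
import pytest

from hetsvar import data_io, simulate


@pytest.fixture
def tiny_csv():
    """Three-day panel with hand-checkable counts."""
    return io.StringIO(
        "date,law,minorities,whites,twitter\n"
        "2015-01-01,0,1,2,937\n"
        "2015-01-02,1,0,1,3320\n"
        "2015-01-03,5,2,0,56000\n"
    )


@pytest.fixture
def count_series():
    dates = pd.date_range("2015-01-01", periods=6, freq="D")
    return data_io.DailyCountSeries("law", dates, np.array([0, 1, 6, 0, 2, 3320]))


@pytest.fixture(scope="session")
def paper_truth():
    return simulate.paper_preset(seed=11)


@pytest.fixture(scope="session")
def paper_panel(paper_truth):
    return simulate.generate(paper_truth, T=639)


def make_transformed(values, name="x", start="2015-01-01", differenced=False):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return data_io.TransformedSeries(name, dates, values, differenced=differenced)
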