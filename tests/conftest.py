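import numpy as np
import pandas as pd
import pytest

from spaceanova import CellTable, RadiusGrid, Window, simulate_csri


@pytest.fixture
def unit_window():
    return Window(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def grid100():
    return RadiusGrid.from_step(100.0, 1.0)


@pytest.fixture
def csri_pattern(unit_window):
    return simulate_csri(unit_window, {"A": 500, "B": 500}, seed=7)


def make_table(rows):
    """Build a CellTable from (x, y, cell_type, image_id, subject_id, group) tuples."""
    df = pd.DataFrame(rows, columns=["x", "y", "cell_type", "image_id", "subject_id", "group"])
    return CellTable.from_dataframe(df, allow_duplicates=True)


@pytest.fixture
def tiny_table():
    rows = []
    rng = np.random.default_rng(0)
    for img, sub, grp in [("i1", "s1", "g1"), ("i2", "s1", "g1"), ("i3", "s2", "g2")]:
        for t in ("A", "B"):
            for _ in range(5):
                rows.append((rng.uniform(0, 100), rng.uniform(0, 100), t, img, sub, grp))
    return make_table(rows)
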