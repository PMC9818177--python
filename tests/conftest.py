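import numpy as np
import pandas as pd
import pytest

from methyldriver.io_formats import SampleSheet


@pytest.fixture
def small_sheet() -> SampleSheet:
    """3 cases vs 2 controls."""
    return SampleSheet(
        ("CASE1", "CASE2", "CASE3", "CTRL1", "CTRL2"),
        ("CASE", "CASE", "CASE", "CONTROL", "CONTROL"),
    )


@pytest.fixture
def cohort_sheet() -> SampleSheet:
    """5 cases vs 6 controls, the default study design."""
    ids = tuple(f"CASE{i}" for i in range(1, 6)) + tuple(f"CTRL{i}" for i in range(1, 7))
    return SampleSheet(ids, ("CASE",) * 5 + ("CONTROL",) * 6)


def make_beta(values, sheet, probe_ids=None) -> pd.DataFrame:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if probe_ids is None:
        probe_ids = [f"cg{i:04d}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=probe_ids, columns=list(sheet.sample_ids))
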