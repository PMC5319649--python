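import numpy as np
import pandas as pd
import pytest

from pitcherchem.peak_tables import QUALITATIVE, QUANTITATIVE, CompoundTable


def make_table(rows, mode, samples=None, compounds=None, meta=None):
    """Build a CompoundTable straight from a nested list / array."""
    arr = np.asarray(rows, dtype=float)
    samples = samples or [f"S{i+1}" for i in range(arr.shape[0])]
    compounds = compounds or [f"C{j+1}" for j in range(arr.shape[1])]
    values = pd.DataFrame(arr, index=pd.Index(samples, name="sample_id"),
                          columns=compounds)
    return CompoundTable(values=values, mode=mode, meta=meta)


@pytest.fixture
def binary_table():
    return make_table(
        [[1, 0, 1], [1, 1, 0], [0, 0, 0]], QUALITATIVE
    )


@pytest.fixture
def quant_table():
    return make_table(
        [[25.0, 0.0, 75.0], [100.0, 0.0, 0.0], [0.0, 0.0, 0.0]], QUANTITATIVE
    )
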