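import numpy as np
import pytest

from irtmiss.datagen import DesignCell, ItemBank, ResponseData, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One N=1500 dataset at delta=-1, 10% missing, with truth and complete X."""
    cell = DesignCell(delta=-1.0, missing_rate=0.10)
    data, truth, complete = generate_dataset(cell, 20, return_complete=True)
    return data, truth, complete


@pytest.fixture(scope="session")
def mixed_bank():
    """Small bank with both CR and MC items."""
    return ItemBank(
        item_id=np.array(["c1", "c2", "m1", "m2"]),
        discrimination=np.ones(4),
        difficulty=np.array([-1.0, 0.0, 0.5, 1.0]),
        format=np.array(["CR", "CR", "MC", "MC"], dtype=object),
        n_options=np.array([np.nan, np.nan, 4.0, 5.0]),
        beta=np.zeros(4),
        delta=np.zeros(4),
    )


def make_response_data(observed):
    observed = np.asarray(observed, dtype=float)
    r = (~np.isnan(observed)).astype(np.int8)
    return ResponseData(observed=observed, indicators=r,
                        administered=np.ones_like(r))


@pytest.fixture
def tiny_data():
    """4 persons x 4 items with assorted missing cells."""
    nan = np.nan
    return make_response_data(
        [
            [1, 0, 1, 0],
            [1, nan, 0, nan],
            [nan, nan, 1, 1],
            [0, 1, nan, nan],
        ]
    )
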