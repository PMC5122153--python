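import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def trio_pedigree():
    """Sire, dam and their offspring."""
    return pd.DataFrame(
        {"animal": ["S", "D", "O"], "sire": [None, None, "S"], "dam": [None, None, "D"]}
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the full-sib mating."""
    return pd.DataFrame(
        {
            "animal": ["A", "B", "C", "D", "E"],
            "sire": [None, None, "A", "A", "C"],
            "dam": [None, None, "B", "B", "D"],
        }
    )
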