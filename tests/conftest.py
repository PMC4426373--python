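import numpy as np
import pandas as pd
import pytest

from smoltqg.pedigree import pedigree_from_frame


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return pedigree_from_frame(
        pd.DataFrame(
            {
                "id": ["s", "d", "o"],
                "sire": ["0", "0", "s"],
                "dam": ["0", "0", "d"],
                "generation": ["P1", "P1", "F1"],
                "cross_type": ["founder", "founder", "AxA"],
                "family": ["0", "0", "f1"],
            }
        )
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Full sibs mated: the offspring has F = 0.25."""
    rows = [
        ("gs", "0", "0"), ("gd", "0", "0"),
        ("a", "gs", "gd"), ("b", "gs", "gd"),
        ("x", "a", "b"),
    ]
    return pedigree_from_frame(
        pd.DataFrame(rows, columns=["id", "sire", "dam"]).assign(
            generation="G", cross_type="AxA", family="f"
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151)
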