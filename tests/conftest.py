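import numpy as np
import pandas as pd
import pytest

from heatnorm.kinship import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pedigree():
    """Five animals: two founders, two full sibs, one inbred offspring."""
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["s", "d", "x", "y", "z"],
                "sire": [0, 0, "s", "s", "x"],
                "dam": [0, 0, "d", "d", "y"],
            }
        )
    )


def make_records(
    n_animals=6,
    tests_per_animal=5,
    herd="h1",
    start="2005-01-10",
    milk=10.0,
    age=30.0,
    dim0=10,
    spacing=40,
):
    """Small compliant test-day table (one herd, one calendar month per test)."""
    rows = []
    start = pd.Timestamp(start)
    for a in range(n_animals):
        for t in range(tests_per_animal):
            rows.append(
                {
                    "animal": f"c{a + 1}",
                    "herd": herd,
                    "date": start + pd.Timedelta(days=spacing * t),
                    "dim": dim0 + spacing * t,
                    "milk_kg": milk,
                    "age_months": age,
                    "milking_freq": "2x",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def compliant_records():
    return make_records()


@pytest.fixture
def toy_parents():
    return pd.DataFrame(
        {
            "animal": [f"c{i}" for i in range(1, 9)],
            "sire": ["s1"] * 8,
            "dam": [0] * 8,
        }
    )
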