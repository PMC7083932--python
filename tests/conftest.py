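import numpy as np
import pandas as pd
import pytest

from prpscan import AbundanceTable, SpectralCountTable


@pytest.fixture()
def small_counts() -> SpectralCountTable:
    """Three proteins (plus albumin) over six samples, two subjects x three
    trimesters, with hand-pickable numbers."""
    samples = ["s1t1", "s2t1", "s1t2", "s2t2", "s1t3", "s2t3"]
    counts = pd.DataFrame(
        {
            "s1t1": [480, 12, 48, 480],
            "s2t1": [480, 0, 48, 480],
            "s1t2": [480, 96, 12, 480],
            "s2t2": [480, 96, 12, 480],
            "s1t3": [480, 48, 24, 480],
            "s2t3": [480, 48, 24, 480],
        },
        index=["ALBU", "UP", "DOWN", "FLAT"],
    )
    design = pd.DataFrame(
        {
            "subject": [1, 2, 1, 2, 1, 2],
            "trimester": [1, 1, 2, 2, 3, 3],
            "species": "test",
        },
        index=samples,
    )
    return SpectralCountTable(counts=counts, design=design)


def abundance_from_values(values: pd.DataFrame, trimesters: list[int]) -> AbundanceTable:
    design = pd.DataFrame(
        {"subject": range(len(values.columns)), "trimester": trimesters, "species": "test"},
        index=values.columns,
    )
    return AbundanceTable(values=values, design=design, reference_id="ALB", scale=100.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240317)
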