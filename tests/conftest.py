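import numpy as np
import pandas as pd
import pytest

from tfcooc import (
    GenomeWindow,
    MotifGroupMap,
    MotifMatrix,
    PlantedSpec,
    SampleSheet,
    end_to_end_fixture,
)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study, shared across tests that only read it."""
    return end_to_end_fixture(PlantedSpec(seed=0))


@pytest.fixture
def two_ct_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"],
                "cell_type": ["A"] * 4 + ["B"] * 4,
            }
        )
    )


@pytest.fixture
def toy_motif():
    """Width-3 motif with consensus ACG and strong base preference."""
    counts = np.array(
        [
            [9, 1, 1, 1],
            [1, 9, 1, 1],
            [1, 1, 9, 1],
        ]
    )
    return MotifMatrix("M_ACG", "ACG", counts)


def make_windows(n, width=200, chrom="chr1"):
    return [GenomeWindow(chrom, i * width, (i + 1) * width) for i in range(n)]


@pytest.fixture
def group_map_abc():
    return MotifGroupMap({"m1": "A", "m2": "A", "m3": "B", "m4": "C"})
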