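import numpy as np
import pytest

from neutralassembly.otu_io import CommunitySAD, GroupMap, OTUTable


@pytest.fixture
def small_table() -> OTUTable:
    counts = np.array(
        [
            [5, 0, 1, 1],
            [2, 3, 0, 0],
            [0, 0, 0, 7],
        ]
    )
    return OTUTable(counts, ["s1", "s2", "s3"], ["otuA", "otuB", "otuC", "otuD"])


@pytest.fixture
def small_groups() -> GroupMap:
    return GroupMap({"s1": "lean", "s2": "obese", "s3": "lean"})


@pytest.fixture
def sad_75() -> CommunitySAD:
    # counts (0, 5, 1, 1) -> D = (5, 1, 1)
    return CommunitySAD.from_counts([0, 5, 1, 1])
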