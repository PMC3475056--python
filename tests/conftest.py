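import numpy as np
import pandas as pd
import pytest

from ncisnorm import GenomeLayout


@pytest.fixture
def layout():
    return GenomeLayout(("chrA", "chrB"), (1000, 600))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_tags(chroms, positions, strands=None):
    n = len(positions)
    if strands is None:
        strands = ["+"] * n
    if isinstance(chroms, str):
        chroms = [chroms] * n
    return pd.DataFrame({"chrom": chroms,
                         "pos": np.asarray(positions, dtype=np.int64),
                         "strand": strands})


@pytest.fixture
def tags_factory():
    return make_tags
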