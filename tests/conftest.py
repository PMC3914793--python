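import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from paircn.core import GenomeGrid, RatioProfile


@pytest.fixture
def toy_grid() -> GenomeGrid:
    """Two 100 kb chromosomes, probes every 10 kb at 5k, 15k, ..., 95k.

    Probe bp intervals are exactly [1,10k), [10k,20k), ..., [90k,100k+1),
    so bp-weighted statistics have round expected values.
    """
    return GenomeGrid.uniform({"1": 100_000, "2": 100_000}, spacing_bp=10_000)


@pytest.fixture
def make_profile():
    def _make(grid, log2, sample_id="s", role="primary", site="none", cellularity=1.0):
        return RatioProfile(sample_id, role, site, grid, np.asarray(log2, float), cellularity)

    return _make
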