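import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from finishkit.core_io import LinkRecord
from finishkit.contig_graph import build_graph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_copy_repeat_graph():
    """Circular genome U1 R U2 R with a 2-copy repeat: unique traversal."""
    lengths = {"U1": 20_000, "R": 3_000, "U2": 25_000}
    coverage = {"U1": 20.0, "R": 41.0, "U2": 19.5}
    links = [
        LinkRecord("U1", "E", "R", "B", 3, 0),
        LinkRecord("R", "E", "U2", "B", 3, 0),
        LinkRecord("U2", "E", "R", "B", 3, 0),
        LinkRecord("R", "E", "U1", "B", 3, 0),
    ]
    return build_graph(lengths, links, coverage)


@pytest.fixture
def three_copy_repeat_graph():
    """Circular genome U1 R U2 R U3 R: two distinct interleavings."""
    lengths = {"U1": 20_000, "R": 3_000, "U2": 25_000, "U3": 30_000}
    coverage = {"U1": 20.0, "R": 61.0, "U2": 19.0, "U3": 21.0}
    links = [
        LinkRecord("U1", "E", "R", "B", 3, 0),
        LinkRecord("R", "E", "U2", "B", 3, 0),
        LinkRecord("U2", "E", "R", "B", 3, 0),
        LinkRecord("R", "E", "U3", "B", 3, 0),
        LinkRecord("U3", "E", "R", "B", 3, 0),
        LinkRecord("R", "E", "U1", "B", 3, 0),
    ]
    return build_graph(lengths, links, coverage)
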