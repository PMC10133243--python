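import numpy as np
import pytest

from panmorph import CellRecord, SlideTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_truth(n, cls="cancer", seed=0, extent=1000.0):
    """Uniformly scattered annotation table of one class."""
    r = np.random.default_rng(seed)
    cells = [
        CellRecord(f"{cls[:3]}{i}", float(x), float(y), cls)
        for i, (x, y) in enumerate(r.uniform(0, extent, size=(n, 2)))
    ]
    return SlideTable("t", "SYN", 1.0, cells)


def make_mixed_truth(n_per_class, seed=0, extent=1000.0):
    r = np.random.default_rng(seed)
    cells = []
    for cls, n in n_per_class.items():
        for i, (x, y) in enumerate(r.uniform(0, extent, size=(n, 2))):
            cells.append(CellRecord(f"{cls[:3]}{i}", float(x), float(y), cls))
    return SlideTable("t", "SYN", 1.0, cells)
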