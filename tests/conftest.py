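import numpy as np
import pytest

from oligofish.io_formats import CellSignal, ProbeAssay


def make_cells(signatures, sample_id="S1", assay=ProbeAssay.CHR1):
    """Build a cell list from (R, G) pairs or 'R/G' strings."""
    cells = []
    for i, sig in enumerate(signatures):
        if isinstance(sig, str):
            r, g = (int(x) for x in sig.split("/"))
        else:
            r, g = sig
        cells.append(CellSignal(sample_id, assay, f"c{i + 1}", r, g))
    return cells


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
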