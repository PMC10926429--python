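import pytest

from amplihap import demo_panel
from amplihap.readproc import ReadPair


@pytest.fixture(scope="session")
def panel():
    """Synthetic nine-locus reference panel (deterministic)."""
    return demo_panel(seed=11)


@pytest.fixture(scope="session")
def wg(panel):
    """One representative 410-bp locus."""
    return panel["pWg"]


def pairs_from_records(reads1, reads2):
    """Zip simulator output into ReadPair objects."""
    return [
        ReadPair(a[0], a[1], a[2], b[1], b[2])
        for a, b in zip(reads1, reads2, strict=True)
    ]
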