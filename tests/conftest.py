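import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/helpers.py

from homeoplex import catalog as cat
from homeoplex import synthgen as sg


@pytest.fixture(scope="session")
def refs():
    """The prepared A/B/D homoeolog reference panel (seed 1, ~92% identity)."""
    return cat.prepare_panel(sg.generate_references(1))


@pytest.fixture(scope="session")
def barcodes():
    return sg.make_barcodes(96)
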