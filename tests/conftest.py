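import pytest
from hypothesis import settings

from plasmidshot.seqio import random_plasmid

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template_2319():
    """Plasmid-scale synthetic template (pLEXSY-like length, mid GC)."""
    return random_plasmid(2319, 0.55, seed=11)


@pytest.fixture(scope="session")
def template_small():
    """Small template for exhaustive checks."""
    return random_plasmid(400, 0.5, seed=5)
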