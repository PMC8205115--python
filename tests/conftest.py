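import numpy as np
import pytest
from hypothesis import settings

from ampligeno import default_templates, synthetic_assay

settings.register_profile("suite", max_examples=50, derandomize=True,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def assay():
    """Synthetic two-motif assay (no filter motifs)."""
    return synthetic_assay("GeneA", seed=11)


@pytest.fixture
def filtered_assay():
    """Synthetic assay carrying one filter motif."""
    return synthetic_assay("GeneF", seed=12, n_filter=1)


@pytest.fixture
def templates(assay):
    return default_templates(assay, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def embed(motif, rng, left=30, right=40):
    """Random read carrying a motif once, used as a minimal test read."""
    bases = "ACGT"
    flank = lambda n: "".join(bases[i] for i in rng.integers(0, 4, size=n))
    return flank(left) + motif + flank(right)
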