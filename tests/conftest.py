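import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_alignment():
    """5-taxon gap-free alignment with focal-unique residues at columns 2 and 6."""
    from lineasig.msa_unique_residues import Alignment

    rows = (
        ("focal",  "MKWLTAHG"),
        ("taxon1", "MKRLTAQG"),
        ("taxon2", "MKRLTAQG"),
        ("taxon3", "MKRITAQG"),
        ("taxon4", "MKRLSAQG"),
    )
    return Alignment("toy", rows, "focal")
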