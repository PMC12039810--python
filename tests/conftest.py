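import pytest

from neoscan import build_index
from neoscan.simulate import SimConfig, make_locus, simulate_synthesis


@pytest.fixture(scope="session")
def ref_locus():
    """Reference-architecture synthetic locus (280 nt, 120-nt template)."""
    return make_locus(seed=1)


@pytest.fixture(scope="session")
def ref_index(ref_locus):
    return build_index(
        ref_locus.sequence, 11,
        template_interval=(ref_locus.template_start, ref_locus.template_end),
    )


@pytest.fixture(scope="session")
def small_sims(ref_locus):
    """300 simulated molecules with ground truth (no sequencing errors)."""
    config = SimConfig(locus=ref_locus, n_reads=300, seed=42)
    return simulate_synthesis(config)
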