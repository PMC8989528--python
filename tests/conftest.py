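import pytest

from lesionmux.constructs import (build_construct, make_barcode_oligo,
                                  make_lesion_oligo, random_genome_stub)
from lesionmux.designs import design_layouts
from lesionmux.simulate import SimulationConfig, simulate_reads


@pytest.fixture(scope="session")
def small_stub():
    return random_genome_stub(400, seed=7)


@pytest.fixture(scope="session")
def small_layout(small_stub):
    """A compact lesion construct (TXG context) for unit tests."""
    return build_construct(
        small_stub, make_barcode_oligo("ACG"), make_lesion_oligo("TXG"),
        150, base_identity="oxoeA", region_of_interest=(150, 190))


@pytest.fixture(scope="session")
def txg_lesion_mix():
    return design_layouts("txg_lesion")


def simulate_sample(mix, tmp_dir, **overrides):
    """Helper: run the simulator with defaults suitable for tests."""
    params = dict(genome_mix=mix, n_read_pairs=1000, seed=11)
    params.update(overrides)
    cfg = SimulationConfig(**params)
    return cfg, simulate_reads(cfg, tmp_dir)
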