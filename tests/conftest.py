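import pytest

from plastovar.records import PlastomeRecord
from plastovar.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """6 samples in two clades plus two hybrids, on a 7 kb quadripartite genome."""
    guide = "((S1:0.1,S2:0.1):0.3,(S3:0.1,S4:0.1):0.3,(S5:0.1,S6:0.1):0.3);"
    cfg = SimulationConfig(
        seed=5, n_samples=6, guide_tree=guide,
        lsc_len=4000, ir_len=1200, ssc_len=600,
        hybrids=[("H1", "S1", 5), ("H4", "S4", 5)],
    )
    records, truth, backbone = simulate_population(cfg)
    return cfg, records, truth, backbone


@pytest.fixture(scope="session")
def plain_backbone():
    cfg = SimulationConfig(seed=3, n_samples=4, lsc_len=4000, ir_len=1200, ssc_len=600)
    _records, _truth, backbone = simulate_population(cfg)
    return cfg, backbone


@pytest.fixture
def tiny_record():
    return PlastomeRecord(id="tiny", sequence="ACGTACGTTGCA")
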