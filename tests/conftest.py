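import numpy as np
import pytest

from vernadyn.simulate import GenotypeParams, SimulationConfig, simulate_expression


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def exact_two_phase():
    """Noiseless two-phase expression table with known features."""
    cfg = SimulationConfig(
        genotypes=[GenotypeParams("g1", 20.0, 0.2, 0.15),
                   GenotypeParams("g2", 12.0, 0.1, 0.05)],
        timepoints=(10, 20, 30, 40, 50, 60, 70, 80),
        breakpoint_day=45.0,
        n_replicates=3, n_blocks=1,
        noise_sd_log=0.0, block_sd_log=0.0,
        seed=7,
    )
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth
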