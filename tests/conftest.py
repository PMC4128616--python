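import numpy as np
import pytest

from tracepure import (SimConfig, diverge_template, random_template,
                       simulate_trace)


@pytest.fixture(scope="session")
def pure_trace():
    """One clean single-template chromatogram at default parameters."""
    template = random_template(650, seed=11)
    return simulate_trace(SimConfig(templates=[template], seed=1))


@pytest.fixture(scope="session")
def mixed_trace():
    """A 50:50 two-template chromatogram, 10% divergent, no indels."""
    template = random_template(650, seed=11)
    other, sites = diverge_template(template, 0.10, seed=12)
    record, truth = simulate_trace(
        SimConfig(templates=[template, other], proportions=[0.5, 0.5], seed=1))
    return record, truth, sites


def make_pure_config(seed: int) -> SimConfig:
    return SimConfig(templates=[random_template(650, seed=10_000 + seed)],
                     seed=seed)


def make_mixed_config(seed: int, minor: float = 0.5,
                      divergence: float = 0.10) -> SimConfig:
    template = random_template(650, seed=20_000 + seed)
    other, _ = diverge_template(template, divergence, seed=30_000 + seed)
    return SimConfig(templates=[template, other],
                     proportions=[1.0 - minor, minor], seed=seed)
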