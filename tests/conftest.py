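import numpy as np
import pytest

from mrkit.simulate import finngen_as_instruments, simulate_summary_stats
from mrkit.summary_io import HarmonizedSet, harmonize


@pytest.fixture
def as_instruments():
    """The seven published ankylosing-spondylitis instruments."""
    return finngen_as_instruments()


@pytest.fixture
def harmonized_seven():
    """A 7-SNP harmonized set with modest heterogeneity around beta = 0.05."""
    rng = np.random.default_rng(7)
    gamma = rng.uniform(0.2, 1.5, 7) * rng.choice([-1, 1], 7)
    se_gamma = np.full(7, 0.05)
    se_Gamma = rng.uniform(0.005, 0.02, 7)
    Gamma = 0.05 * gamma + rng.normal(0, se_Gamma)
    return HarmonizedSet.from_arrays(gamma, se_gamma, Gamma, se_Gamma)


def sim_harmonized(cfg):
    """Simulate a dataset pair under ``cfg`` and harmonize it."""
    exposure, outcome, truth = simulate_summary_stats(cfg)
    return harmonize(exposure, outcome), truth
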