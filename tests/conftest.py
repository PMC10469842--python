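import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dualqsip import GradientDesign, TaxonTruth
from dualqsip.synthetic import simulate_sample


@pytest.fixture
def design():
    return GradientDesign()


@pytest.fixture
def community(design):
    """100 taxa with known GC and true 13C AFE, plus the rng that made them."""
    rng = np.random.default_rng(42)
    n = 100
    gc = rng.uniform(0.3, 0.7, n)
    afe = rng.uniform(0.0, 0.8, n)
    ab = rng.dirichlet(np.ones(n) * 2)
    truths = [
        TaxonTruth(f"t{i:03d}", gc[i], ab[i], afe[i], 0.0) for i in range(n)
    ]
    return truths


def simulated_pair(truths, design, isotope, rng, noiseless=False):
    lab = simulate_sample(truths, design, isotope, "lab", rng, noiseless=noiseless)
    unl = simulate_sample(truths, design, "unlabeled", "unl", rng, noiseless=noiseless)
    return lab, unl
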