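import numpy as np
import pytest

from nmr2kit.relaxation import RelaxationContext
from nmr2kit.synthetic import (
    SyntheticComplexSpec,
    make_benchmark,
    make_toy_complex,
    simulate_noesy,
)


@pytest.fixture(scope="session")
def ctx():
    """Working relaxation context: tau_c = 10.1 ns at 800 MHz."""
    return RelaxationContext.from_field(10.1e-9, 800.0)


@pytest.fixture(scope="session")
def toy_complex():
    spec = SyntheticComplexSpec(seed=1)
    receptor, ligand, truth = make_toy_complex(spec)
    return spec, receptor, ligand, truth


@pytest.fixture(scope="session")
def simulated(toy_complex):
    spec, receptor, ligand, truth = toy_complex
    peaks, visibility = simulate_noesy(receptor, ligand, truth, spec)
    return spec, receptor, ligand, truth, peaks, visibility


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: 12 methyls, 10 resonances, 25+15 restraints."""
    return make_benchmark(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
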