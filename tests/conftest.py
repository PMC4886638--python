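import numpy as np
import pytest

from fluorplex import synthetic_data as sd


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-design synthetic dataset (37 analytes, 3 plates)."""
    return sd.generate_dataset(sd.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced crossed design with the default 5PL readout."""
    cfg = sd.GeneratorConfig.small(n_analytes=6, n_conditions=4,
                                   n_per_cell=4, n_plates=2, seed=7)
    return sd.generate_dataset(cfg)


@pytest.fixture(scope="session")
def linear_dataset():
    """Reduced crossed design with linear readout (log2 Fl = latent)."""
    cfg = sd.GeneratorConfig.small(
        n_analytes=6, n_conditions=4, n_per_cell=4, n_plates=2, seed=19,
        readout="linear", fl_noise_sd_log2=0.0, quantization_step=1e-9,
        baseline_low=4.0, baseline_high=12.0)
    return sd.generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
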