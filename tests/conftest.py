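import numpy as np
import pytest

import sccosol as s


@pytest.fixture(scope="session")
def busulfan_truth():
    """Published modified-Arrhenius coefficients for the most soluble drug."""
    return s.load_reference_coefficients("busulfan")


@pytest.fixture(scope="session")
def clean_dataset(busulfan_truth):
    """Noiseless 4x8-grid dataset generated from known coefficients."""
    return s.generate_dataset(
        "modified_arrhenius", busulfan_truth, noise=s.NoiseSpec(kind="none")
    )


@pytest.fixture(scope="session")
def bracket_bounds(busulfan_truth):
    """A coefficient box bracketing the generating truth with 50% margin."""
    t = np.asarray(busulfan_truth.a)
    w = 0.5 * np.abs(t) + 1e-5
    return list(zip(t - w, t + w))


@pytest.fixture
def noisy_dataset_factory(busulfan_truth):
    def make(seed, sigma=0.05):
        return s.generate_dataset(
            "modified_arrhenius",
            busulfan_truth,
            noise=s.NoiseSpec(sigma=sigma, seed=seed),
        )

    return make


@pytest.fixture
def quick_config():
    """Small DE budget for unit tests; studies use larger budgets."""
    return s.DEConfig(restarts=1, generations=400, patience=100, seed=42)
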