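import pytest

from hepatoclear import SimulationTruth, clint_to_k, simulate_depletion


@pytest.fixture
def noiseless_dataset():
    """Exact exponential decay at k_bio = 0.005/min (Cl_int = 10), no noise."""
    truth = SimulationTruth("CHEM-NL", k_bio_true=0.005, noise_sd_true=0.0, seed=11)
    ds, truth = simulate_depletion(truth)
    return ds, truth


@pytest.fixture
def strong_dataset():
    """Cl_int = 5 with 10% lognormal noise — comfortably detectable."""
    truth = SimulationTruth(
        "CHEM-S", k_bio_true=clint_to_k(5.0), noise_sd_true=0.1, seed=21
    )
    ds, truth = simulate_depletion(truth)
    return ds, truth


@pytest.fixture
def flat_dataset():
    """Metabolically stable chemical (k_bio = k_abio = 0) with noise."""
    truth = SimulationTruth("CHEM-F", k_bio_true=0.0, noise_sd_true=0.1, seed=31)
    ds, truth = simulate_depletion(truth)
    return ds, truth
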