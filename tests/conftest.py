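import numpy as np
import pytest

from iondecon import (MatchCriteria, NoiseModel, PlantedCompound, SimConfig,
                      Spectrum, TargetCompound, random_spectrum, simulate_run,
                      tables_fixture)


@pytest.fixture(scope="session")
def tables():
    """The packaged green/roasted coffee abundance table (227 compounds)."""
    return tables_fixture()


@pytest.fixture
def simple_spectrum():
    """A 4-ion spectrum with base peak 93 and known qualifier ratios."""
    return Spectrum({93: 1000.0, 136: 500.0, 121: 250.0, 68: 100.0})


@pytest.fixture
def simple_target(simple_spectrum):
    """Target on the simple spectrum: main ion 93, qualifiers 136/121/68."""
    return TargetCompound.from_spectrum("probe", rt=0.25,
                                        spectrum=simple_spectrum,
                                        n_qualifiers=3)


@pytest.fixture
def clean_run(simple_spectrum):
    """Noiseless single-compound run: Gaussian peak at 0.25 min."""
    comp = PlantedCompound("probe", simple_spectrum, rt=0.25, sigma=0.01,
                           total_abundance=5e5)
    run, truth = simulate_run([comp], SimConfig(duration=0.5, seed=11))
    return run, truth, comp


@pytest.fixture
def noisy_run(simple_spectrum):
    """Same single compound over a noisy baseline (per-cell sd 3 counts)."""
    comp = PlantedCompound("probe", simple_spectrum, rt=0.25, sigma=0.01,
                           total_abundance=5e5)
    run, truth = simulate_run([comp], SimConfig(duration=0.5, seed=11,
                                                noise_sd=3.0))
    return run, truth, comp


@pytest.fixture
def default_criteria():
    return MatchCriteria()
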