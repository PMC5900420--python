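import numpy as np
import pytest

from shikispec import synth

META = ["plant_id", "genotype", "treatment", "day"]


@pytest.fixture(scope="session")
def library():
    return synth.make_spectral_library(seed=1)


@pytest.fixture(scope="session")
def experiment(library):
    """One default glyphosate trial shared across read-only tests."""
    design = synth.DesignSpec(seed=1)
    spectra, chlf, truth = synth.simulate_experiment(design, library)
    return spectra, chlf, truth


@pytest.fixture(scope="session")
def spectra_matrix(experiment):
    spectra, _, truth = experiment
    X = spectra.drop(columns=META).to_numpy(dtype=float)
    return X, truth.shikimate


@pytest.fixture(scope="session")
def chlf_matrix(experiment):
    _, chlf, truth = experiment
    names = [c for c in chlf.columns if c not in META]
    return chlf[names].to_numpy(dtype=float), truth.shikimate, names
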