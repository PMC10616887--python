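import pytest

from dermospec import (MCConfig, UnitConventions, build_training_set,
                       fit_conversion_vectors, load_chromophore_table,
                       training_grid)
from dermospec.validation import run_recovery_experiment


@pytest.fixture(scope="session")
def spectra():
    return load_chromophore_table()


@pytest.fixture(scope="session")
def units():
    return UnitConventions()


@pytest.fixture(scope="session")
def quick_calibration(spectra):
    """Desk-scale calibration for functional tests: thinned grid,
    path-reweighted sweep at 2e5 photons/wavelength."""
    ts = build_training_set(training_grid(thin=True), spectra,
                            MCConfig(n_photons=200_000, seed=33),
                            method="pathlength")
    return fit_conversion_vectors(ts), ts


@pytest.fixture(scope="session")
def recovery(spectra):
    """The study-scale recovery experiment: full grids, 5e6 photons per
    wavelength via path reweighting, out-of-sample validation seeds."""
    return run_recovery_experiment(spectra)
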