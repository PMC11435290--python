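import warnings

import pandas as pd
import pytest

from saltspec import simulate


@pytest.fixture(scope="session")
def design():
    return simulate.FieldDesign()


@pytest.fixture(scope="session")
def trait_panel(design):
    """Default simulated 24 x 2 x 3 trial: (table, ground truth)."""
    return simulate.simulate_trait_panel(design, seed=11)


@pytest.fixture(scope="session")
def spectra_set(trait_panel):
    table, _ = trait_panel
    return simulate.simulate_canopy_spectra(table, seed=12)


@pytest.fixture(scope="session")
def marker_panel(trait_panel):
    _, truth = trait_panel
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate.simulate_marker_panel(
            pd.Series(truth["tolerance_scores"]), seed=13)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A written fixture bundle (spectra/trait/marker CSVs + truth JSON)."""
    directory = tmp_path_factory.mktemp("bundle")
    return simulate.write_fixture_bundle(directory, seed=7)
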