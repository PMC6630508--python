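import pytest

from atriasim import fit_model, model_preset, simulate_model


@pytest.fixture(scope="session")
def model4_curves():
    return simulate_model(model_preset("model4"))


@pytest.fixture(scope="session")
def model4_fits(model4_curves):
    return fit_model(model4_curves)
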