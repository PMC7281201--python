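import pytest

from cyanogem.fba import set_photoautotrophic_medium
from cyanogem.toy import ToyModelSpec, generate_toy_photoautotroph


@pytest.fixture(scope="session")
def toy_bundle():
    """Default toy photoautotroph with its analytic ground truth."""
    spec = ToyModelSpec()
    model, truth = generate_toy_photoautotroph(spec)
    return spec, model, truth


@pytest.fixture()
def toy_model(toy_bundle):
    # fresh copy per test so mutations cannot leak
    spec, model, truth = toy_bundle
    return model.copy()


@pytest.fixture()
def toy_truth(toy_bundle):
    return toy_bundle[2]


@pytest.fixture()
def toy_spec(toy_bundle):
    return toy_bundle[0]


@pytest.fixture()
def photo_constraints(toy_model, toy_spec):
    cons = set_photoautotrophic_medium(toy_model)
    cons.ngam_flux = toy_spec.energy.ngam
    return cons
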