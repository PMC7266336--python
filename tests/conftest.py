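import numpy as np
import pytest

from irriplan.fixtures import (
    fixture_paper_instance,
    fixture_toy_instance,
    fixture_toy_models,
)


@pytest.fixture(scope="session")
def paper_case():
    """Case-study-scale instance with documented stand-in costs."""
    return fixture_paper_instance()


@pytest.fixture
def toy(request):
    """A seeded toy fixture: (tiny, instance, price, water, precip)."""
    seed = getattr(request, "param", 0)
    tiny = fixture_toy_instance(seed)
    price, water, precip = fixture_toy_models(tiny, seed)
    return tiny, tiny.instance, price, water, precip


def random_realization(instance, price_model, water_model, seed):
    """A realization with positive probability under the toy models."""
    rng = np.random.default_rng(seed)
    return dict(
        price=price_model.mean * float(rng.uniform(0.7, 1.3)),
        water_limit=float(rng.uniform(0.5, 1.5)) * water_model.mean * instance.area,
        precipitation=rng.uniform(0.0, 0.03, instance.n_periods),
    )
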