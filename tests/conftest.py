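import numpy as np
import pytest

from mptdc import build_model, default_parameters


ALL_VARIANTS = [
    (fam, var) for fam in ("2HT", "SDT") for var in ("classic", "CL", "RT", "CL_RT")
]


def random_params(model, rng):
    """Uniform in-bounds parameter draw for any model variant."""
    params = {}
    for p in model.parameters:
        if p.lower == 0.0 and p.upper == 1.0:
            params[p.name] = rng.uniform(0.0, 1.0)
        elif p.role == "sd":
            params[p.name] = rng.uniform(0.3, 2.5)
        elif p.role == "sensitivity":
            params[p.name] = rng.uniform(-1.0, 3.0)
        elif p.role == "criterion":
            params[p.name] = rng.uniform(-2.0, 2.0)
        elif p.role == "criterion_increment":
            params[p.name] = rng.uniform(0.0, 1.0)
        else:  # pragma: no cover
            raise AssertionError(p)
    return params


@pytest.fixture
def rng():
    return np.random.default_rng(20240104)


@pytest.fixture(params=ALL_VARIANTS, ids=lambda fv: f"{fv[0]}-{fv[1]}")
def any_model(request):
    return build_model(*request.param)


@pytest.fixture
def classic_2ht():
    return build_model("2HT", "classic")


@pytest.fixture
def classic_sdt():
    return build_model("SDT", "classic")


@pytest.fixture
def gen_params():
    return default_parameters
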