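import numpy as np
import pytest
from hypothesis import settings

from greysharp import FixtureSpec, make_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: one representative image per fixture kind, used by the cross-cutting tests
FIXTURE_SPECS = [
    FixtureSpec("constant", (16, 16), (100,)),
    FixtureSpec("vstep", (16, 16), (50, 150)),
    FixtureSpec("hstep", (16, 16), (30, 200)),
    FixtureSpec("ramp", (16, 32), (0, 255)),
    FixtureSpec("checkerboard", (32, 32), (40, 180), block=8),
    FixtureSpec("salt-pepper", (32, 32), (100,), density=0.02, seed=3),
    FixtureSpec("smooth-field", (32, 32), (60, 140), seed=5),
]


@pytest.fixture(params=FIXTURE_SPECS, ids=lambda s: s.kind)
def fixture_image(request):
    return make_fixture(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(20140916)
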