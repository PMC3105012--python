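import numpy as np
import pytest

from craniomorph import canonical_template, face_template


@pytest.fixture(scope="session")
def template():
    """The canonical 64^3 head phantom (1 mm isotropic)."""
    return canonical_template()


@pytest.fixture(scope="session")
def template_landmarks():
    return face_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def head_mask(template):
    return template.data > 0.1 * template.data.max()
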