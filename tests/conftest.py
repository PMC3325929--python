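import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mtpop.datasets import maori_cohort, maori_motifs
from mtpop.reference import rcrs
from mtpop.simulate import random_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """The bundled rCRS coordinate model (no base string)."""
    return rcrs()


@pytest.fixture(scope="session")
def cohort():
    """The bundled 20-sample cohort (coding/HVRII panel)."""
    return maori_cohort()


@pytest.fixture(scope="session")
def motif_table():
    return maori_motifs()


@pytest.fixture(scope="session")
def synth_ref():
    """A small synthetic reference with sequence and gene map."""
    return random_reference(length=1200, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
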