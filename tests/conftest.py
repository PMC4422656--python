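import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from galkit.synthetic import (
    ContactSpec,
    SaltBridgeSpec,
    WaterBridgeSpec,
    make_toy_complex,
)

settings.register_profile(
    "galkit",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("galkit")


@pytest.fixture(scope="session")
def ln1_site():
    """A type-1 LacNAc binding-site fixture with one engineered contact,
    both salt-bridge classes and a water bridge."""
    structure, manifest = make_toy_complex(
        linkage="beta1_3",
        phi=-60.0,
        psi=135.0,
        contacts=(ContactSpec("GAL", "O4", "HIS", 44, "NE2", 2.87),),
        salt_bridges=(
            SaltBridgeSpec("ARG", 48, "ASP", 54, 2.9, "monodentate"),
            SaltBridgeSpec("ARG", 73, "GLU", 71, 2.9, "bidentate"),
        ),
        waters=(WaterBridgeSpec("GlcNAc", "N2", 2.80, "ASP", 154, "OD1", 2.75),),
        seed=7,
    )
    return structure, manifest


@pytest.fixture(scope="session")
def ln2_site():
    """A type-2 LacNAc fixture (no waters, one contact)."""
    structure, manifest = make_toy_complex(
        linkage="beta1_4",
        phi=-66.0,
        psi=-108.0,
        contacts=(ContactSpec("GAL", "O4", "HIS", 44, "NE2", 2.71),),
        seed=11,
    )
    return structure, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
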