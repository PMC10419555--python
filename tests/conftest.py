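import numpy as np
import pytest

from craniosym.synthetic import CohortConfig, generate_subject
from craniosym.template import build_template


@pytest.fixture(scope="session")
def default_template():
    return build_template()


@pytest.fixture(scope="session")
def coarse_template():
    return build_template(32, 24)


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def class1_male_subject(default_config):
    """One deterministic class-I male subject (landmarks only)."""
    rng = np.random.default_rng(42)
    return generate_subject("I", "M", default_config, rng)


@pytest.fixture(scope="session")
def mesh_subject(default_config):
    """One deterministic subject with an attached head mesh."""
    rng = np.random.default_rng(11)
    return generate_subject("I", "F", default_config, rng, with_mesh=True)


@pytest.fixture(scope="session")
def symmetric_mesh_subject():
    """A subject whose mesh carries zero injected asymmetry."""
    cfg = CohortConfig()
    for norms in cfg.head_norms.values():
        norms["AF"] = (0.0, 0.0)
        norms["AH"] = (0.0, 0.0)
    rng = np.random.default_rng(5)
    return generate_subject("I", "M", cfg, rng, with_mesh=True)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
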