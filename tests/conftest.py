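import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dentaxis import (
    DentitionLandmarks,
    Jaw,
    benchmark_dataset,
    make_default_protocol,
    make_template,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return make_default_protocol()


@pytest.fixture(scope="session")
def template(protocol):
    return make_template(protocol)


@pytest.fixture(scope="session")
def smoke_population():
    """10 individuals, 2 modes, noise 0.05 mm, random rigid pose."""
    return benchmark_dataset("smoke")


@pytest.fixture(scope="session")
def default_population():
    """30 individuals, 4 modes, noise 0.05 mm — the standard benchmark."""
    return benchmark_dataset("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noisy_template(template) -> DentitionLandmarks:
    """Template with tiny deterministic jitter (a generic complete case)."""
    gen = np.random.default_rng(7)
    pts = {l: p + gen.normal(0, 0.01, 3) for l, p in template.points.items()}
    return template.with_points(pts, individual_id="jittered")
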