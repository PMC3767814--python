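import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gshrad.synthgen import GeneratorConfig, generate
from gshrad.template import reference_coordinates
from gshrad.topology import build_gsh_oh_topology
from gshrad.trajio import Trajectory

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def topology():
    return build_gsh_oh_topology()


@pytest.fixture(scope="session")
def small_traj():
    """Default-conditions synthetic run with guest (desk scale)."""
    return generate(GeneratorConfig(seed=42, n_frames=300))


@pytest.fixture(scope="session")
def contact_rich_traj():
    """High contact probability so every stage sees plenty of events."""
    return generate(GeneratorConfig(seed=7, n_frames=400, contact_probability=0.6))


@pytest.fixture(scope="session")
def host_traj():
    return generate(GeneratorConfig(seed=5, n_frames=200, include_guest=False))


@pytest.fixture()
def rigid_template_traj(topology):
    """Five identical copies of the extended reference conformer."""
    ref = reference_coordinates()
    return Trajectory(topology=topology, coords=np.tile(ref, (5, 1, 1)))
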