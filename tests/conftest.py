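import numpy as np
import pytest

from meaobond.atomic_partition import AtomicPartition, build_partition
from meaobond.chem_backend import run_mean_field
from meaobond.geometries import geometry_path


@pytest.fixture
def rng():
    # fresh, deterministic stream per test (no cross-test order dependence)
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def h2_mf():
    """H2 at 0.74 A, cc-pVDZ."""
    return run_mean_field("2\nh2\nH 0 0 0\nH 0 0 0.74\n", "cc-pvdz")


@pytest.fixture(scope="session")
def he2_mf():
    return run_mean_field(geometry_path("he2"), "cc-pvdz")


@pytest.fixture(scope="session")
def lih_mf():
    return run_mean_field(geometry_path("lih"), "cc-pvdz")


@pytest.fixture(scope="session")
def lih_partition(lih_mf):
    return build_partition(lih_mf, "iao-minimal")


@pytest.fixture
def two_atom_fixture(rng):
    """Synthetic 2-atom, 2-orbitals-per-atom closed-shell fixture: a random
    rank-2 projector density and its partition."""
    x = rng.standard_normal((4, 2))
    q, _ = np.linalg.qr(x)
    gamma = 2.0 * q @ q.T
    part = AtomicPartition(
        np.eye(4), np.array([0, 0, 1, 1]), ["A", "B"], "iao-minimal", True, np.eye(4)
    )
    return gamma, part
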