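import pytest
from hypothesis import settings

from microvillus.assembly import (
    attach_light_chains,
    build_bundle,
    place_all_crosslinkers,
    place_myosin,
)
from microvillus.components import (
    fimbrin_spec,
    light_chain_spec,
    myosin_spec,
    villin_spec,
)
from microvillus.helix import ACTIN_RISE, ACTIN_TWIST, make_symmetry
from microvillus.lattice import adjacency_edges, hex_points

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def actin_sym():
    return make_symmetry(ACTIN_RISE, ACTIN_TWIST)


@pytest.fixture(scope="session")
def hex_helix_sym():
    """Ideal hexagonal 6/1 helix (no lattice frustration)."""
    return make_symmetry(10.0, -60.0)


@pytest.fixture(scope="session")
def lattice19():
    return hex_points(2, 120.0)


@pytest.fixture(scope="session")
def edges19(lattice19):
    return adjacency_edges(lattice19)


@pytest.fixture(scope="session")
def small_bundle(actin_sym, lattice19):
    """Two complete repeats: enough for every placement rule to engage."""
    return build_bundle(actin_sym, lattice19, 75.0)  # 27 monomers -> 2 repeats


@pytest.fixture(scope="session")
def full_bundle(actin_sym, lattice19):
    """The default 1000 nm, 19-filament core bundle."""
    return build_bundle(actin_sym, lattice19, 1000.0)


@pytest.fixture(scope="session")
def full_build(full_bundle, edges19):
    """Complete default build: cross-linkers, motors, light chains."""
    crosslinkers = place_all_crosslinkers(
        full_bundle, fimbrin_spec(), villin_spec(), edges19
    )
    motors = place_myosin(full_bundle, myosin_spec(), crosslinkers=crosslinkers)
    lc = light_chain_spec()
    light_chains = [q for m in motors for q in attach_light_chains(m, lc)]
    return {
        "bundle": full_bundle,
        "crosslinkers": crosslinkers,
        "motors": motors,
        "light_chains": light_chains,
    }
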