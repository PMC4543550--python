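"""Shared fixtures.

The expensive full-geometry packed crypt is built once per session and shared
(copied) between simulation tests; replicate-specific identities, timers and
noise are drawn from each test's own seed.
"""

import numpy as np
import pytest

import cryptsim as cs

# desk-scale numerical settings used by the simulation-level tests: coarser
# chemistry grid, quasi-steady field solves, and a coarser coupling step /
# lifecycle cadence (see docs/methods.md, "Problem sizes")
DESK = dict(grid_spacing=2.0, dt_mech=14.4, dt_chem=0.0144,
            chem_mode="quasi_steady", lifecycle_every=62,
            chem_update_every_s=900.0)


@pytest.fixture(scope="session")
def desk_config():
    return cs.load_config(DESK)


@pytest.fixture(scope="session")
def surface():
    return cs.CryptSurface(30.0, 160.0)


@pytest.fixture(scope="session")
def packed_crypt(desk_config):
    """Identity-less confluent packing of the full crypt (shared, ~minutes)."""
    rng = np.random.default_rng(20240901)
    return cs.pack_crypt(desk_config, rng)


@pytest.fixture(scope="session")
def small_config():
    """A reduced crypt (half height/diameter) for cheap end-to-end checks."""
    return cs.load_config({**DESK, "crypt_height": 80.0, "crypt_diameter": 40.0})


@pytest.fixture(scope="session")
def small_packed(small_config):
    rng = np.random.default_rng(7)
    return cs.pack_crypt(small_config, rng)


def make_round_cell(rng, centre, n=20, spread=1.5):
    """A blob of n elements around a centre, for hand-built configurations."""
    return np.asarray(centre, float) + rng.normal(0.0, spread, size=(n, 3))
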