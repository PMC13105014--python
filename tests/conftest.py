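"""Shared fixtures: synthetic fibrils at the three symmetry classes.

All fixtures are generated in memory by the package's own generator; no
binary test data is stored.
"""

import numpy as np
import pytest

from crossbeta.synth import FibrilSpec, generate_fibril


@pytest.fixture(scope="session")
def c2_fibril():
    """Two-subunit C2 fibril with the rapid-twist parameters (-3.55 deg / 4.69 A)."""
    return generate_fibril(FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2",
                                      n_layers=4))


@pytest.fixture(scope="session")
def screw_fibril():
    """Pseudo-2_1 fibril (-181.75 deg / 2.34 A), three layers per subunit."""
    return generate_fibril(FibrilSpec(twist=-181.75, rise=2.34,
                                      symmetry="pseudo-2_1", n_layers=3))


@pytest.fixture(scope="session")
def c1_fibril():
    """C1 fibril with two conformationally inequivalent subunits (-5.24 / 9.40)."""
    return generate_fibril(FibrilSpec(twist=-5.24, rise=9.40, symmetry="C1",
                                      n_layers=4))


@pytest.fixture(scope="session")
def tilted_c2_fibril():
    """C2 fibril whose subunits are tilted 3.5 deg each (herringbone 7 deg)."""
    return generate_fibril(FibrilSpec(twist=-3.55, rise=4.69, symmetry="C2",
                                      n_layers=4, subunit_tilt_deg=3.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def strip_ground_truth(m):
    """Copy of a generated model without the generator's assignments/axis."""
    from crossbeta.model_io import FibrilModel

    return FibrilModel(atoms=m.atoms.copy(), name=m.name)
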