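import numpy as np
import pytest

from cyclodesign.model import (MacrocycleSequence, ResidueSpec,
                               build_from_torsions)
from cyclodesign.fixtures import make_fixture_ring


@pytest.fixture(scope="session")
def ring8():
    """A closed 8-residue polyglycine ring passing the bump check."""
    return make_fixture_ring(8, "beta_hairpin_like", seed=3)


@pytest.fixture(scope="session")
def ring6():
    return make_fixture_ring(6, "beta_hairpin_like", seed=1)


@pytest.fixture(scope="session")
def helix8():
    """Open alpha-helical chain: residues 4..7 donate i->i-4 H-bonds."""
    seq = MacrocycleSequence.polyglycine(8)
    t = np.zeros((8, 3))
    t[:, 0] = -57.0
    t[:, 1] = -47.0
    t[:, 2] = 180.0
    return build_from_torsions(seq, t)


@pytest.fixture(scope="session")
def mixed_seq8():
    """Length-8 sequence exercising chirality, N-methyl, PRO, GLY, AIB."""
    return MacrocycleSequence([
        ResidueSpec("ALA", "L"), ResidueSpec("PRO", "D"),
        ResidueSpec("GLY", "achiral"), ResidueSpec("LEU", "D", True),
        ResidueSpec("AIB", "achiral"), ResidueSpec("PHE", "L"),
        ResidueSpec("VAL", "L", True), ResidueSpec("ILE", "D"),
    ])


def random_torsions(rng, n, omega_choices=(180.0,)):
    return np.column_stack([
        rng.uniform(-180.0, 180.0, n),
        rng.uniform(-180.0, 180.0, n),
        rng.choice(omega_choices, n),
    ])
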