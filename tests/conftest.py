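import numpy as np
import pytest

from cphmd.fixtures import FixtureSpec, make_fixture
from cphmd.model import Atom, LambdaGroup, TitratableSystem


@pytest.fixture
def ideal_site():
    return make_fixture(FixtureSpec(kind="ideal_site", pKa_refs=(4.0,)))


@pytest.fixture
def shifted_site():
    return make_fixture(FixtureSpec(kind="shifted_site", pKa_refs=(4.0,)))


@pytest.fixture
def his_like():
    return make_fixture(FixtureSpec(kind="his_like", pKa_refs=(6.53, 6.94)))


@pytest.fixture
def buffered_site():
    return make_fixture(
        FixtureSpec(kind="buffer_bath", base="ideal_site", pKa_refs=(4.0,), n_buffers=10)
    )


def random_multisite_system(rng, n_sites=2, n_atoms_per_site=2, n_env=3, spread=3.0):
    """Random collection of two-state groups plus environment charges.

    Positions are drawn in a box large enough that no pair is close to
    singular; lambdas are set to random interior values.
    """
    atoms, groups = [], []
    aid = 0
    for gi in range(n_sites):
        ids = []
        for _ in range(n_atoms_per_site):
            atoms.append(
                Atom(id=aid, position=rng.uniform(0, spread, 3), q_A=0.0, group_id=gi)
            )
            ids.append(aid)
            aid += 1
        g = LambdaGroup.two_state(
            ids,
            rng.uniform(-1, 1, n_atoms_per_site),
            rng.uniform(-1, 1, n_atoms_per_site),
            4.0,
            name=f"site{gi}",
        )
        lam = rng.uniform(0.1, 0.9)
        g.set_lambdas([1 - lam, lam])
        groups.append(g)
    for _ in range(n_env):
        atoms.append(
            Atom(id=aid, position=rng.uniform(0, spread, 3), q_A=float(rng.uniform(-0.5, 0.5)))
        )
        aid += 1
    return TitratableSystem(atoms=atoms, groups=groups)
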