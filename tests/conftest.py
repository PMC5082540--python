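import dataclasses

import numpy as np
import pytest

from torsionfep.model_system import (Bead, RFParams, SoftcoreParams,
                                     ToyTopology, ZRow, build_toy_mutation)


@pytest.fixture(scope="session")
def top():
    """The default two-torsion Ala->Gly toy topology."""
    return build_toy_mutation()


@pytest.fixture(scope="session")
def sc():
    return SoftcoreParams()


def make_torsion_chain(k=1.0, m=1, delta=0.0, n_dof=1):
    """A bead chain with only torsional energy (no nonbonded terms).

    n_dof=1 gives a 4-bead chain with a single driven dihedral; n_dof=2
    appends a fifth bead driven by a second dihedral.  All pairs are
    excluded, so the potential is exactly the sum of cosine terms.
    """
    n = 4 + (n_dof - 1)
    beads = [Bead(i, f"B{i}", (0.0, 0.0), (0.0, 0.0), 0.0, 0.0)
             for i in range(n)]
    zmat = [
        ZRow(-1, -1, -1, 0.0, 0.0, -1, 0.0),
        ZRow(0, -1, -1, 0.15, 0.0, -1, 0.0),
        ZRow(1, 0, -1, 0.15, 110.0, -1, 0.0),
        ZRow(2, 1, 0, 0.15, 110.0, 0, 0.0),
    ]
    dofs = [((0, 1, 2, 3), "t0")]
    terms = [(0, k, m, delta)]
    if n_dof == 2:
        zmat.append(ZRow(3, 2, 1, 0.15, 110.0, 1, 0.0))
        dofs.append(((1, 2, 3, 4), "t1"))
        terms.append((1, k, m, delta))
    excl = {(i, j) for i in range(n) for j in range(i + 1, n)}
    return ToyTopology(beads=beads, zmat=zmat, torsion_dofs=dofs,
                       torsion_terms=terms, exclusions=excl,
                       extra_exclusions=set(), rf=RFParams(),
                       temperature_K=298.0)


def retabled(top, **changes):
    """dataclasses.replace that guarantees fresh kernel tables."""
    return dataclasses.replace(top, **changes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160916)
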