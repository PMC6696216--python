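import numpy as np
import pytest

from cdftkit.models import AtomicPopulationTable
from cdftkit.synthetic_fixtures import load_virotoxin_fixtures


def make_table(charge_state, charges, spins=None, elements=None, multiplicity=None):
    charges = np.asarray(charges, dtype=float)
    n = len(charges)
    if elements is None:
        elements = tuple(["C"] * n)
    if multiplicity is None:
        multiplicity = 1 if spins is None else int(round(abs(float(np.sum(spins))))) + 1
    return AtomicPopulationTable(
        charge_state=charge_state,
        multiplicity_hint=multiplicity,
        indices=np.arange(1, n + 1),
        elements=tuple(elements),
        charges=charges,
        spins=None if spins is None else np.asarray(spins, dtype=float),
    )


@pytest.fixture(scope="session")
def bundle():
    return load_virotoxin_fixtures()


@pytest.fixture
def toy_triple():
    """3-atom hand-checked charge-state triple.

    f- = [0.5, 0.2, 0.3], f+ = [0.6, 0.2, 0.2], dual = [0.1, 0.0, -0.1].
    """
    neutral = make_table(0, [0.0, 0.2, -0.2])
    cation = make_table(1, [0.5, 0.4, 0.1], spins=[0.7, 0.2, 0.1])
    anion = make_table(-1, [-0.6, 0.0, -0.4], spins=[0.1, 0.3, 0.6])
    return neutral, cation, anion
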