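import numpy as np
import pytest

from betallps.pairing import _AA_INDEX, EnergyTable, Orientation


def pair_table(orientation, entries, base=0.0):
    """Build an EnergyTable from a {(a, b): energy} mapping."""
    m = np.full((20, 20), float(base))
    for (a, b), e in entries.items():
        m[_AA_INDEX[a], _AA_INDEX[b]] = e
    return EnergyTable(orientation, m)


@pytest.fixture
def zero_tables():
    return (
        EnergyTable.zeros(Orientation.PARALLEL),
        EnergyTable.zeros(Orientation.ANTIPARALLEL),
    )


@pytest.fixture
def vv_tables():
    """Parallel e(V,V) = -1, everything else zero."""
    return (
        pair_table(Orientation.PARALLEL, {("V", "V"): -1.0}),
        EnergyTable.zeros(Orientation.ANTIPARALLEL),
    )


def random_tables(seed):
    rng = np.random.default_rng(seed)
    return (
        EnergyTable(Orientation.PARALLEL, rng.normal(0.0, 1.0, (20, 20))),
        EnergyTable(Orientation.ANTIPARALLEL, rng.normal(0.0, 1.0, (20, 20))),
    )


def random_sequence(rng, n):
    from betallps.pairing import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=n))
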