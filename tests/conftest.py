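import numpy as np
import pytest

import cocomo2 as c


@pytest.fixture(scope="session")
def params2():
    return c.default_params("cocomo2")


@pytest.fixture(scope="session")
def params1():
    return c.default_params("cocomo")


@pytest.fixture(scope="session")
def table(params2):
    # session-wide residue table; reference areas computed once
    return c.residue_table(params2)


def make_state(sequences, coords, box, params, domains=None, references=None):
    """Assemble a SystemState from per-chain sequences and coordinates."""
    domains = domains or [None] * len(sequences)
    references = references or [None] * len(sequences)
    tops = [
        c.build_chain_topology(s, d, r, params)
        for s, d, r in zip(sequences, domains, references)
    ]
    chain_index = np.concatenate(
        [np.full(len(s), k, dtype=np.int64) for k, s in enumerate(sequences)]
    )
    return c.SystemState(np.concatenate(coords), box, chain_index, tops)


@pytest.fixture()
def dimer_factory(params2):
    """Two single-bead chains at separation r: the minimal nonbonded system."""

    def build(code_a, code_b, r, box=50.0, params=None):
        return make_state(
            [code_a, code_b],
            [np.array([[box / 2, box / 2, box / 2]]),
             np.array([[box / 2 + r, box / 2, box / 2]])],
            [box] * 3,
            params or params2,
        )

    return build
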