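"""Shared fixtures: small structures, libraries and matrices.

Session-scoped where construction is expensive; everything is generated
programmatically and seeded."""

import numpy as np
import pytest

import designkit as dk
from designkit.energetics import EnergyModel, PairEnergyMatrix, build_energy_matrix

#: Rigid-rotamer model used by most tests (pair_min_steps=0 = oracle mode).
RIGID = EnergyModel(pair_min_steps=0)


@pytest.fixture(scope="session")
def params():
    return dk.ParameterSet.default()


@pytest.fixture(scope="session")
def small_lib():
    # 4 types, one free chi each -> 10 states per position
    return dk.grid_library(types="AVSD", max_chi=1)


@pytest.fixture(scope="session")
def helix5(params):
    return dk.make_structure(dk.FixtureSpec(kind="helix", length=5),
                             parameters=params)


@pytest.fixture(scope="session")
def strand6(params):
    return dk.make_structure(dk.FixtureSpec(kind="strand", length=6),
                             parameters=params)


@pytest.fixture(scope="session")
def small_matrix(helix5, small_lib):
    return build_energy_matrix(helix5, small_lib, RIGID)


@pytest.fixture(scope="session")
def design_matrix():
    """8-residue helix over an 8-type, <=3-rotamer library: the workhorse
    for optimizer and ensemble tests (22 states per position)."""
    tpl = dk.make_structure(dk.FixtureSpec(kind="helix", length=8))
    lib = dk.grid_library(types="AVLSDKRE", max_chi=1)
    return tpl, lib, build_energy_matrix(tpl, lib, RIGID)


def random_matrix(rng, n_pos=3, types=("A", "V", "L"), n_rot=2,
                  sigma=2.0) -> PairEnergyMatrix:
    """A synthetic precomputed matrix with Gaussian singleton and pairwise
    entries - the optimizer test bed (no structure involved)."""
    states = [[(aa, r) for aa in types for r in range(n_rot)]
              for _ in range(n_pos)]
    n = len(states[0])
    singleton = [np.column_stack([rng.normal(0, sigma, n),
                                  np.zeros(n), np.zeros(n)])
                 for _ in range(n_pos)]
    pairwise = {}
    for p in range(n_pos):
        for q in range(p + 1, n_pos):
            block = np.zeros((n, n, 3))
            block[:, :, 0] = rng.normal(0, sigma, (n, n))
            pairwise[(p, q)] = block
    return PairEnergyMatrix(
        positions=[{"index": p + 1, "native": types[0], "designable": True}
                   for p in range(n_pos)],
        states=states,
        singleton=singleton,
        eref=[np.zeros(n) for _ in range(n_pos)],
        pairwise=pairwise,
        constant=np.zeros(3),
        capped={},
        model=RIGID,
    )


def enumerate_gmec(matrix: PairEnergyMatrix):
    """Exhaustive search over all assignments (oracle)."""
    import itertools

    best, best_s = np.inf, None
    ranges = [range(matrix.n_states(p))
              for p in range(matrix.n_positions)]
    for s in itertools.product(*ranges):
        e = matrix.energy(list(s))
        if e < best:
            best, best_s = e, s
    return best, best_s
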