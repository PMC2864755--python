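"""Energy function: nonbonded terms, surface areas, matrix, references."""

import math

import numpy as np
import pytest

import designkit as dk
from designkit.energetics import (
    KCOUL,
    EnergyError,
    EnergyModel,
    UnfoldedReference,
    build_energy_matrix,
    casa_breakdown,
    coulomb_energy,
    fold_free_energy,
    lj_energy,
    minimize_structure,
    pair_interaction_energy,
    sasa_exact,
    sasa_pairwise_approx,
    surface_energy,
    unfolded_reference_energy,
)
from designkit.structure import AtomGroup, Rotamer

from conftest import RIGID


def atoms_at(coords, charge=0.0, eps=0.1, rmin=2.0, radius=1.9,
             sigma=0.012):
    coords = np.atleast_2d(coords)
    n = len(coords)
    return AtomGroup([f"X{i}" for i in range(n)], coords,
                     np.full(n, charge), np.full(n, eps), np.full(n, rmin),
                     np.full(n, radius), np.full(n, sigma))


# -- Coulomb ---------------------------------------------------------------

def test_coulomb_unit_charges():
    a = atoms_at([[0, 0, 0]], charge=1.0)
    b = atoms_at([[3, 0, 0]], charge=1.0)
    assert coulomb_energy(a, b, eps=10.0) == pytest.approx(
        KCOUL / 30.0, abs=1e-9)


def test_coulomb_zero_charge_and_eps_scaling():
    a = atoms_at([[0, 0, 0]], charge=0.0)
    b = atoms_at([[2, 0, 0]], charge=1.0)
    assert coulomb_energy(a, b, eps=10.0) == 0.0
    a2 = atoms_at([[0, 0, 0]], charge=-1.0)
    e10 = coulomb_energy(a2, b, eps=10.0)
    e20 = coulomb_energy(a2, b, eps=20.0)
    assert e20 == pytest.approx(e10 / 2.0)


def test_coulomb_coincident_charges_error():
    a = atoms_at([[0, 0, 0]], charge=1.0)
    b = atoms_at([[0, 0, 0]], charge=1.0)
    with pytest.raises(EnergyError):
        coulomb_energy(a, b, eps=10.0)


def test_excluded_pairs_skipped():
    a = atoms_at([[0, 0, 0], [1.5, 0, 0]], charge=1.0)
    assert coulomb_energy(a, eps=1.0, excluded={(0, 1)}) == 0.0
    assert lj_energy(a, excluded={(0, 1)}) == 0.0


# -- Lennard-Jones ---------------------------------------------------------

def test_lj_minimum_and_decay():
    a = atoms_at([[0, 0, 0]], eps=0.09, rmin=2.1)
    b = atoms_at([[4.2, 0, 0]], eps=0.09, rmin=2.1)
    assert lj_energy(a, b) == pytest.approx(-0.09, abs=1e-12)
    far = atoms_at([[500.0, 0, 0]], eps=0.09, rmin=2.1)
    assert abs(lj_energy(a, far)) < 1e-10


def test_lj_positive_inside_sigma():
    # LJ crosses zero at r = rmin / 2^(1/6) ~ 0.891 rmin
    a = atoms_at([[0, 0, 0]], eps=0.1, rmin=2.0)
    r_zero = 4.0 / 2.0 ** (1.0 / 6.0)
    closer = atoms_at([[r_zero * 0.99, 0, 0]], eps=0.1, rmin=2.0)
    beyond = atoms_at([[r_zero * 1.01, 0, 0]], eps=0.1, rmin=2.0)
    assert lj_energy(a, closer) > 0
    assert lj_energy(a, beyond) < 0


def test_lj_zero_distance_error():
    a = atoms_at([[0, 0, 0], [0, 0, 0]])
    with pytest.raises(EnergyError):
        lj_energy(a)


# -- surface areas ---------------------------------------------------------

def test_isolated_atom_analytic_area():
    g = atoms_at([[0, 0, 0]], radius=1.9)
    expected = 4.0 * math.pi * 3.3 ** 2
    assert sasa_exact(g)[0] == pytest.approx(expected, abs=1e-9)
    assert sasa_pairwise_approx(g)[0] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(136.848, abs=1e-3)


def test_far_separated_atoms_additive():
    g = atoms_at([[0, 0, 0], [50, 0, 0]], radius=1.9)
    iso = 4.0 * math.pi * 3.3 ** 2
    assert np.allclose(sasa_exact(g), iso)


@pytest.mark.parametrize("d", [0.5, 1.5, 2.5, 3.3, 4.5, 6.0, 6.5])
def test_two_body_pairwise_equals_exact(d):
    """On any two-sphere system the contact-area formula is the exact
    Lee-Richards result (to 1e-6 A^2)."""
    g = AtomGroup(["a", "b"], [[0, 0, 0], [d, 0.3, -0.2]],
                  [0, 0], [0.1, 0.1], [2.0, 1.6], [1.9, 1.6],
                  [0.012, -0.06])
    ex = sasa_exact(g)
    ap = sasa_pairwise_approx(g)
    assert np.abs(ex - ap).max() < 1e-6


def test_multi_overlap_nonnegative_and_convergent():
    base = np.array([[0.0, 0, 0], [3.0, 0, 0], [1.5, 2.6, 0]])
    for scale in (1.0, 2.0, 3.0):
        g = atoms_at(base * scale, radius=1.9)
        ap = sasa_pairwise_approx(g)
        assert (ap >= 0).all()
    # far apart: approx converges to exact
    g = atoms_at(base * 3.0, radius=1.9)
    assert np.abs(sasa_pairwise_approx(g) - sasa_exact(g)).max() < 1e-6


def test_sasa_exact_matches_independent_oracle():
    """Cross-check the Lee-Richards implementation against an independent
    Shrake-Rupley computation on a random cluster."""
    bst = pytest.importorskip("biotite.structure")
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 6.0, size=(15, 3))
    g = atoms_at(coords, radius=1.9)
    ex = sasa_exact(g)
    arr = bst.AtomArray(15)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * 15)
    arr.atom_name = np.array([f"C{i}" for i in range(15)])
    arr.res_id = np.ones(15, dtype=int)
    arr.res_name = np.array(["UNK"] * 15)
    sr = bst.sasa(arr, vdw_radii=np.full(15, 1.9), point_number=3000)
    assert np.abs(ex - sr).max() < 1.0  # dot-sampling noise of the oracle


def test_surface_energy_examples():
    area = 4.0 * math.pi * 3.3 ** 2
    assert surface_energy([area], [0.012]) == pytest.approx(
        0.012 * area, abs=1e-9)
    assert surface_energy([10.0, 20.0], [0.0, 0.0]) == 0.0
    assert surface_energy([10.0], [0.012], surface_scale=0.0) == 0.0


# -- pair interactions and the matrix --------------------------------------

def test_pair_beyond_cutoff_is_zero(helix5, small_lib):
    model = EnergyModel(pair_min_steps=0, cutoff=0.1)
    comp = pair_interaction_energy(
        helix5, 0, ("V", small_lib["V"][0]), 4, ("V", small_lib["V"][0]),
        model)
    assert comp == (0.0, 0.0, 0.0)


def test_far_separated_ala_pair_negligible(params):
    tpl = dk.make_structure(dk.FixtureSpec(kind="strand", length=12),
                            parameters=params)
    comp = pair_interaction_energy(
        tpl, 0, ("A", Rotamer("A", ())), 11, ("A", Rotamer("A", ())),
        EnergyModel(pair_min_steps=0, cutoff=1e9))
    assert all(abs(x) < 1e-3 for x in comp)


def test_relaxed_pair_reduces_to_rigid_at_zero_steps(helix5, small_lib):
    rigid = pair_interaction_energy(
        helix5, 1, ("D", small_lib["D"][0]), 2, ("S", small_lib["S"][1]),
        EnergyModel(pair_min_steps=0))
    again = pair_interaction_energy(
        helix5, 1, ("D", small_lib["D"][0]), 2, ("S", small_lib["S"][1]),
        EnergyModel(pair_min_steps=0))
    assert rigid == again


def test_pair_relaxation_lowers_cross_energy(helix5, small_lib):
    """With relaxation on, the vdW+Coulomb cross energy of a clashing pair
    should not be (much) worse than the rigid evaluation."""
    state_i = ("D", small_lib["D"][0])
    state_j = ("D", small_lib["D"][0])
    rigid = pair_interaction_energy(helix5, 1, state_i, 2, state_j,
                                    EnergyModel(pair_min_steps=0))
    relaxed = pair_interaction_energy(helix5, 1, state_i, 2, state_j,
                                      EnergyModel(pair_min_steps=10))
    assert relaxed.vdw + relaxed.coulomb <= rigid.vdw + rigid.coulomb + 1.0


def test_matrix_combinatorics_and_symmetry(small_matrix):
    M = small_matrix
    assert M.n_positions == 5
    assert all(M.n_states(p) == 10 for p in range(5))
    for (p, q), block in M.pairwise.items():
        assert p < q
        assert block.shape == (10, 10, 3)
        assert np.isfinite(block).all()
        # symmetry: the (p,q) entry serves both orientations
        assert np.allclose(M.pair_block(p, q), M.pair_block(q, p).T)


def test_cutoff_soundness(helix5, small_lib):
    """Enlarging the cutoff never changes entries already present."""
    m_small = build_energy_matrix(
        helix5, small_lib, EnergyModel(pair_min_steps=0, cutoff=7.0))
    m_large = build_energy_matrix(
        helix5, small_lib, EnergyModel(pair_min_steps=0, cutoff=1e9))
    for key, block in m_small.pairwise.items():
        assert np.allclose(block, m_large.pairwise[key], atol=1e-12)
    assert set(m_small.pairwise) <= set(m_large.pairwise)


def test_matrix_reconstruction_equals_direct_evaluation(strand6, small_lib):
    """Matrix-reconstructed fold energy == whole-system evaluation from
    assembled coordinates (rigid rotamers, no cutoff), to 1e-3 kcal/mol."""
    no_cut = EnergyModel(pair_min_steps=0, cutoff=1e9)
    M = build_energy_matrix(strand6, small_lib, no_cut)
    rng = np.random.default_rng(42)
    for _ in range(20):
        s = [int(rng.integers(M.n_states(p))) for p in range(6)]
        bd = fold_free_energy(M, s)
        assignment = [
            (M.states[p][s[p]][0],
             small_lib[M.states[p][s[p]][0]][M.states[p][s[p]][1]])
            for p in range(6)]
        direct = casa_breakdown(strand6, assignment, no_cut)
        assert bd.total == pytest.approx(direct.total, abs=1e-3)
        assert bd.vdw == pytest.approx(direct.vdw, abs=1e-3)
        assert bd.surface == pytest.approx(direct.surface, abs=1e-3)


def test_breakdown_internal_consistency(small_matrix):
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = [int(rng.integers(small_matrix.n_states(p))) for p in range(5)]
        bd = small_matrix.assignment_breakdown(s)
        assert bd.total == pytest.approx(
            bd.vdw + bd.coulomb + bd.surface - bd.unfolded, abs=1e-6)


def test_empty_pairwise_means_singleton_sum(helix5, small_lib):
    m = build_energy_matrix(helix5, small_lib,
                            EnergyModel(pair_min_steps=0, cutoff=1e-3))
    assert not m.pairwise
    s = [0] * 5
    bd = m.assignment_breakdown(s)
    expected = (m.constant.sum()
                + sum(m.singleton[p][0].sum() - m.eref[p][0]
                      for p in range(5)))
    assert bd.total == pytest.approx(expected, abs=1e-9)


def test_matrix_serialization_roundtrip(tmp_path, small_matrix):
    path = tmp_path / "m.json"
    small_matrix.save(path)
    back = type(small_matrix).load(path)
    s = [1, 2, 3, 0, 5]
    assert back.energy(s) == pytest.approx(small_matrix.energy(s),
                                           abs=1e-6)
    assert back.states == small_matrix.states


def test_unknown_state_errors(small_matrix):
    with pytest.raises(EnergyError):
        small_matrix.assignment_breakdown([0, 0, 0, 0, 99])
    with pytest.raises(EnergyError):
        small_matrix.state_index(0, "W", 0)


# -- unfolded reference ----------------------------------------------------

def test_unfolded_reference_deterministic_and_monotone(small_lib):
    e1 = unfolded_reference_energy("V", small_lib, RIGID)
    e2 = unfolded_reference_energy("V", small_lib, RIGID)
    assert e1 == e2
    # enlarging the rotamer set cannot increase the minimum
    bigger = dk.grid_library(types="V")  # all 3 chi values free
    e3 = unfolded_reference_energy("V", bigger, RIGID)
    assert e3 <= e1 + 1e-9


def test_unfolded_reference_ala_matches_enumeration(small_lib):
    """e_ref(Ala) equals explicit enumeration over the backbone catalog."""
    from designkit.energetics import DEFAULT_PHI_PSI_CATALOG
    from designkit.structure import build_chain_backbone

    best = math.inf
    ala = Rotamer("A", ())
    for phi_psi in DEFAULT_PHI_PSI_CATALOG:
        tpl = build_chain_backbone("AAA", [phi_psi] * 3)
        bd = casa_breakdown(tpl, [("A", ala)] * 3, RIGID)
        best = min(best, bd.vdw + bd.coulomb + bd.surface)
    assert unfolded_reference_energy("A", small_lib, RIGID) == \
        pytest.approx(best, abs=1e-9)


# -- whole-structure preparation -------------------------------------------

def _toy_system(stretch=1.0):
    coords = np.array([[0.0, 0, 0], [1.5 * stretch, 0, 0],
                       [3.0 * stretch, 0.5, 0], [4.5 * stretch, 0, 0.5]])
    g = AtomGroup(["a", "b", "c", "d"], coords,
                  [0.2, -0.2, 0.2, -0.2], [0.1] * 4, [1.8] * 4,
                  [1.9] * 4, [0.012] * 4)
    bonds = [(0, 1), (1, 2), (2, 3)]
    return g, bonds


def test_minimize_descends_and_zero_steps_identity():
    g, bonds = _toy_system(stretch=1.2)
    model = EnergyModel(pair_min_steps=0)
    out, info = minimize_structure(g, bonds, model, max_steps=100)
    assert info["energy_final"] <= info["energy_initial"] + 1e-9
    same, info0 = minimize_structure(g, bonds, model, max_steps=0)
    assert np.allclose(same.coords, g.coords)
    assert info0["backbone_rmsd"] == 0.0


def test_minimize_relaxed_input_stays_put():
    g, bonds = _toy_system()
    model = EnergyModel(pair_min_steps=0)
    once, _ = minimize_structure(g, bonds, model, max_steps=300)
    twice, info = minimize_structure(once, bonds, model, max_steps=300)
    assert info["energy_final"] == pytest.approx(info["energy_initial"],
                                                 abs=0.05)
    assert info["backbone_rmsd"] < 0.2


# -- composition calibration ----------------------------------------------

def test_calibrate_zero_eta_no_change(small_matrix):
    target = {aa: 0.25 for aa in "AVSD"}
    corr, hist = dk.calibrate_corrections(
        small_matrix, target, eta=0.0, max_rounds=2,
        design_config=dk.DesignConfig(n_cycles=10, seed=0))
    assert all(v == 0.0 for v in corr.values())
    assert len(hist) == 2


def test_calibrate_rejects_frozen_and_unnormalized(small_matrix):
    with pytest.raises(EnergyError):
        dk.calibrate_corrections(small_matrix, {"G": 1.0})
    with pytest.raises(EnergyError):
        dk.calibrate_corrections(small_matrix, {"A": 0.6, "V": 0.6})


def test_calibrate_moves_composition_toward_target(small_matrix):
    """The returned corrections achieve a composition divergence no worse
    than the uncalibrated design (round 0)."""
    target = {"A": 0.4, "V": 0.3, "S": 0.2, "D": 0.1}
    corr, hist = dk.calibrate_corrections(
        small_matrix, target, eta=0.5, max_rounds=6,
        design_config=dk.DesignConfig(n_cycles=60, seed=11))
    assert min(hist) <= hist[0] + 1e-9
    assert min(hist) < hist[0]  # it actually improves on this system
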