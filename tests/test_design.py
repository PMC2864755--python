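"""Optimizer and baseline sequence generators."""

import numpy as np
import pytest

import designkit as dk
from designkit.design import DesignConfig, DesignError

from conftest import enumerate_gmec, random_matrix


def test_single_position_finds_global_minimum():
    rng = np.random.default_rng(0)
    M = random_matrix(rng, n_pos=1)
    rec = dk.heuristic_cycle(M, DesignConfig(n_cycles=1, seed=0),
                             np.random.default_rng(5))
    gmec, s = enumerate_gmec(M)
    assert rec.dg_fold == pytest.approx(gmec)
    assert rec.rotamers == s


def test_cycle_energy_never_exceeds_start():
    rng = np.random.default_rng(1)
    for trial in range(10):
        M = random_matrix(rng, n_pos=4)
        start_rng = np.random.default_rng(trial)
        rec = dk.heuristic_cycle(M, DesignConfig(n_cycles=1, seed=0),
                                 start_rng)
        # replay the random initial state to get its energy
        replay = np.random.default_rng(trial)
        s0 = [int(replay.choice(np.arange(M.n_states(p))))
              for p in range(4)]
        assert rec.dg_fold <= M.energy(s0) + 1e-9


def test_gmec_recovery_on_small_instances():
    """Best of 25 cycles hits the exhaustive optimum on most random
    3-position instances (subset here; the full census is run by the
    acceptance suite)."""
    rng = np.random.default_rng(2024)
    hits = 0
    for inst in range(20):
        M = random_matrix(rng)
        gmec, _ = enumerate_gmec(M)
        best = min(
            dk.heuristic_cycle(M, DesignConfig(n_cycles=1, seed=0),
                               np.random.default_rng([inst, c])).dg_fold
            for c in range(25))
        hits += abs(best - gmec) < 1e-9
    assert hits >= 18


def test_run_design_deterministic_and_sorted(design_matrix):
    _, _, M = design_matrix
    cfg = DesignConfig(n_cycles=30, seed=7)
    e1 = dk.run_design(M, cfg)
    e2 = dk.run_design(M, cfg)
    assert e1.to_tsv() == e2.to_tsv()
    assert e1.to_fasta() == e2.to_fasta()
    energies = e1.energies
    assert (np.diff(energies) >= -1e-12).all()


def test_select_k_and_best_so_far_monotone(design_matrix):
    _, _, M = design_matrix
    full = dk.run_design(M, DesignConfig(n_cycles=12, seed=3,
                                         select_k=100))
    assert len(full) == 12  # select_k >= n_cycles keeps everything
    best = [dk.run_design(M, DesignConfig(n_cycles=n, seed=3)).energies[0]
            for n in (3, 6, 12)]
    assert best[0] >= best[1] >= best[2]


def test_dg_reproducible_from_matrix(design_matrix):
    _, _, M = design_matrix
    ens = dk.run_design(M, DesignConfig(n_cycles=5, seed=1))
    for rec in ens.records:
        assert M.energy(list(rec.rotamers)) == pytest.approx(
            rec.dg_fold, abs=1e-6)
        assert rec.sequence == "".join(
            M.states[p][rec.rotamers[p]][0] for p in range(M.n_positions))


def test_frozen_overrides_respected(design_matrix):
    _, _, M = design_matrix
    cfg = DesignConfig(n_cycles=8, seed=5, frozen_overrides={2: "S"})
    ens = dk.run_design(M, cfg)
    assert all(rec.sequence[2] == "S" for rec in ens.records)


def test_frozen_positions_never_mutate():
    tpl = dk.make_structure(
        dk.FixtureSpec(kind="helix", length=6, sequence="AVCAVA"))
    lib = dk.grid_library(types="AVSD", max_chi=1)
    from conftest import RIGID
    M = dk.build_energy_matrix(tpl, lib, RIGID)
    ens = dk.run_design(M, DesignConfig(n_cycles=10, seed=2))
    assert all(rec.sequence[2] == "C" for rec in ens.records)


# -- restrained optimization ----------------------------------------------

def _matrix_with_types(types, rng, n_pos=3):
    return random_matrix(rng, n_pos=n_pos, types=types, n_rot=1)


def test_restrained_keeps_flavor():
    """A start Phe may move to Tyr but never to Trp under the nine-class
    alphabet ({FY} vs {W})."""
    rng = np.random.default_rng(9)
    for trial in range(10):
        M = _matrix_with_types(("F", "Y", "W", "A"), rng)
        start = [0, 0, 0]  # all F
        rec = dk.restrained_cycle(M, DesignConfig(n_cycles=1, seed=0),
                                  np.random.default_rng(trial), start,
                                  flavor_of="nine")
        assert set(rec.sequence) <= {"F", "Y"}


def test_restrained_energy_dominates_unrestrained():
    rng = np.random.default_rng(10)
    for trial in range(10):
        M = _matrix_with_types(("F", "Y", "W", "A"), rng)
        start = [0, 0, 0]
        restrained = dk.restrained_cycle(
            M, DesignConfig(n_cycles=1, seed=0),
            np.random.default_rng(trial), start)
        gmec, _ = enumerate_gmec(M)
        assert restrained.dg_fold >= gmec - 1e-9


# -- rotamer-only optimization --------------------------------------------

def test_rotamer_only_single_rotamer_is_static(design_matrix):
    tpl, lib, _ = design_matrix
    from conftest import RIGID
    one_rot = dk.grid_library(types="AVLSDKRE", max_chi=0)
    M1 = dk.build_energy_matrix(tpl, one_rot, RIGID)
    seq = "VLKDSERA"
    r1 = dk.rotamer_only_optimize(M1, seq,
                                  rng=np.random.default_rng(0))
    r2 = dk.rotamer_only_optimize(M1, seq,
                                  rng=np.random.default_rng(99))
    assert r1.dg_fold == pytest.approx(r2.dg_fold)
    assert r1.sequence == seq


def test_rotamer_only_beats_random_assignments(design_matrix):
    _, _, M = design_matrix
    seq = "VLKDSERA"
    opt = dk.rotamer_only_optimize(M, seq, rng=np.random.default_rng(1))
    rng = np.random.default_rng(2)
    allowed = []
    for p, aa in enumerate(seq):
        allowed.append([i for i, (t, _) in enumerate(M.states[p])
                        if t == aa])
    for _ in range(50):
        s = [int(rng.choice(a)) for a in allowed]
        assert opt.dg_fold <= M.energy(s) + 1e-9


def test_rotamer_only_unknown_type_errors(design_matrix):
    _, _, M = design_matrix
    with pytest.raises(DesignError):
        dk.rotamer_only_optimize(M, "WWWWWWWW")


# -- profile sampling ------------------------------------------------------

def test_profile_sampling_delta_columns():
    profile = [{"A": 1.0}, {"V": 1.0}, {"L": 1.0}]
    seqs = dk.sample_from_profile(profile, 5, np.random.default_rng(0))
    assert seqs == ["AVL"] * 5


def test_profile_sampling_marginals_within_multinomial_bands():
    profile = [{"A": 0.5, "V": 0.3, "L": 0.2}] * 4
    n = 10000
    seqs = dk.sample_from_profile(profile, n, np.random.default_rng(42))
    for c in range(4):
        col = [s[c] for s in seqs]
        for aa, p in profile[c].items():
            f = col.count(aa) / n
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(f - p) < 3.5 * sigma


def test_profile_sampling_destroys_correlations():
    """Sampling i.i.d. per column erases the coupling a planted MSA has."""
    spec = dk.PlantedMSASpec(
        n_sequences=400, length=10, seed=5,
        coupled_pairs=[(2, 7, [("A", "K", 0.5), ("V", "D", 0.5)])])
    msa, truth = dk.make_planted_msa(spec)
    planted_mi = dk.mutual_information_matrix(msa, "nine")
    i, j = truth["coupled_pairs"][0]
    planted_peak = planted_mi.values[i, j]
    profile = [msa.frequencies(c) for c in range(10)]
    sampled = dk.MSA(dk.sample_from_profile(
        profile, 400, np.random.default_rng(6)))
    sampled_mi = dk.mutual_information_matrix(sampled, "nine")
    off = sampled_mi.values.copy()
    np.fill_diagonal(off, 0.0)
    assert off.max() < planted_peak / 3


def test_profile_sampling_empty_column_errors():
    with pytest.raises(DesignError):
        dk.sample_from_profile([{"-": 1.0}], 1, np.random.default_rng(0))


# -- random-identity baselines --------------------------------------------

def test_random_identity_full_identity_is_native():
    tpl = dk.make_structure(dk.FixtureSpec(kind="helix", length=10))
    seqs = dk.random_identity_sequences(tpl, 100.0, 3,
                                        np.random.default_rng(0))
    assert seqs == [tpl.sequence] * 3


def test_random_identity_hits_target_mean():
    tpl = dk.make_structure(dk.FixtureSpec(kind="strand", length=40))
    rng = np.random.default_rng(1)
    seqs = dk.random_identity_sequences(tpl, 55.0, 300, rng)
    idents = [dk.identity_score(s, tpl.sequence) for s in seqs]
    assert abs(np.mean(idents) - 55.0) < 2.0


def test_random_identity_preserves_marked_positions():
    tpl = dk.make_structure(
        dk.FixtureSpec(kind="strand", length=12, sequence="AVCLKDCERAVL"))
    rng = np.random.default_rng(2)
    seqs = dk.random_identity_sequences(tpl, 40.0, 50, rng,
                                        preserve=(2, 6))
    for s in seqs:
        assert s[2] == "C" and s[6] == "C"


def test_random_identity_below_floor_errors():
    tpl = dk.make_structure(dk.FixtureSpec(kind="helix", length=10))
    with pytest.raises(DesignError):
        dk.random_identity_sequences(tpl, 5.0, 1,
                                     np.random.default_rng(0),
                                     preserve=range(5))


# -- identity vs energy ----------------------------------------------------

def test_identity_vs_energy_counts_conserved(design_matrix):
    tpl, _, M = design_matrix
    ens = dk.run_design(M, DesignConfig(n_cycles=25, seed=4))
    table = dk.identity_vs_energy(ens, tpl.sequence)
    assert sum(row["count"] for row in table) == len(ens)


def test_identity_vs_energy_single_record(design_matrix):
    tpl, _, M = design_matrix
    ens = dk.run_design(M, DesignConfig(n_cycles=1, seed=4))
    table = dk.identity_vs_energy(ens, tpl.sequence)
    assert len(table) == 1 and table[0]["count"] == 1


def test_identity_vs_energy_planted_trend():
    """On an ensemble constructed so identity rises as energy falls, the
    fitted identity-vs-energy slope is negative."""
    from designkit.design import DesignEnsemble, DesignRecord
    from designkit.energetics import FoldEnergyBreakdown

    ref = "AVLD" * 5
    rng = np.random.default_rng(8)
    records = []
    for k in range(200):
        energy = -100.0 + k  # ascending
        n_mut = int(round(k / 200 * 10))  # more mutations at high energy
        seq = list(ref)
        for pos in rng.choice(20, size=n_mut, replace=False):
            seq[pos] = "K"
        bd = FoldEnergyBreakdown(vdw=energy, coulomb=0.0, surface=0.0,
                                 unfolded=0.0, n_residues=20)
        records.append(DesignRecord(sequence="".join(seq), rotamers=(),
                                    dg_fold=energy, breakdown=bd))
    ens = DesignEnsemble(records=records)
    table = dk.identity_vs_energy(ens, ref)
    xs = [row["mean_energy"] for row in table]
    ys = [row["mean_identity"] for row in table]
    slope = np.polyfit(xs, ys, 1)[0]
    assert slope < 0
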