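"""Effective energy for fixed-backbone design.

The score is a molecular-mechanics + implicit-solvent ("CASA") energy:

    E = E_vdW + E_Coulomb / eps + a * sum_i sigma_i * A_i

where the Coulomb term is screened by a uniform dielectric (eps = 10 during
design), A_i is the solvent-accessible surface area of atom i, sigma_i an
atomic solvation coefficient by atom class (0.012 kcal/mol/A^2 for C/S,
-0.06 for O/N, 0 for H, -0.15 for ionized groups) and ``a`` an overall
surface scale.

Surface areas come either from an exact Lee-Richards computation
(:func:`sasa_exact`) or from the pairwise contact-area approximation
(:func:`sasa_pairwise_approx`): each atom's buried area is the sum of
two-sphere lens areas against its neighbours.  The approximation makes the
surface term decompose over residue pairs, which is what allows the whole
design energy to be precomputed as a (position, type, rotamer) singleton +
pairwise matrix (:func:`build_energy_matrix`).

The folding free energy of a sequence is the folded-state energy minus a
per-type unfolded reference: the best Ala-X-Ala tripeptide energy over a
small backbone catalog and the rotamers of X, plus an optional empirical
composition correction.  Negative values mean stable folding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.distance import cdist

from .structure import (
    AA1,
    DESIGNABLE_TYPES,
    FROZEN_TYPES,
    AtomGroup,
    BackboneTemplate,
    ParameterSet,
    Rotamer,
    RotamerLibrary,
    StructureError,
    build_chain_backbone,
    excluded_pairs,
    get_topology,
    place_rotamer,
)

__all__ = [
    "KCOUL",
    "EnergyModel",
    "EnergyError",
    "UnfoldedReference",
    "FoldEnergyBreakdown",
    "PairEnergyMatrix",
    "InteractionComponents",
    "coulomb_energy",
    "lj_energy",
    "surface_energy",
    "sasa_exact",
    "sasa_pairwise_approx",
    "buried_lens_areas",
    "pair_interaction_energy",
    "build_energy_matrix",
    "unfolded_reference_energy",
    "compute_unfolded_reference",
    "fold_free_energy",
    "casa_breakdown",
    "minimize_structure",
    "calibrate_corrections",
]

#: Coulomb constant, kcal*A/(mol*e^2).
KCOUL = 332.0636

#: (phi, psi) catalog for the Ala-X-Ala unfolded-state scan: ideal helix,
#: sheet, polyproline-II-like and fully extended backbones.
DEFAULT_PHI_PSI_CATALOG = (
    (-57.0, -47.0), (-119.0, 113.0), (-75.0, 145.0), (-180.0, 180.0))

#: Pair entries above this (kcal/mol) are stored as computed but flagged.
ENERGY_CAP = 100.0

#: Latitude slices used for in-context Lee-Richards areas inside the energy
#: model (identical wherever the model is evaluated, so decompositions are
#: exact); standalone sasa_exact calls default to a finer 400.
_SASA_SLICES = 120


class EnergyError(ValueError):
    """Raised for ill-posed energy evaluations."""


@dataclass(frozen=True)
class EnergyModel:
    """Tunable knobs of the effective energy.

    eps_design: dielectric during design (dimensionless); eps_prep:
    dielectric for structure preparation; surface_scale: overall surface
    factor; probe_radius in A; cutoff: residue-pair (CB-CB) distance in A
    beyond which pair entries are exactly zero; pair_min_steps: relaxation
    iterations per stage of the pair protocol (0 = rigid rotamers)."""

    eps_design: float = 10.0
    eps_prep: float = 20.0
    surface_scale: float = 1.0
    probe_radius: float = 1.4
    cutoff: float = 14.0
    pair_min_steps: int = 15

    def __post_init__(self):
        if self.eps_design <= 0 or self.eps_prep <= 0:
            raise EnergyError("dielectric must be positive")
        if self.probe_radius < 0 or self.pair_min_steps < 0:
            raise EnergyError("probe_radius and pair_min_steps must be >= 0")


# --------------------------------------------------------------------------
# Nonbonded terms
# --------------------------------------------------------------------------

def _pair_mask(n_a, n_b, excluded, intra):
    """Boolean inclusion mask; for intra sets only the upper triangle."""
    if intra:
        mask = np.triu(np.ones((n_a, n_a), dtype=bool), k=1)
    else:
        mask = np.ones((n_a, n_b), dtype=bool)
    if excluded:
        for i, j in excluded:
            mask[i, j] = False
            if intra:
                mask[j, i] = False
    return mask


def coulomb_energy(atoms_a: AtomGroup, atoms_b: AtomGroup | None = None,
                   eps: float = 10.0, excluded=None) -> float:
    """Screened Coulomb energy sum(k q_i q_j / (eps r_ij)), kcal/mol.

    With one group, all internal pairs are summed; with two, cross pairs
    only.  ``excluded`` lists (i, j) index pairs to skip (1-2/1-3 bonded)."""
    if eps <= 0:
        raise EnergyError("eps must be positive")
    intra = atoms_b is None
    b = atoms_a if intra else atoms_b
    if len(atoms_a) == 0 or len(b) == 0:
        return 0.0
    d = cdist(atoms_a.coords, b.coords)
    mask = _pair_mask(len(atoms_a), len(b), excluded, intra)
    qq = np.outer(atoms_a.charge, b.charge)
    bad = mask & (d < 1e-6) & (np.abs(qq) > 0)
    if bad.any():
        raise EnergyError("coincident charged atoms")
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(mask & (np.abs(qq) > 0), KCOUL * qq / (eps * d), 0.0)
    return float(e.sum())


def lj_energy(atoms_a: AtomGroup, atoms_b: AtomGroup | None = None,
              excluded=None) -> float:
    """Lennard-Jones 12-6 energy with eps_ij = sqrt(eps_i eps_j) and
    rmin_ij = rmin_i + rmin_j (per-atom halves)."""
    intra = atoms_b is None
    b = atoms_a if intra else atoms_b
    if len(atoms_a) == 0 or len(b) == 0:
        return 0.0
    d = cdist(atoms_a.coords, b.coords)
    mask = _pair_mask(len(atoms_a), len(b), excluded, intra)
    if (mask & (d < 1e-9)).any():
        raise EnergyError("zero interatomic distance in LJ evaluation")
    epsij = np.sqrt(np.outer(atoms_a.eps, b.eps))
    rmin = np.add.outer(atoms_a.rmin, b.rmin)
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(mask, rmin / d, 0.0)
        e = epsij * (sr ** 12 - 2.0 * sr ** 6)
    return float(np.where(mask, e, 0.0).sum())


def surface_energy(areas, sigmas, surface_scale: float = 1.0) -> float:
    """Surface term: scale * sum_i sigma_i A_i (kcal/mol)."""
    areas = np.asarray(areas, dtype=float)
    if isinstance(sigmas, AtomGroup):
        sigmas = sigmas.sigma
    return float(surface_scale * np.dot(areas, np.asarray(sigmas)))


# --------------------------------------------------------------------------
# Surface areas
# --------------------------------------------------------------------------

def buried_lens_areas(atoms: AtomGroup, probe: float = 1.4) -> np.ndarray:
    """Matrix b[i, j]: area of (probe-expanded) sphere i buried inside
    sphere j, from the analytic two-sphere lens formula.  Diagonal is 0."""
    n = len(atoms)
    R = atoms.radius + probe
    if n == 0:
        return np.zeros((0, 0))
    d = cdist(atoms.coords, atoms.coords)
    np.fill_diagonal(d, np.inf)
    Ri = R[:, None]
    Rj = R[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = Ri - (d ** 2 + Ri ** 2 - Rj ** 2) / (2.0 * d)
    h = np.clip(h, 0.0, 2.0 * Ri)
    b = 2.0 * math.pi * Ri * h
    b[d >= Ri + Rj] = 0.0
    return b


def sasa_pairwise_approx(atoms: AtomGroup, probe: float = 1.4) -> np.ndarray:
    """Per-atom accessible area under the pairwise contact-area
    approximation: isolated area minus summed two-sphere lens areas,
    clamped at zero."""
    R = atoms.radius + probe
    iso = 4.0 * math.pi * R ** 2
    if len(atoms) == 0:
        return iso
    buried = buried_lens_areas(atoms, probe).sum(axis=1)
    return np.maximum(iso - buried, 0.0)


def sasa_exact(atoms: AtomGroup, probe: float = 1.4,
               n_slices: int = 400, subset=None) -> np.ndarray:
    """Per-atom solvent-accessible areas by the Lee-Richards construction.

    Each atom's sphere is cut into latitude slices; the accessible arc of
    each slice circle is found by subtracting the azimuth intervals blocked
    by neighbouring spheres and converted to area with the exact hat-box
    weight 2*pi*R*dz.  When an atom's neighbour caps are pairwise disjoint
    on its sphere the exact analytic cap formula is used instead (the
    slicing limit), so isolated atoms and all two-body systems are exact.

    ``subset`` restricts the computation to the given atom indices (all
    atoms still occlude); other entries of the returned array are zero.
    """
    n = len(atoms)
    R = atoms.radius + probe
    areas = np.zeros(n)
    if n == 0:
        return areas
    coords = atoms.coords
    d = cdist(coords, coords)
    for i in (range(n) if subset is None else subset):
        Ri = R[i]
        nb = [j for j in range(n)
              if j != i and d[i, j] < Ri + R[j] and d[i, j] > 0]
        if any(d[i, j] <= R[j] - Ri for j in nb):
            areas[i] = 0.0  # engulfed
            continue
        nb = [j for j in nb if d[i, j] > Ri - R[j]]  # j engulfed by i: no cap
        if not nb:
            areas[i] = 4.0 * math.pi * Ri ** 2
            continue
        # cap axis unit vectors and angular radii on sphere i
        axes = []
        alphas = []
        for j in nb:
            dij = d[i, j]
            cosa = (dij ** 2 + Ri ** 2 - R[j] ** 2) / (2.0 * dij * Ri)
            alphas.append(math.acos(max(-1.0, min(1.0, cosa))))
            axes.append((coords[j] - coords[i]) / dij)
        disjoint = True
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                gamma = math.acos(max(-1.0, min(
                    1.0, float(np.dot(axes[a], axes[b])))))
                if gamma < alphas[a] + alphas[b]:
                    disjoint = False
                    break
            if not disjoint:
                break
        if disjoint:
            caps = sum(2.0 * math.pi * Ri ** 2 * (1.0 - math.cos(al))
                       for al in alphas)
            areas[i] = 4.0 * math.pi * Ri ** 2 - caps
            continue
        areas[i] = _sasa_sliced(coords, R, d, i, nb, n_slices)
    return areas


def _sasa_sliced(coords, R, d, i, nb, n_slices) -> float:
    """Accessible area of sphere i by z-slicing with arc clipping.

    Vectorized over (slice, neighbour); only slices blocked by two or more
    arcs need an explicit interval union."""
    Ri = R[i]
    ci = coords[i]
    nbc = coords[nb]
    Rj = R[nb]
    dxy = nbc[:, :2] - ci[:2]
    dd = np.hypot(dxy[:, 0], dxy[:, 1])
    mid = np.arctan2(dxy[:, 1], dxy[:, 0])
    dz = 2.0 * Ri / n_slices
    zs = ci[2] - Ri + (np.arange(n_slices) + 0.5) * dz
    rho = np.sqrt(np.maximum(Ri ** 2 - (zs - ci[2]) ** 2, 0.0))
    # neighbour slice-circle radii: (n_slices, n_nb)
    rj2 = Rj[None, :] ** 2 - (zs[:, None] - nbc[None, :, 2]) ** 2
    act = rj2 > 0
    rj = np.sqrt(np.where(act, rj2, 0.0))
    overlap = act & (dd[None, :] < rho[:, None] + rj) & (rho[:, None] > 0)
    swallowed = (overlap & (dd[None, :] + rho[:, None] <= rj)).any(axis=1)
    inside = overlap & (dd[None, :] + rj <= rho[:, None])
    arcs = overlap & ~inside
    with np.errstate(divide="ignore", invalid="ignore"):
        cosw = ((dd[None, :] ** 2 + rho[:, None] ** 2 - rj ** 2)
                / (2.0 * dd[None, :] * rho[:, None]))
    w = np.arccos(np.clip(cosw, -1.0, 1.0))
    n_arcs = arcs.sum(axis=1)
    frac = np.zeros(n_slices)
    simple = (~swallowed) & (n_arcs == 1)
    if simple.any():
        frac[simple] = w[simple][arcs[simple]] / math.pi
    complex_slices = np.where((~swallowed) & (n_arcs >= 2))[0]
    for k in complex_slices:
        sel = arcs[k]
        blocked = list(zip(mid[sel] - w[k, sel], mid[sel] + w[k, sel]))
        frac[k] = _circular_union(blocked)
    frac[swallowed] = 1.0
    frac[rho <= 0] = 1.0
    return float(((1.0 - frac) * 2.0 * math.pi * Ri * dz).sum())


def _circular_union(intervals) -> float:
    """Fraction of the circle covered by the union of angle intervals."""
    if not intervals:
        return 0.0
    two_pi = 2.0 * math.pi
    segs = []
    for a, b in intervals:
        width = b - a
        if width >= two_pi:
            return 1.0
        a %= two_pi
        b = a + width
        if b > two_pi:
            segs.append((a, two_pi))
            segs.append((0.0, b - two_pi))
        else:
            segs.append((a, b))
    segs.sort()
    covered = 0.0
    cur_a, cur_b = segs[0]
    for a, b in segs[1:]:
        if a > cur_b:
            covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    covered += cur_b - cur_a
    return min(1.0, covered / two_pi)


def _lens_onesided(a: AtomGroup, b: AtomGroup, probe: float) -> float:
    """Sigma-weighted area that atoms of ``a`` lose to the spheres of ``b``
    under the two-sphere lens formula (one direction only)."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    g = AtomGroup.concat([a, b])
    lens = buried_lens_areas(g, probe)
    na = len(a)
    return float(np.dot(a.sigma, lens[:na, na:].sum(axis=1)))


def _lens_sigma_cross(a: AtomGroup, b: AtomGroup, probe: float) -> float:
    """Sigma-weighted surface area lost to contacts between groups a and b
    (both directions)."""
    return _lens_onesided(a, b, probe) + _lens_onesided(b, a, probe)


def _context_sigma_area(target: AtomGroup, context: AtomGroup, probe: float,
                        n_slices: int = _SASA_SLICES) -> float:
    """Sigma-weighted exact accessible area of ``target`` atoms in the
    presence of ``context`` atoms (context areas are not evaluated)."""
    if len(target) == 0:
        return 0.0
    g = AtomGroup.concat([target, context])
    areas = sasa_exact(g, probe, n_slices=n_slices,
                       subset=range(len(target)))
    return float(np.dot(target.sigma, areas[: len(target)]))


# --------------------------------------------------------------------------
# Unfolded reference
# --------------------------------------------------------------------------

@dataclass
class UnfoldedReference:
    """Per-type unfolded-state energies (Ala-X-Ala minimum) plus optional
    empirical composition corrections (default 0)."""

    e_ref: dict[str, float]
    correction: dict[str, float] = field(default_factory=dict)

    def total(self, aa: str) -> float:
        return self.e_ref[aa] + self.correction.get(aa, 0.0)

    @classmethod
    def zero(cls, types=AA1) -> "UnfoldedReference":
        return cls({aa: 0.0 for aa in types})


class InteractionComponents(NamedTuple):
    vdw: float
    coulomb: float
    surface: float


@dataclass
class FoldEnergyBreakdown:
    """Folding free energy and its channels (kcal/mol).

    total = vdw + coulomb + surface - unfolded; negative = stable."""

    vdw: float
    coulomb: float
    surface: float
    unfolded: float
    n_residues: int

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb + self.surface - self.unfolded

    @property
    def per_residue(self) -> dict[str, float]:
        n = max(1, self.n_residues)
        return {"total": self.total / n, "vdw": self.vdw / n,
                "coulomb": self.coulomb / n, "surface": self.surface / n,
                "unfolded": self.unfolded / n}


# --------------------------------------------------------------------------
# System assembly and direct (whole-system) evaluation
# --------------------------------------------------------------------------

_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("N", "H")]


def _backbone_group(template: BackboneTemplate) -> AtomGroup:
    params = template.params()
    specs, residue = [], []
    for k, pos in enumerate(template.positions):
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                specs.append(params.spec(pos.native_type, name,
                                         pos.backbone[name]))
                residue.append(k)
    return AtomGroup.from_specs(specs, residue=residue)


def _assemble(template: BackboneTemplate, assignment):
    """Assemble a full sequence onto the template.

    ``assignment`` is a list over positions of either None (frozen native
    side chain) or (aa, Rotamer).  Returns (AtomGroup of all atoms,
    excluded index pairs, per-position side-chain AtomGroups)."""
    keys: list[str] = []
    specs = []
    residue = []
    bonds: list[tuple[str, str]] = []
    sc_groups: list[AtomGroup] = []
    params = template.params()
    for k, pos in enumerate(template.positions):
        a = assignment[k]
        aa = pos.native_type if a is None else a[0]
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                keys.append(f"{k}:{name}")
                specs.append(params.spec(aa, name, pos.backbone[name]))
                residue.append(k)
        if a is None:
            sc = pos.frozen_sidechain or []
        else:
            sc = place_rotamer(template, k, aa, a[1])
        for atom in sc:
            keys.append(f"{k}:{atom.name}")
            specs.append(atom)
            residue.append(k)
        sc_groups.append(AtomGroup.from_specs(sc))
        present = {name for name in pos.backbone} | {s.name for s in sc}
        for x, y in get_topology(aa).bonds:
            if x in present and y in present:
                bonds.append((f"{k}:{x}", f"{k}:{y}"))
        if k + 1 < len(template.positions):
            bonds.append((f"{k}:C", f"{k + 1}:N"))
    group = AtomGroup.from_specs(specs, residue=residue)
    excl = excluded_pairs(bonds, keys)
    return group, excl, sc_groups


def casa_breakdown(template: BackboneTemplate, assignment,
                   model: EnergyModel | None = None,
                   unfolded: UnfoldedReference | None = None,
                   ) -> FoldEnergyBreakdown:
    """Direct whole-system evaluation of the design energy on assembled
    coordinates (rigid rotamers, no cutoff).

    The surface term follows the model's residue-pair decomposition: exact
    Lee-Richards areas for the backbone alone and for each side chain in
    the context of its own backbone, minus analytic two-sphere contact
    areas for side-chain/backbone and side-chain/side-chain cross burial.
    """
    model = model or EnergyModel()
    group, excl, sc_groups = _assemble(template, assignment)
    bb = _backbone_group(template)
    vdw = lj_energy(group, excluded=excl)
    coul = coulomb_energy(group, eps=model.eps_design, excluded=excl)
    pr = model.probe_radius
    surf = _context_sigma_area(bb, AtomGroup.from_specs([]), pr)
    for sc in sc_groups:
        if len(sc):
            surf += _context_sigma_area(sc, bb, pr)
            surf -= _lens_onesided(bb, sc, pr)
    for p in range(len(sc_groups)):
        for q in range(p + 1, len(sc_groups)):
            if len(sc_groups[p]) and len(sc_groups[q]):
                surf -= _lens_sigma_cross(sc_groups[p], sc_groups[q], pr)
    surf *= model.surface_scale
    if unfolded is None:
        unf = 0.0
    else:
        unf = sum(unfolded.total(
            pos.native_type if assignment[k] is None else assignment[k][0])
            for k, pos in enumerate(template.positions))
    return FoldEnergyBreakdown(vdw=vdw, coulomb=coul, surface=surf,
                               unfolded=unf, n_residues=len(template))


# --------------------------------------------------------------------------
# Relaxation (shared by pair protocol and structure preparation)
# --------------------------------------------------------------------------

def _restraint_terms(group: AtomGroup, bond_pairs):
    """Harmonic 1-2 and 1-3 distance restraints to the input geometry.

    Radial restraints stand in for bond and angle terms during Cartesian
    relaxation; force constants are fixed package defaults."""
    adj: dict[int, set[int]] = {}
    for i, j in bond_pairs:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    pairs = []
    for i, js in adj.items():
        for j in js:
            if j > i:
                pairs.append((i, j, 300.0))
        for j in js:
            for k in adj[j]:
                if k > i and k not in js:
                    pairs.append((i, k, 50.0))
    idx = np.array([(p[0], p[1]) for p in pairs], dtype=int).reshape(-1, 2)
    kk = np.array([p[2] for p in pairs])
    if len(idx):
        r0 = np.linalg.norm(group.coords[idx[:, 0]]
                            - group.coords[idx[:, 1]], axis=1)
    else:
        r0 = np.zeros(0)
    return idx, kk, r0


def _relax(group: AtomGroup, move: np.ndarray, excl, eps: float,
           steps: int, bond_pairs) -> AtomGroup:
    """Minimize vdW + screened Coulomb + geometry restraints over the
    coordinates of atoms flagged in ``move`` (L-BFGS, ``steps`` iterations).
    The surface term is not part of the relaxation objective."""
    if steps <= 0 or not move.any():
        return group
    n = len(group)
    mask = _pair_mask(n, n, excl, intra=True)
    both_fixed = np.outer(~move, ~move)
    mask = mask & ~both_fixed
    epsij = np.sqrt(np.outer(group.eps, group.eps))
    rmin = np.add.outer(group.rmin, group.rmin)
    qq = KCOUL * np.outer(group.charge, group.charge) / eps
    ridx, kk, r0 = _restraint_terms(group, bond_pairs)
    move_idx = np.where(move)[0]
    base = group.coords.copy()

    def fg(x):
        coords = base.copy()
        coords[move_idx] = x.reshape(-1, 3)
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(d, 1.0)
        inv = 1.0 / np.maximum(d, 1e-3)
        sr6 = (rmin * inv) ** 6
        e_lj = np.where(mask, epsij * (sr6 ** 2 - 2 * sr6), 0.0)
        e_c = np.where(mask, qq * inv, 0.0)
        # dE/dr
        dlj = np.where(mask, epsij * (-12 * sr6 ** 2 + 12 * sr6) * inv, 0.0)
        dc = np.where(mask, -qq * inv ** 2, 0.0)
        dEdr = dlj + dc
        gvec = (dEdr[:, :, None] * diff * inv[:, :, None])
        grad = gvec.sum(axis=1) - gvec.sum(axis=0)
        e = e_lj.sum() + e_c.sum()
        if len(ridx):
            dv = coords[ridx[:, 0]] - coords[ridx[:, 1]]
            dr = np.linalg.norm(dv, axis=1)
            e += (kk * (dr - r0) ** 2).sum()
            f = (2 * kk * (dr - r0) / np.maximum(dr, 1e-9))[:, None] * dv
            np.add.at(grad, ridx[:, 0], f)
            np.add.at(grad, ridx[:, 1], -f)
        return e, grad[move_idx].ravel()

    res = _scipy_minimize(fg, base[move_idx].ravel(), jac=True,
                          method="L-BFGS-B",
                          options={"maxiter": steps, "maxls": 40})
    out = base.copy()
    out[move_idx] = res.x.reshape(-1, 3)
    new = AtomGroup(group.names, out, group.charge, group.eps, group.rmin,
                    group.radius, group.sigma, residue=group.residue)
    return new


def _excluded_from_index_bonds(bonds, n):
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    out = set()
    for i in adj:
        for j in adj[i]:
            out.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    out.add((min(i, k), max(i, k)))
    return out


def minimize_structure(group: AtomGroup, bonds, model: EnergyModel,
                       max_steps: int = 500,
                       backbone_mask: np.ndarray | None = None):
    """Conjugate-gradient-style preparation of a whole structure: minimize
    vdW + Coulomb (eps_prep) + geometry restraints over all atoms.

    ``bonds`` lists (i, j) atom-index pairs.  Returns (relaxed AtomGroup,
    info) where info reports initial/final energies and the RMSD of
    ``backbone_mask`` atoms (all atoms when no mask is given)."""
    idx_bonds = [(int(i), int(j)) for i, j in (bonds or [])]
    excl = _excluded_from_index_bonds(idx_bonds, len(group))

    def energy_of(g):
        return (lj_energy(g, excluded=excl)
                + coulomb_energy(g, eps=model.eps_prep, excluded=excl))

    e0 = energy_of(group)
    if not np.isfinite(e0):
        raise EnergyError("non-finite initial energy")
    move = np.ones(len(group), dtype=bool)
    relaxed = _relax(group, move, excl, model.eps_prep, max_steps, idx_bonds)
    e1 = energy_of(relaxed)
    if e1 > e0:  # descent guarantee: keep input if no improvement
        relaxed, e1 = group, e0
    sel = backbone_mask if backbone_mask is not None else move
    rmsd = float(np.sqrt(((relaxed.coords[sel] - group.coords[sel]) ** 2)
                         .sum(axis=1).mean())) if sel.any() else 0.0
    return relaxed, {"energy_initial": e0, "energy_final": e1,
                     "backbone_rmsd": rmsd}


# --------------------------------------------------------------------------
# Pair interaction protocol
# --------------------------------------------------------------------------

def _residue_context(template, k, aa, sc_atoms):
    """Atom group of side chain k plus the full backbone, with exclusions
    and bond list; side-chain atoms come last."""
    params = template.params()
    keys, specs, bonds = [], [], []
    for m, pos in enumerate(template.positions):
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                keys.append(f"{m}:{name}")
                specs.append(params.spec(
                    aa if m == k else pos.native_type, name,
                    pos.backbone[name]))
        if m + 1 < len(template.positions):
            bonds.append((f"{m}:C", f"{m + 1}:N"))
        for x, y in _BACKBONE_BONDS:
            bonds.append((f"{m}:{x}", f"{m}:{y}"))
    n_bb = len(keys)
    present = set(n for n in template.positions[k].backbone)
    present |= {a.name for a in sc_atoms}
    for atom in sc_atoms:
        keys.append(f"{k}:{atom.name}")
        specs.append(atom)
    for x, y in get_topology(aa).bonds:
        if x in present and y in present:
            bonds.append((f"{k}:{x}", f"{k}:{y}"))
    group = AtomGroup.from_specs(
        specs, residue=[int(key.split(":")[0]) for key in keys])
    excl = excluded_pairs(bonds, keys)
    move = np.zeros(len(group), dtype=bool)
    move[n_bb:] = True
    idx_bonds = []
    key_index = {key: i for i, key in enumerate(keys)}
    for x, y in bonds:
        if x in key_index and y in key_index:
            idx_bonds.append((key_index[x], key_index[y]))
    return group, excl, move, idx_bonds


def _relax_sidechain(template, k, aa, sc_atoms, model):
    """Stage-1 relaxation: one side chain against the fixed backbone."""
    group, excl, move, idx_bonds = _residue_context(template, k, aa, sc_atoms)
    relaxed = _relax(group, move, excl, model.eps_design,
                     model.pair_min_steps, idx_bonds)
    n_sc = int(move.sum())
    out = []
    for atom, xyz in zip(sc_atoms, relaxed.coords[-n_sc:] if n_sc else []):
        out.append(replace_coords(atom, xyz))
    return out


def replace_coords(atom, xyz):
    from dataclasses import replace as _dc_replace
    return _dc_replace(atom, coords=np.asarray(xyz, dtype=float))


def _cross_components(sc_i: AtomGroup, sc_j: AtomGroup,
                      model: EnergyModel) -> InteractionComponents:
    vdw = lj_energy(sc_i, sc_j)
    coul = coulomb_energy(sc_i, sc_j, eps=model.eps_design)
    surf = -model.surface_scale * _lens_sigma_cross(
        sc_i, sc_j, model.probe_radius)
    return InteractionComponents(vdw, coul, surf)


def pair_interaction_energy(template: BackboneTemplate, i: int, state_i,
                            j: int, state_j,
                            model: EnergyModel | None = None,
                            ) -> InteractionComponents:
    """Interaction energy components between side chains at positions i, j.

    ``state_*`` is (aa, Rotamer).  With pair_min_steps > 0 each side chain
    is first relaxed against the backbone with the partner absent, then the
    pair is relaxed together; components are the cross terms on the final
    geometry.  Beyond the residue cutoff the result is identically zero.
    With pair_min_steps = 0 this is the rigid-rotamer evaluation.
    """
    model = model or EnergyModel()
    if i == j:
        raise EnergyError("pair requires two distinct positions")
    pi, pj = template.positions[i], template.positions[j]
    if np.linalg.norm(pi.cb_anchor - pj.cb_anchor) > model.cutoff:
        return InteractionComponents(0.0, 0.0, 0.0)
    sc_i = place_rotamer(template, i, state_i[0], state_i[1])
    sc_j = place_rotamer(template, j, state_j[0], state_j[1])
    if model.pair_min_steps > 0:
        sc_i = _relax_sidechain(template, i, state_i[0], sc_i, model)
        sc_j = _relax_sidechain(template, j, state_j[0], sc_j, model)
        sc_i, sc_j = _relax_pair(template, i, state_i[0], sc_i,
                                 j, state_j[0], sc_j, model)
    gi = AtomGroup.from_specs(sc_i) if sc_i else AtomGroup.from_specs([])
    gj = AtomGroup.from_specs(sc_j) if sc_j else AtomGroup.from_specs([])
    if len(gi) == 0 or len(gj) == 0:
        return InteractionComponents(0.0, 0.0, 0.0)
    comp = _cross_components(gi, gj, model)
    if not all(math.isfinite(x) for x in comp):
        raise EnergyError("non-finite pair interaction after relaxation")
    return comp


def _relax_pair(template, i, aa_i, sc_i, j, aa_j, sc_j, model):
    """Stage-2 relaxation: both side chains move, pair interactions on."""
    params = template.params()
    keys, specs, bonds = [], [], []
    for m, pos in enumerate(template.positions):
        aa_here = aa_i if m == i else aa_j if m == j else pos.native_type
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                keys.append(f"{m}:{name}")
                specs.append(params.spec(aa_here, name, pos.backbone[name]))
        if m + 1 < len(template.positions):
            bonds.append((f"{m}:C", f"{m + 1}:N"))
        for x, y in _BACKBONE_BONDS:
            bonds.append((f"{m}:{x}", f"{m}:{y}"))
    n_bb = len(keys)
    starts = {}
    for k, aa, sc in ((i, aa_i, sc_i), (j, aa_j, sc_j)):
        starts[k] = len(keys)
        present = set(template.positions[k].backbone) | {a.name for a in sc}
        for atom in sc:
            keys.append(f"{k}:{atom.name}")
            specs.append(atom)
        for x, y in get_topology(aa).bonds:
            if x in present and y in present:
                bonds.append((f"{k}:{x}", f"{k}:{y}"))
    group = AtomGroup.from_specs(
        specs, residue=[int(kk.split(":")[0]) for kk in keys])
    excl = excluded_pairs(bonds, keys)
    move = np.zeros(len(group), dtype=bool)
    move[n_bb:] = True
    key_index = {key: t for t, key in enumerate(keys)}
    idx_bonds = [(key_index[x], key_index[y]) for x, y in bonds
                 if x in key_index and y in key_index]
    relaxed = _relax(group, move, excl, model.eps_design,
                     model.pair_min_steps, idx_bonds)
    out_i = [replace_coords(a, relaxed.coords[starts[i] + t])
             for t, a in enumerate(sc_i)]
    out_j = [replace_coords(a, relaxed.coords[starts[j] + t])
             for t, a in enumerate(sc_j)]
    return out_i, out_j


# --------------------------------------------------------------------------
# Precomputed energy matrix
# --------------------------------------------------------------------------

@dataclass
class PairEnergyMatrix:
    """Precomputed singleton + pairwise design energies.

    states[p] lists (aa_type, rotamer_index) for position p; singleton[p]
    holds per-state channel arrays of shape (n_p, 3) = (vdw, coulomb,
    surface) for folded-state terms involving only that side chain and the
    backbone; eref[p] the per-state unfolded reference (e_ref + correction);
    pairwise[(p, q)] (p < q) arrays of shape (n_p, n_q, 3).  Entries beyond
    the residue cutoff are absent (exactly zero).  ``constant`` holds the
    sequence-independent backbone channels."""

    positions: list[dict]
    states: list[list[tuple[str, int]]]
    singleton: list[np.ndarray]
    eref: list[np.ndarray]
    pairwise: dict[tuple[int, int], np.ndarray]
    constant: np.ndarray
    capped: dict[tuple[int, int], np.ndarray]
    model: EnergyModel
    provenance: str = ""

    @property
    def n_positions(self) -> int:
        return len(self.states)

    def n_states(self, p: int) -> int:
        return len(self.states[p])

    def state_index(self, p: int, aa: str, rot: int) -> int:
        try:
            return self.states[p].index((aa, rot))
        except ValueError:
            raise EnergyError(
                f"state ({aa}, {rot}) not in matrix at position {p}"
            ) from None

    def state_types(self, p: int) -> list[str]:
        return [aa for aa, _ in self.states[p]]

    def singleton_total(self, p: int) -> np.ndarray:
        cache = self.__dict__.setdefault("_cache_singleton", {})
        if p not in cache:
            cache[p] = self.singleton[p].sum(axis=1) - self.eref[p]
        return cache[p]

    def pair_block(self, p: int, q: int) -> np.ndarray | None:
        """Summed-channel pair block oriented (p, q); None beyond cutoff."""
        key = (min(p, q), max(p, q))
        if key not in self.pairwise:
            return None
        cache = self.__dict__.setdefault("_cache_summed", {})
        if key not in cache:
            cache[key] = self.pairwise[key].sum(axis=2)
        blk = cache[key]
        return blk if p < q else blk.T

    def assignment_breakdown(self, s) -> FoldEnergyBreakdown:
        if len(s) != self.n_positions:
            raise EnergyError("assignment length mismatch")
        ch = self.constant.copy()
        unf = 0.0
        for p, sp in enumerate(s):
            if not 0 <= sp < self.n_states(p):
                raise EnergyError(f"state {sp} out of range at position {p}")
            ch += self.singleton[p][sp]
            unf += self.eref[p][sp]
        for (p, q), block in self.pairwise.items():
            ch += block[s[p], s[q]]
        return FoldEnergyBreakdown(vdw=float(ch[0]), coulomb=float(ch[1]),
                                   surface=float(ch[2]), unfolded=float(unf),
                                   n_residues=self.n_positions)

    def energy(self, s) -> float:
        return self.assignment_breakdown(s).total

    def with_corrections(self, correction: dict[str, float]
                         ) -> "PairEnergyMatrix":
        """Return a copy whose unfolded references include per-type
        ``correction`` offsets (cheap: singletons are untouched)."""
        eref = []
        for p in range(self.n_positions):
            delta = np.array([correction.get(aa, 0.0)
                              for aa, _ in self.states[p]])
            eref.append(self.eref[p] + delta)
        return PairEnergyMatrix(
            positions=self.positions, states=self.states,
            singleton=self.singleton, eref=eref, pairwise=self.pairwise,
            constant=self.constant, capped=self.capped, model=self.model,
            provenance=self.provenance)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def arr(a):
            return np.round(np.asarray(a), 9).tolist()
        payload = {
            "format": "designkit-energy-matrix-v1",
            "provenance": self.provenance,
            "model": {
                "eps_design": self.model.eps_design,
                "eps_prep": self.model.eps_prep,
                "surface_scale": self.model.surface_scale,
                "probe_radius": self.model.probe_radius,
                "cutoff": self.model.cutoff,
                "pair_min_steps": self.model.pair_min_steps,
            },
            "positions": self.positions,
            "states": [[[aa, r] for aa, r in st] for st in self.states],
            "singleton": [arr(s) for s in self.singleton],
            "eref": [arr(e) for e in self.eref],
            "constant": arr(self.constant),
            "pairwise": {f"{p},{q}": arr(b)
                         for (p, q), b in sorted(self.pairwise.items())},
            "capped": {f"{p},{q}": np.asarray(c).astype(int).tolist()
                       for (p, q), c in sorted(self.capped.items())},
        }
        return json.dumps(payload, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "PairEnergyMatrix":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "designkit-energy-matrix-v1":
            raise EnergyError(f"{path}: not an energy-matrix file")
        model = EnergyModel(**d["model"])
        pairwise = {}
        capped = {}
        for key, block in d["pairwise"].items():
            p, q = (int(x) for x in key.split(","))
            pairwise[(p, q)] = np.asarray(block, dtype=float)
        for key, block in d["capped"].items():
            p, q = (int(x) for x in key.split(","))
            capped[(p, q)] = np.asarray(block, dtype=bool)
        return cls(
            positions=d["positions"],
            states=[[(aa, int(r)) for aa, r in st] for st in d["states"]],
            singleton=[np.asarray(s, dtype=float) for s in d["singleton"]],
            eref=[np.asarray(e, dtype=float) for e in d["eref"]],
            pairwise=pairwise, constant=np.asarray(d["constant"]),
            capped=capped, model=model, provenance=d.get("provenance", ""))


def _position_states(template, library, p):
    pos = template.positions[p]
    if not pos.designable:
        return [(pos.native_type, 0)]
    return [(aa, r) for aa in DESIGNABLE_TYPES if aa in library
            for r in range(len(library[aa]))]


def _state_sidechain(template, p, aa, rot_index, library, model):
    pos = template.positions[p]
    if not pos.designable:
        sc = pos.frozen_sidechain or []
    else:
        sc = place_rotamer(template, p, aa, library[aa][rot_index])
    if model.pair_min_steps > 0 and sc:
        sc = _relax_sidechain(template, p, aa, sc, model)
    return sc


def build_energy_matrix(template: BackboneTemplate, library: RotamerLibrary,
                        model: EnergyModel | None = None,
                        unfolded: UnfoldedReference | None = None,
                        ) -> PairEnergyMatrix:
    """Precompute all singleton and pairwise design energies.

    Singletons cover side-chain/backbone and intra-side-chain terms plus the
    side chain's own surface contribution (isolated areas minus burial by
    the entire backbone and by itself); pair entries hold pure side-chain x
    side-chain cross terms.  Residue pairs whose CB anchors are farther
    apart than the cutoff are omitted (zero).  Deterministic given inputs.
    """
    model = model or EnergyModel()
    unfolded = unfolded or UnfoldedReference.zero()
    params = template.params()
    L = len(template)
    bb = _backbone_group(template)

    # backbone-only constant channels
    bb_keys, bb_bonds = [], []
    for k, pos in enumerate(template.positions):
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                bb_keys.append(f"{k}:{name}")
        for x, y in _BACKBONE_BONDS:
            bb_bonds.append((f"{k}:{x}", f"{k}:{y}"))
        if k + 1 < L:
            bb_bonds.append((f"{k}:C", f"{k + 1}:N"))
    bb_excl = excluded_pairs(bb_bonds, bb_keys)
    constant = np.array([
        lj_energy(bb, excluded=bb_excl),
        coulomb_energy(bb, eps=model.eps_design, excluded=bb_excl),
        model.surface_scale * _context_sigma_area(
            bb, AtomGroup.from_specs([]), model.probe_radius),
    ])

    states = [_position_states(template, library, p) for p in range(L)]
    for p, st in enumerate(states):
        if not st:
            raise EnergyError(f"position {p} has an empty allowed-state set")
    sidechains: list[list[AtomGroup]] = []
    singleton: list[np.ndarray] = []
    eref: list[np.ndarray] = []
    for p in range(L):
        groups = []
        chan = np.zeros((len(states[p]), 3))
        ers = np.zeros(len(states[p]))
        for si, (aa, ri) in enumerate(states[p]):
            sc = _state_sidechain(template, p, aa, ri, library, model)
            g = AtomGroup.from_specs(sc) if sc else AtomGroup.from_specs([])
            groups.append(g)
            chan[si] = _singleton_channels(template, p, aa, g, bb, model)
            ers[si] = unfolded.total(aa)
        sidechains.append(groups)
        singleton.append(chan)
        eref.append(ers)

    anchors = [pos.cb_anchor for pos in template.positions]
    stacked = [_stack_states(groups) for groups in sidechains]
    pairwise: dict[tuple[int, int], np.ndarray] = {}
    capped: dict[tuple[int, int], np.ndarray] = {}
    for p in range(L):
        for q in range(p + 1, L):
            if np.linalg.norm(anchors[p] - anchors[q]) > model.cutoff:
                continue
            if model.pair_min_steps > 0:
                block = np.zeros((len(states[p]), len(states[q]), 3))
                for si, gi in enumerate(sidechains[p]):
                    if len(gi) == 0:
                        continue
                    for sj, gj in enumerate(sidechains[q]):
                        if len(gj) == 0:
                            continue
                        block[si, sj] = pair_interaction_energy(
                            template, p,
                            (states[p][si][0],
                             library[states[p][si][0]][states[p][si][1]]),
                            q,
                            (states[q][sj][0],
                             library[states[q][sj][0]][states[q][sj][1]]),
                            model)
            else:
                block = _pair_block_rigid(sidechains[p], stacked[q],
                                          len(states[q]), model)
            total = block.sum(axis=2)
            bad = ~np.isfinite(total)
            if bad.any():
                block[bad] = np.array([1e4, 0.0, 0.0])
                total = block.sum(axis=2)
            pairwise[(p, q)] = block
            capped[(p, q)] = total > ENERGY_CAP
    positions = [{"index": pos.index, "native": pos.native_type,
                  "designable": bool(pos.designable)}
                 for pos in template.positions]
    return PairEnergyMatrix(
        positions=positions, states=states, singleton=singleton, eref=eref,
        pairwise=pairwise, constant=constant, capped=capped, model=model)


def _stack_states(groups: list[AtomGroup]):
    """Concatenate per-state side-chain groups into flat arrays with a
    state-id per atom (for batched pair-block evaluation)."""
    coords, charge, eps, rmin, radius, sigma, sid = [], [], [], [], [], [], []
    for s, g in enumerate(groups):
        if len(g) == 0:
            continue
        coords.append(g.coords)
        charge.append(g.charge)
        eps.append(g.eps)
        rmin.append(g.rmin)
        radius.append(g.radius)
        sigma.append(g.sigma)
        sid.append(np.full(len(g), s, dtype=int))
    if not coords:
        return None
    return {
        "coords": np.concatenate(coords),
        "charge": np.concatenate(charge),
        "eps": np.concatenate(eps),
        "rmin": np.concatenate(rmin),
        "radius": np.concatenate(radius),
        "sigma": np.concatenate(sigma),
        "state": np.concatenate(sid),
    }


def _pair_block_rigid(groups_p: list[AtomGroup], stacked_q, n_q: int,
                      model: EnergyModel) -> np.ndarray:
    """Rigid-rotamer (vdw, coulomb, surface) cross terms between every
    state of position p and every state of q, vectorized over q."""
    n_p = len(groups_p)
    block = np.zeros((n_p, n_q, 3))
    if stacked_q is None:
        return block
    Q = stacked_q
    qs = Q["state"]
    probe = model.probe_radius
    Rq = Q["radius"] + probe
    for si, gi in enumerate(groups_p):
        if len(gi) == 0:
            continue
        d = cdist(gi.coords, Q["coords"])
        if (d < 1e-9).any():
            raise EnergyError("zero interatomic distance in pair block")
        # vdW
        epsij = np.sqrt(np.outer(gi.eps, Q["eps"]))
        rmin = np.add.outer(gi.rmin, Q["rmin"])
        sr6 = (rmin / d) ** 6
        vdw = epsij * (sr6 ** 2 - 2.0 * sr6)
        # Coulomb
        coul = KCOUL * np.outer(gi.charge, Q["charge"]) / (
            model.eps_design * d)
        # lens burial, both directions
        Ri = (gi.radius + probe)[:, None]
        Rj = Rq[None, :]
        h_i = np.clip(Ri - (d ** 2 + Ri ** 2 - Rj ** 2) / (2 * d),
                      0.0, 2 * Ri)
        h_j = np.clip(Rj - (d ** 2 + Rj ** 2 - Ri ** 2) / (2 * d),
                      0.0, 2 * Rj)
        sep = d >= Ri + Rj
        b_i = np.where(sep, 0.0, 2 * math.pi * Ri * h_i)
        b_j = np.where(sep, 0.0, 2 * math.pi * Rj * h_j)
        surf = -(model.surface_scale
                 * (gi.sigma[:, None] * b_i + Q["sigma"][None, :] * b_j))
        nb = n_q
        block[si, :, 0] = np.bincount(qs, weights=vdw.sum(axis=0),
                                      minlength=nb)
        block[si, :, 1] = np.bincount(qs, weights=coul.sum(axis=0),
                                      minlength=nb)
        block[si, :, 2] = np.bincount(qs, weights=surf.sum(axis=0),
                                      minlength=nb)
    return block


def _singleton_channels(template, p, aa, sc: AtomGroup, bb: AtomGroup,
                        model: EnergyModel) -> np.ndarray:
    """Folded-state channels of one (position, state): intra-side-chain +
    side-chain/backbone vdW and Coulomb, and the side chain's surface
    share (own isolated area minus burial by itself and the backbone)."""
    if len(sc) == 0:
        return np.zeros(3)
    bb_keys = []
    for m, pos in enumerate(template.positions):
        for name in ("N", "CA", "C", "O", "H"):
            if name in pos.backbone:
                bb_keys.append(f"{m}:{name}")
    keys = bb_keys + [f"{p}:{n}" for n in sc.names]
    bonds = []
    for m, pos in enumerate(template.positions):
        for x, y in _BACKBONE_BONDS:
            bonds.append((f"{m}:{x}", f"{m}:{y}"))
        if m + 1 < len(template.positions):
            bonds.append((f"{m}:C", f"{m + 1}:N"))
    present = set(template.positions[p].backbone) | set(sc.names)
    for x, y in get_topology(aa).bonds:
        if x in present and y in present:
            bonds.append((f"{p}:{x}", f"{p}:{y}"))
    excl_all = excluded_pairs(bonds, keys)
    n_bb = len(bb_keys)
    # split exclusions into (sc, sc) and (bb, sc)
    excl_intra = {(i - n_bb, j - n_bb) for i, j in excl_all
                  if i >= n_bb and j >= n_bb}
    excl_cross = {(i, j - n_bb) for i, j in excl_all
                  if i < n_bb <= j}
    vdw = (lj_energy(sc, excluded=excl_intra)
           + lj_energy(bb, sc, excluded=excl_cross))
    coul = (coulomb_energy(sc, eps=model.eps_design, excluded=excl_intra)
            + coulomb_energy(bb, sc, eps=model.eps_design,
                             excluded=excl_cross))
    surf = model.surface_scale * (
        _context_sigma_area(sc, bb, model.probe_radius)
        - _lens_onesided(bb, sc, model.probe_radius))
    return np.array([vdw, coul, surf])


def fold_free_energy(matrix: PairEnergyMatrix, assignment
                     ) -> FoldEnergyBreakdown:
    """Folding free energy of an assignment (list of state indices)."""
    return matrix.assignment_breakdown(list(assignment))


# --------------------------------------------------------------------------
# Unfolded reference energies
# --------------------------------------------------------------------------

def unfolded_reference_energy(aa: str, library: RotamerLibrary,
                              model: EnergyModel | None = None,
                              parameters: ParameterSet | None = None,
                              catalog=DEFAULT_PHI_PSI_CATALOG) -> float:
    """Reference energy of type X: the minimum Ala-X-Ala tripeptide energy
    over the backbone catalog and the rotamers of X (rigid rotamers)."""
    model = model or EnergyModel()
    params = parameters or ParameterSet.default()
    if aa in library:
        rots = library[aa]
    elif get_topology(aa).n_chi == 0:
        rots = [Rotamer(aa, ())]
    else:
        # type outside the working library (e.g. a frozen native Cys/Pro):
        # score its ideal-geometry side chain
        from .structure import ideal_chis

        rots = [Rotamer(aa, ideal_chis(aa))]
    best = math.inf
    ala = Rotamer("A", ())
    for phi_psi in catalog:
        tpl = build_chain_backbone("A" + aa + "A", [phi_psi] * 3, params)
        # scan rotamers even for the frozen types
        tpl.positions[1].frozen_sidechain = None
        for rot in rots:
            assignment = [("A", ala), (aa, rot), ("A", ala)]
            bd = casa_breakdown(tpl, assignment, model)
            e = bd.vdw + bd.coulomb + bd.surface
            if e < best:
                best = e
    return best


def compute_unfolded_reference(library: RotamerLibrary,
                               model: EnergyModel | None = None,
                               parameters: ParameterSet | None = None,
                               types: str = AA1,
                               catalog=DEFAULT_PHI_PSI_CATALOG
                               ) -> UnfoldedReference:
    return UnfoldedReference(
        {aa: unfolded_reference_energy(aa, library, model, parameters,
                                       catalog)
         for aa in types})


# --------------------------------------------------------------------------
# Composition calibration
# --------------------------------------------------------------------------

def calibrate_corrections(matrix: PairEnergyMatrix, target: dict[str, float],
                          design_config=None, eta: float = 0.5,
                          max_rounds: int = 8,
                          pseudocount: float = 0.5):
    """Iteratively adjust unfolded-reference corrections so the designed
    composition approaches ``target`` over the designable types.

    Each round runs a short design on the adjusted matrix, measures the
    ensemble composition f and updates
    correction(X) += eta_r * ln(target(X) / f(X)) — raising the
    folded-state favourability of under-represented types.  The step size
    is damped over rounds (eta_r = eta / (1 + r), stochastic-approximation
    style) because the short-design composition estimate is noisy; the
    corrections of the best round (lowest divergence) are returned together
    with the per-round history of KL(f || target).
    """
    from .design import DesignConfig, run_design

    if any(aa in FROZEN_TYPES for aa in target):
        raise EnergyError("target composition must not include frozen types")
    tot = sum(target.values())
    if abs(tot - 1.0) > 1e-6:
        raise EnergyError("target composition must sum to 1")
    config = design_config or DesignConfig(n_cycles=50, seed=0)
    corr = {aa: 0.0 for aa in target}
    best_corr = dict(corr)
    best_kl = math.inf
    history = []
    for rnd in range(max_rounds):
        adjusted = matrix.with_corrections(corr)
        ens = run_design(adjusted, config)
        counts = {aa: pseudocount for aa in target}
        for rec in ens.records:
            for p, aa in enumerate(rec.sequence):
                if adjusted.positions[p]["designable"] and aa in counts:
                    counts[aa] += 1
        total = sum(counts.values())
        f = {aa: c / total for aa, c in counts.items()}
        kl = sum(f[aa] * math.log(f[aa] / target[aa])
                 for aa in target if target[aa] > 0 and f[aa] > 0)
        history.append(kl)
        if kl < best_kl:
            best_kl = kl
            best_corr = dict(corr)
        if eta == 0.0:
            continue
        step = eta / (1.0 + rnd)
        for aa in target:
            if target[aa] > 0:
                corr[aa] += step * math.log(target[aa] / f[aa])
    return best_corr, history
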