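"""Molecular structures for fixed-backbone design.

This module provides the structural layer of the package: a united-atom
(polar-hydrogen) chemical model of the 20 amino acids, side-chain
construction from internal coordinates on a fixed backbone, discrete rotamer
libraries, a self-contained molecular-mechanics parameter set, and PDB I/O.

Conventions
-----------
* Coordinates are in Angstroms, right-handed axes.
* Residue indexing is 1-based, following author numbering of the selected
  PDB chain.
* Side chains are united-atom: aliphatic/aromatic hydrogens are implicit,
  hydrogens bound to N/O/S are explicit.
* Native cysteines, glycines and prolines are never redesigned; their side
  chains stay frozen at input coordinates.  Every other position may mutate
  freely among the 17 types outside {C, G, P}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AA1",
    "AA3_TO_1",
    "AA1_TO_3",
    "FROZEN_TYPES",
    "DESIGNABLE_TYPES",
    "SIGMA_BY_CLASS",
    "AtomSpec",
    "AtomGroup",
    "Rotamer",
    "RotamerLibrary",
    "ResidueTopology",
    "ParameterSet",
    "TemplatePosition",
    "BackboneTemplate",
    "StructureError",
    "dihedral",
    "bond_angle",
    "place_atom",
    "get_topology",
    "grid_library",
    "load_rotamer_library",
    "save_rotamer_library",
    "place_rotamer",
    "measure_chis",
    "ideal_cb",
    "read_pdb",
    "write_pdb",
]


class StructureError(ValueError):
    """Raised for malformed structures, parameters or rotamers."""


# --------------------------------------------------------------------------
# Amino-acid bookkeeping
# --------------------------------------------------------------------------

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Types with a special effect on backbone/unfolded structure; kept native.
FROZEN_TYPES = frozenset("CGP")
#: Types allowed at designable positions.
DESIGNABLE_TYPES = tuple(sorted(set(AA1) - FROZEN_TYPES))

#: Atomic solvation coefficients (kcal/mol/A^2) by atom class.
SIGMA_BY_CLASS = {
    "carbon_sulfur": 0.012,
    "oxygen_nitrogen": -0.06,
    "hydrogen": 0.0,
    "ionized": -0.15,
}

# Side-chain chi angle definitions (4-atom dihedrals), standard nomenclature.
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "A": [],
    "G": [],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
}

# Explicit (polar) side-chain hydrogens retained in the united-atom model.
_POLAR_SIDECHAIN_H = {
    "S": ("HG",), "T": ("HG1",), "C": ("HG",), "Y": ("HH",),
    "K": ("HZ1", "HZ2", "HZ3"),
    "R": ("HE", "HH11", "HH12", "HH21", "HH22"),
    "N": ("HD21", "HD22"), "Q": ("HE21", "HE22"),
    "W": ("HE1",), "H": ("HD1",),  # neutral His, delta tautomer
}

_BACKBONE_NAMES = ("N", "CA", "C", "O", "H")


# --------------------------------------------------------------------------
# Geometry primitives
# --------------------------------------------------------------------------

def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """IUPAC dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a3: np.ndarray, a2: np.ndarray, a1: np.ndarray,
               r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom X bonded to a1 with |X-a1| = r, angle X-a1-a2 = theta and
    dihedral X-a1-a2-a3 = phi (degrees).  NeRF construction."""
    th = math.radians(theta)
    ph = math.radians(phi)
    bc = a1 - a2
    bc = bc / np.linalg.norm(bc)
    n = np.cross(a2 - a3, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(th),
                  r * math.sin(th) * math.cos(ph),
                  r * math.sin(th) * math.sin(ph)])
    return a1 + d[0] * bc + d[1] * m + d[2] * n


def _wrap_angle(x: float) -> float:
    x = (x + 180.0) % 360.0 - 180.0
    return 180.0 if x == -180.0 else x


# --------------------------------------------------------------------------
# Atoms and parameters
# --------------------------------------------------------------------------

@dataclass
class AtomSpec:
    """A placed atom with its nonbonded parameters.

    charge in e; lj_epsilon (kcal/mol) and lj_rmin (per-atom half of the
    pair distance at the LJ minimum, A); radius is the solvation radius (A);
    sigma_solv the atomic solvation coefficient (kcal/mol/A^2)."""

    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin: float = 0.0
    radius: float = 1.0
    sigma_solv: float = 0.0
    atom_class: str = "carbon_sulfur"


class AtomGroup:
    """Columnar container for a set of atoms (the energetics workhorse)."""

    __slots__ = ("names", "coords", "charge", "eps", "rmin", "radius",
                 "sigma", "residue")

    def __init__(self, names, coords, charge, eps, rmin, radius, sigma,
                 residue=None):
        n = len(names)
        self.names = list(names)
        self.coords = np.asarray(coords, dtype=float).reshape(n, 3)
        self.charge = np.asarray(charge, dtype=float)
        self.eps = np.asarray(eps, dtype=float)
        self.rmin = np.asarray(rmin, dtype=float)
        self.radius = np.asarray(radius, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.residue = (np.zeros(n, dtype=int) if residue is None
                        else np.asarray(residue, dtype=int))

    @classmethod
    def from_specs(cls, specs, residue=None):
        return cls(
            [s.name for s in specs],
            np.array([s.coords for s in specs], dtype=float).reshape(-1, 3),
            [s.charge for s in specs],
            [s.lj_epsilon for s in specs],
            [s.lj_rmin for s in specs],
            [s.radius for s in specs],
            [s.sigma_solv for s in specs],
            residue=residue,
        )

    @classmethod
    def concat(cls, groups):
        groups = [g for g in groups if len(g) > 0]
        if not groups:
            return cls([], np.zeros((0, 3)), [], [], [], [], [])
        return cls(
            sum((g.names for g in groups), []),
            np.concatenate([g.coords for g in groups]),
            np.concatenate([g.charge for g in groups]),
            np.concatenate([g.eps for g in groups]),
            np.concatenate([g.rmin for g in groups]),
            np.concatenate([g.radius for g in groups]),
            np.concatenate([g.sigma for g in groups]),
            residue=np.concatenate([g.residue for g in groups]),
        )

    def __len__(self):
        return len(self.names)


# Charges (e).  Backbone is shared; PRO overrides its N-terminus of the ring.
_BACKBONE_CHARGES = {"N": -0.35, "H": 0.25, "CA": 0.10, "C": 0.55, "O": -0.55}
_PRO_BACKBONE_CHARGES = {"N": -0.25, "CA": 0.15, "C": 0.55, "O": -0.55}

_SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "S": {"CB": 0.25, "OG": -0.65, "HG": 0.40},
    "T": {"CB": 0.25, "OG1": -0.65, "HG1": 0.40},
    "C": {"CB": 0.10, "SG": -0.45, "HG": 0.35},
    "Y": {"CZ": 0.25, "OH": -0.65, "HH": 0.40},
    "N": {"CG": 0.55, "OD1": -0.55, "ND2": -0.60, "HD21": 0.30, "HD22": 0.30},
    "Q": {"CD": 0.55, "OE1": -0.55, "NE2": -0.60, "HE21": 0.30, "HE22": 0.30},
    "D": {"CB": -0.16, "CG": 0.36, "OD1": -0.60, "OD2": -0.60},
    "E": {"CG": -0.16, "CD": 0.36, "OE1": -0.60, "OE2": -0.60},
    "K": {"CE": 0.25, "NZ": -0.30, "HZ1": 0.35, "HZ2": 0.35, "HZ3": 0.35},
    "R": {"CD": 0.10, "NE": -0.40, "HE": 0.30, "CZ": 0.50,
          "NH1": -0.45, "NH2": -0.45,
          "HH11": 0.35, "HH12": 0.35, "HH21": 0.35, "HH22": 0.35},
    "H": {"CG": 0.10, "ND1": -0.40, "HD1": 0.30, "CD2": 0.10,
          "CE1": 0.30, "NE2": -0.40},
    "W": {"NE1": -0.60, "HE1": 0.30, "CD1": 0.15, "CE2": 0.15},
    "M": {"CG": 0.06, "SD": -0.12, "CE": 0.06},
    "P": {"CD": 0.10},
}

# (lj_epsilon kcal/mol, lj_rmin_half A, solvation radius A) by element.
_LJ_BY_ELEMENT = {
    "C": (0.090, 2.10, 1.90),
    "N": (0.2384, 1.60, 1.60),
    "O": (0.1591, 1.60, 1.60),
    "S": (0.043, 1.89, 1.85),
    "H": (0.0498, 0.80, 1.00),
}

# Atoms of ionized groups get the ionized solvation class.
_IONIZED_ATOMS = {
    ("D", "OD1"), ("D", "OD2"), ("E", "OE1"), ("E", "OE2"),
    ("K", "NZ"), ("R", "NE"), ("R", "NH1"), ("R", "NH2"),
}

_PARAM_TSV_HEADER = ("aa", "atom", "element", "charge", "lj_epsilon",
                     "lj_rmin", "radius", "atom_class")


class ParameterSet:
    """Per-(residue, atom) nonbonded parameter tables.

    The default set is a self-contained united-atom parameterization in the
    CHARMM19 spirit (implicit aliphatic hydrogens, explicit polar ones) with
    solvation radii and atom classes used by the surface-area term.
    Alternative tables can be loaded from TSV with columns
    ``aa atom element charge lj_epsilon lj_rmin radius atom_class``.
    """

    def __init__(self, rows: dict[tuple[str, str], dict]):
        self.rows = rows

    def lookup(self, aa: str, atom_name: str) -> dict:
        try:
            return self.rows[(aa, atom_name)]
        except KeyError:
            raise StructureError(
                f"no parameters for atom {atom_name!r} of residue {aa!r}"
            ) from None

    def spec(self, aa: str, name: str, coords: np.ndarray) -> AtomSpec:
        row = self.lookup(aa, name)
        return AtomSpec(name=name, element=row["element"], coords=coords,
                        charge=row["charge"], lj_epsilon=row["lj_epsilon"],
                        lj_rmin=row["lj_rmin"], radius=row["radius"],
                        sigma_solv=SIGMA_BY_CLASS[row["atom_class"]],
                        atom_class=row["atom_class"])

    @staticmethod
    def combine(eps_i, eps_j, rmin_i, rmin_j):
        """Lorentz-like LJ combination: geometric eps, additive rmin."""
        return math.sqrt(eps_i * eps_j), rmin_i + rmin_j

    @classmethod
    def default(cls) -> "ParameterSet":
        rows: dict[tuple[str, str], dict] = {}
        for aa in AA1:
            topo = get_topology(aa)
            bb_charges = (_PRO_BACKBONE_CHARGES if aa == "P"
                          else _BACKBONE_CHARGES)
            for name, element in topo.all_atoms:
                if name in _BACKBONE_NAMES:
                    charge = bb_charges.get(name, 0.0)
                else:
                    charge = _SIDECHAIN_CHARGES.get(aa, {}).get(name, 0.0)
                eps, rmin, radius = _LJ_BY_ELEMENT[element]
                if name == "C":  # carbonyl carbon
                    eps = 0.12
                if (aa, name) in _IONIZED_ATOMS:
                    klass = "ionized"
                elif element in ("C", "S"):
                    klass = "carbon_sulfur"
                elif element in ("N", "O"):
                    klass = "oxygen_nitrogen"
                else:
                    klass = "hydrogen"
                rows[(aa, name)] = {
                    "element": element, "charge": charge,
                    "lj_epsilon": eps, "lj_rmin": rmin, "radius": radius,
                    "atom_class": klass,
                }
        return cls(rows)

    def to_tsv(self, path) -> None:
        lines = ["\t".join(_PARAM_TSV_HEADER)]
        for (aa, atom) in sorted(self.rows):
            r = self.rows[(aa, atom)]
            lines.append("\t".join([
                aa, atom, r["element"], f"{r['charge']:.4f}",
                f"{r['lj_epsilon']:.4f}", f"{r['lj_rmin']:.4f}",
                f"{r['radius']:.4f}", r["atom_class"],
            ]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ParameterSet":
        lines = Path(path).read_text().splitlines()
        if not lines or tuple(lines[0].split("\t")) != _PARAM_TSV_HEADER:
            raise StructureError(f"bad parameter TSV header in {path}")
        rows = {}
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != len(_PARAM_TSV_HEADER):
                raise StructureError(f"{path}:{ln}: expected "
                                     f"{len(_PARAM_TSV_HEADER)} columns")
            aa, atom, element = parts[0], parts[1], parts[2]
            if parts[7] not in SIGMA_BY_CLASS:
                raise StructureError(f"{path}:{ln}: unknown atom class "
                                     f"{parts[7]!r}")
            rows[(aa, atom)] = {
                "element": element, "charge": float(parts[3]),
                "lj_epsilon": float(parts[4]), "lj_rmin": float(parts[5]),
                "radius": float(parts[6]), "atom_class": parts[7],
            }
        return cls(rows)


# --------------------------------------------------------------------------
# Residue topologies (internal coordinates from ideal geometry)
# --------------------------------------------------------------------------

@dataclass
class ZAtom:
    """One side-chain atom in build order.

    ``refs`` are the three upstream reference atoms (a1 bonded parent, a2,
    a3); the torsion X-a1-a2-a3 is either a free chi angle (+ fixed offset
    for branch atoms sharing the chi axis) or a constant (rigid groups)."""

    name: str
    element: str
    refs: tuple[str, str, str]
    r: float
    theta: float
    phi_kind: str        # "chi" or "fixed"
    chi_index: int = -1  # 0-based, for phi_kind == "chi"
    phi_value: float = 0.0


@dataclass
class ResidueTopology:
    aa_type: str
    atoms: list[ZAtom]            # side-chain atoms in build order
    chi_defs: list[tuple[str, str, str, str]]
    bonds: list[tuple[str, str]]  # within-residue bonds over kept atoms
    all_atoms: list[tuple[str, str]]  # (name, element) incl. backbone

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    @property
    def sidechain_names(self) -> list[str]:
        return [a.name for a in self.atoms]


_TOPOLOGY_CACHE: dict[str, ResidueTopology] = {}


def _ideal_residue(aa: str):
    import biotite.structure.info as info

    res = info.residue(AA1_TO_3[aa])
    keep: list[int] = []
    polar = set(_POLAR_SIDECHAIN_H.get(aa, ()))
    for i, (name, element) in enumerate(zip(res.atom_name, res.element)):
        if name in ("OXT", "HXT", "H2", "H3"):
            continue
        if element == "H" and name != "H" and name not in polar:
            continue
        if name == "H" and aa == "P":
            continue
        keep.append(i)
    names = [str(res.atom_name[i]) for i in keep]
    elements = [str(res.element[i]) for i in keep]
    coords = {n: res.coord[i] for n, i in zip(names, keep)}
    idx = {i: k for k, i in enumerate(keep)}
    bonds = []
    for i, j, _ in res.bonds.as_array():
        if i in idx and j in idx:
            a, b = names[idx[i]], names[idx[j]]
            bonds.append((a, b) if a < b else (b, a))
    return names, elements, coords, sorted(set(bonds))


def get_topology(aa: str) -> ResidueTopology:
    """Topology for one amino-acid type, derived once from ideal geometry."""
    if aa not in AA1_TO_3:
        raise StructureError(f"unknown amino-acid type {aa!r}")
    if aa in _TOPOLOGY_CACHE:
        return _TOPOLOGY_CACHE[aa]

    names, elements, coords, bonds = _ideal_residue(aa)
    element_of = dict(zip(names, elements))
    adj: dict[str, list[str]] = {n: [] for n in names}
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    order = {n: i for i, n in enumerate(names)}
    for n in adj:
        adj[n].sort(key=order.__getitem__)

    # BFS tree from CA over side-chain atoms (via CB).
    parent: dict[str, str] = {}
    build_order: list[str] = []
    if "CB" in adj:
        parent["CB"] = "CA"
        queue = ["CB"]
        seen = {"N", "CA", "C", "O", "H", "CB"}
        while queue:
            cur = queue.pop(0)
            build_order.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    parent[nb] = cur
                    queue.append(nb)

    def ref_chain(atom: str) -> tuple[str, str, str]:
        chain = []
        cur = atom
        while len(chain) < 3:
            nxt = parent.get(cur)
            if nxt is None:
                # walked past CA: continue along the backbone
                chain.extend(["N", "C"][: 3 - len(chain)]
                             if chain and chain[-1] == "CA" else ["CA", "N", "C"][: 3 - len(chain)])
                break
            chain.append(nxt)
            cur = nxt
        return tuple(chain[:3])

    chi_defs = CHI_DEFS[aa]
    chi_tip = {cd[3]: k for k, cd in enumerate(chi_defs)}

    zatoms: list[ZAtom] = []
    measured: dict[str, float] = {}
    for name in build_order:
        a1, a2, a3 = ref_chain(name)
        r = float(np.linalg.norm(coords[name] - coords[a1]))
        theta = bond_angle(coords[name], coords[a1], coords[a2])
        phi = dihedral(coords[a3], coords[a2], coords[a1], coords[name])
        measured[name] = phi
        if name in chi_tip:
            z = ZAtom(name, element_of[name], (a1, a2, a3), r, theta,
                      "chi", chi_tip[name], 0.0)
        else:
            # branch sharing a chi axis? (same parent as a chi tip atom)
            sibling = next((t for t in chi_tip
                            if parent.get(t) == parent.get(name)
                            and t != name), None)
            if sibling is not None and sibling in measured:
                off = _wrap_angle(phi - measured[sibling])
                z = ZAtom(name, element_of[name], (a1, a2, a3), r, theta,
                          "chi", chi_tip[sibling], off)
            elif sibling is not None:
                # chi tip not yet built (ordering): fall back to fixed
                z = ZAtom(name, element_of[name], (a1, a2, a3), r, theta,
                          "fixed", -1, phi)
            else:
                z = ZAtom(name, element_of[name], (a1, a2, a3), r, theta,
                          "fixed", -1, phi)
        zatoms.append(z)

    topo = ResidueTopology(
        aa_type=aa, atoms=zatoms, chi_defs=list(chi_defs),
        bonds=bonds, all_atoms=[(n, element_of[n]) for n in names],
    )
    _TOPOLOGY_CACHE[aa] = topo
    return topo


def ideal_chis(aa: str) -> tuple[float, ...]:
    """Chi angles of the ideal-geometry reference residue."""
    _, _, coords, _ = _ideal_residue(aa)
    return tuple(_wrap_angle(round(dihedral(*(coords[x] for x in cd)), 3))
                 for cd in CHI_DEFS[aa])


# --------------------------------------------------------------------------
# Rotamers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Rotamer:
    aa_type: str
    chis: tuple[float, ...]
    weight: float = 1.0

    def __post_init__(self):
        expected = len(CHI_DEFS[self.aa_type])
        if len(self.chis) != expected:
            raise StructureError(
                f"{self.aa_type} expects {expected} chi angles, "
                f"got {len(self.chis)}")
        for chi in self.chis:
            if not (-180.0 < chi <= 180.0):
                raise StructureError(f"chi {chi} out of (-180, 180]")


class RotamerLibrary:
    """Mapping aa_type -> list of rotamers."""

    def __init__(self, rotamers: dict[str, list[Rotamer]]):
        self.rotamers = {aa: list(rs) for aa, rs in rotamers.items()}

    def __getitem__(self, aa: str) -> list[Rotamer]:
        try:
            return self.rotamers[aa]
        except KeyError:
            raise StructureError(f"no rotamers for type {aa!r}") from None

    def __contains__(self, aa: str) -> bool:
        return aa in self.rotamers

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted(self.rotamers))

    def validate(self, required=DESIGNABLE_TYPES) -> None:
        for aa in required:
            if not self.rotamers.get(aa):
                raise StructureError(f"designable type {aa!r} has no rotamer")


def grid_library(chi_values=(-60.0, 60.0, 180.0), types=None,
                 max_chi=None) -> RotamerLibrary:
    """Minimal chi-grid library: every combination of ``chi_values`` over the
    chi angles of each type (Ala gets its single no-chi rotamer).

    ``max_chi`` caps the number of freely gridded chi angles; deeper chis
    are held at 180 to keep combinatorics manageable for long side chains.
    """
    types = AA1 if types is None else types
    lib: dict[str, list[Rotamer]] = {}
    for aa in types:
        n = len(CHI_DEFS[aa])
        if aa == "P":
            lib[aa] = [Rotamer(aa, ideal_chis(aa))]
            continue
        free = n if max_chi is None else min(n, max_chi)
        combos = [()]
        for _ in range(free):
            combos = [c + (v,) for c in combos for v in chi_values]
        combos = [c + (180.0,) * (n - free) for c in combos]
        lib[aa] = [Rotamer(aa, c) for c in combos]
    return RotamerLibrary(lib)


def load_rotamer_library(path=None) -> RotamerLibrary:
    """Load a rotamer TSV (columns: aa, chi1..chi4, optional weight); with no
    path, return the built-in chi-grid library."""
    if path is None:
        return grid_library()
    lines = Path(path).read_text().splitlines()
    lib: dict[str, list[Rotamer]] = {}
    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("aa"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        while parts and parts[-1] == "":
            parts.pop()
        aa = parts[0] if parts else ""
        if aa not in AA1_TO_3:
            raise StructureError(f"{path}:{ln}: unknown type {aa!r}")
        nchi = len(CHI_DEFS[aa])
        try:
            chis = tuple(float(x) for x in parts[1:1 + nchi])
        except ValueError as exc:
            raise StructureError(f"{path}:{ln}: bad chi value ({exc})")
        if len(chis) != nchi:
            raise StructureError(f"{path}:{ln}: expected {nchi} chi angles")
        weight = float(parts[1 + nchi]) if len(parts) > 1 + nchi else 1.0
        try:
            rot = Rotamer(aa, chis, weight)
        except StructureError as exc:
            raise StructureError(f"{path}:{ln}: {exc}")
        lib.setdefault(aa, []).append(rot)
    return RotamerLibrary(lib)


def save_rotamer_library(library: RotamerLibrary, path) -> None:
    lines = ["aa\tchi1..chiN\tweight"]
    for aa in library.types:
        for rot in library[aa]:
            lines.append("\t".join([aa] + [str(c) for c in rot.chis]
                                   + [str(rot.weight)]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Backbone templates
# --------------------------------------------------------------------------

@dataclass
class TemplatePosition:
    index: int                       # 1-based author numbering
    native_type: str
    backbone: dict[str, np.ndarray]  # N, CA, C, O (+H when present)
    designable: bool
    frozen_sidechain: list[AtomSpec] | None = None

    @property
    def cb_anchor(self) -> np.ndarray:
        """Ideal CB position (CA for Gly); used by the pair cutoff."""
        if self.native_type == "G":
            return self.backbone["CA"]
        return ideal_cb(self.backbone["N"], self.backbone["CA"],
                        self.backbone["C"])


@dataclass
class BackboneTemplate:
    positions: list[TemplatePosition]
    chain_id: str = "A"
    parameters: ParameterSet | None = None

    def __len__(self):
        return len(self.positions)

    @property
    def sequence(self) -> str:
        return "".join(p.native_type for p in self.positions)

    def allowed_types(self, pos_idx: int) -> tuple[str, ...]:
        p = self.positions[pos_idx]
        return DESIGNABLE_TYPES if p.designable else (p.native_type,)

    def params(self) -> ParameterSet:
        if self.parameters is None:
            self.parameters = ParameterSet.default()
        return self.parameters


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB from backbone N/CA/C with ideal tetrahedral geometry."""
    _ensure_cb_torsion()
    return place_atom(c, n, ca, 1.53, 110.5, _CB_TORSION)


# Torsion CB-CA-N-C of the ideal L-alanine reference (set at import).
def _cb_torsion() -> float:
    _, _, coords, _ = _ideal_residue("A")
    return dihedral(coords["C"], coords["N"], coords["CA"], coords["CB"])


_CB_TORSION = None  # filled lazily to avoid import-time biotite cost


def _ensure_cb_torsion():
    global _CB_TORSION
    if _CB_TORSION is None:
        _CB_TORSION = _cb_torsion()


_BB_GEOM = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231, "n_h": 0.980,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "ang_h_n_ca": 119.0, "omega": 180.0,
}


def build_chain_backbone(sequence: str, phi_psi, parameters=None,
                         chain_id: str = "A") -> BackboneTemplate:
    """Build an ideal-geometry backbone for ``sequence`` with per-residue
    (phi, psi) dihedrals (degrees).  Native Cys/Gly/Pro positions get frozen
    ideal side chains; every other position is designable."""
    phi_psi = list(phi_psi)
    if len(phi_psi) != len(sequence):
        raise StructureError("phi_psi length must match sequence")
    params = parameters or ParameterSet.default()
    g = _BB_GEOM
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([g["n_ca"], 0.0, 0.0])
    th = math.radians(180.0 - g["ang_n_ca_c"])
    c = ca + g["ca_c"] * np.array([math.cos(th), math.sin(th), 0.0])
    residues = []
    for i, aa in enumerate(sequence):
        residues.append({"N": n, "CA": ca, "C": c})
        psi = phi_psi[i][1]
        if i + 1 < len(sequence):
            phi_next = phi_psi[i + 1][0]
            n2 = place_atom(n, ca, c, g["c_n"], g["ang_ca_c_n"], psi)
            ca2 = place_atom(ca, c, n2, g["n_ca"], g["ang_c_n_ca"],
                             g["omega"])
            c2 = place_atom(c, n2, ca2, g["ca_c"], g["ang_n_ca_c"], phi_next)
            n, ca, c = n2, ca2, c2
    positions = []
    for i, aa in enumerate(sequence):
        if aa not in AA1_TO_3:
            raise StructureError(f"unknown type {aa!r} in sequence")
        bb = residues[i]
        psi = phi_psi[i][1]
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"], g["c_o"],
                             g["ang_ca_c_o"], _wrap_angle(psi - 180.0))
        if i > 0 and aa != "P":
            phi = phi_psi[i][0]
            bb["H"] = place_atom(bb["C"], bb["CA"], bb["N"], g["n_h"],
                                 g["ang_h_n_ca"], _wrap_angle(phi - 180.0))
        frozen = None
        if aa in FROZEN_TYPES and aa != "G":
            frozen = build_sidechain(bb, aa, ideal_chis(aa), params)
        positions.append(TemplatePosition(
            index=i + 1, native_type=aa, backbone=bb,
            designable=aa not in FROZEN_TYPES,
            frozen_sidechain=frozen if aa in FROZEN_TYPES else None))
    return BackboneTemplate(positions=positions, chain_id=chain_id,
                            parameters=params)


# --------------------------------------------------------------------------
# Side-chain construction
# --------------------------------------------------------------------------

def place_rotamer(template: BackboneTemplate, index: int, aa: str,
                  rot: Rotamer) -> list[AtomSpec]:
    """Build the side chain of type ``aa`` at template position ``index``
    (0-based list index) with the chi angles of ``rot``.

    Returns the side-chain atoms only; the backbone is untouched.  For the
    frozen native type at a non-designable position the stored crystal side
    chain is returned as-is.
    """
    pos = template.positions[index]
    if pos.designable:
        if aa in FROZEN_TYPES:
            raise StructureError(
                f"type {aa!r} is not allowed at designable position "
                f"{pos.index}")
    else:
        if aa != pos.native_type:
            raise StructureError(
                f"position {pos.index} is frozen as {pos.native_type!r}")
        if pos.frozen_sidechain is not None:
            return pos.frozen_sidechain
    if rot.aa_type != aa:
        raise StructureError("rotamer type does not match requested type")
    return build_sidechain(pos.backbone, aa, rot.chis, template.params())


def build_sidechain(backbone: dict[str, np.ndarray], aa: str,
                    chis: tuple[float, ...],
                    parameters: ParameterSet) -> list[AtomSpec]:
    """Construct side-chain atoms from internal coordinates."""
    topo = get_topology(aa)
    if len(chis) != topo.n_chi:
        raise StructureError(f"{aa} needs {topo.n_chi} chi angles")
    coords = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    out: list[AtomSpec] = []
    for z in topo.atoms:
        a1, a2, a3 = (coords[r] for r in z.refs)
        if z.phi_kind == "chi":
            phi = _wrap_angle(chis[z.chi_index] + z.phi_value)
        else:
            phi = z.phi_value
        xyz = place_atom(a3, a2, a1, z.r, z.theta, phi)
        coords[z.name] = xyz
        out.append(parameters.spec(aa, z.name, xyz))
    return out


def measure_chis(aa: str, coords: dict[str, np.ndarray]) -> tuple[float, ...]:
    """Chi angles (degrees) measured from a coordinate dict that contains
    backbone N/CA/CB... atoms of the residue."""
    chis = []
    for cd in CHI_DEFS[aa]:
        try:
            pts = [np.asarray(coords[x], dtype=float) for x in cd]
        except KeyError as exc:
            raise StructureError(f"missing atom {exc} for chi of {aa}")
        chis.append(dihedral(*pts))
    return tuple(chis)


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def read_pdb(path, parameters: ParameterSet | None = None,
             chain: str | None = None) -> BackboneTemplate:
    """Read a single-model PDB file into a backbone template.

    The first chain is used unless ``chain`` names one.  Alternate locations
    resolve to the highest-occupancy conformer.  A missing carbonyl O is
    rebuilt from backbone geometry; any other missing backbone atom is a
    hard error naming the residue.  Side chains of native Cys/Gly/Pro are
    kept (frozen); other side chains are discarded (they are rebuilt from
    rotamers during design).
    """
    from Bio.PDB import PDBParser

    _ensure_cb_torsion()
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    chains = list(model.get_chains())
    if not chains:
        raise StructureError(f"{path}: no chains found")
    if chain is None:
        ch = chains[0]
    else:
        match = [c for c in chains if c.id == chain]
        if not match:
            raise StructureError(f"{path}: no chain {chain!r}")
        ch = match[0]

    params = parameters or ParameterSet.default()
    raw: list[tuple[int, str, dict[str, np.ndarray]]] = []
    for res in ch.get_residues():
        hetflag, resseq, _ = res.get_id()
        if hetflag.strip():
            continue  # waters / ligands are out of scope
        resname = res.get_resname()
        if resname not in AA3_TO_1:
            raise StructureError(
                f"{path}: unknown residue {resname} {resseq}")
        atoms: dict[str, np.ndarray] = {}
        for atom in res.get_atoms():
            # Disordered atoms expose the highest-occupancy conformer.
            atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
        raw.append((resseq, AA3_TO_1[resname], atoms))

    positions: list[TemplatePosition] = []
    for k, (resseq, aa, atoms) in enumerate(raw):
        for bb in ("N", "CA", "C"):
            if bb not in atoms:
                raise StructureError(
                    f"{path}: residue {AA1_TO_3[aa]} {resseq} misses "
                    f"backbone atom {bb}")
        backbone = {bb: atoms[bb] for bb in ("N", "CA", "C")}
        if "O" in atoms:
            backbone["O"] = atoms["O"]
        else:
            backbone["O"] = _rebuild_o(
                atoms, raw[k + 1][2] if k + 1 < len(raw) else None)
        if "H" in atoms:
            backbone["H"] = atoms["H"]
        elif k > 0 and aa != "P":
            backbone["H"] = _rebuild_h(raw[k - 1][2], atoms)
        frozen = None
        if aa in FROZEN_TYPES:
            names = get_topology(aa).sidechain_names
            missing = [n for n in names if n not in atoms
                       and not n.startswith("H")]
            if missing:
                # incomplete frozen side chain: rebuild at ideal chis
                frozen = build_sidechain(backbone, aa, ideal_chis(aa), params)
            else:
                frozen = [params.spec(aa, n, atoms[n]) for n in names
                          if n in atoms]
        positions.append(TemplatePosition(
            index=int(resseq), native_type=aa, backbone=backbone,
            designable=aa not in FROZEN_TYPES, frozen_sidechain=frozen))
    if not positions:
        raise StructureError(f"{path}: chain {ch.id!r} has no residues")
    return BackboneTemplate(positions=positions, chain_id=str(ch.id),
                            parameters=params)


def _rebuild_o(atoms, next_atoms) -> np.ndarray:
    n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
    if next_atoms is not None and "N" in next_atoms:
        psi = dihedral(n, ca, c, next_atoms["N"])
    else:
        psi = 180.0
    return place_atom(n, ca, c, 1.23, 120.8, _wrap_angle(psi - 180.0))


def _rebuild_h(prev_atoms, atoms) -> np.ndarray:
    # amide H anti to the preceding carbonyl C across the N-CA axis
    phi_ref = dihedral(prev_atoms["C"], atoms["N"], atoms["CA"], atoms["C"])
    return place_atom(atoms["C"], atoms["CA"], atoms["N"], 0.98, 119.0,
                      _wrap_angle(phi_ref - 180.0))


def write_pdb(template: BackboneTemplate, path,
              sidechains: dict[int, list[AtomSpec]] | None = None) -> None:
    """Write the template backbone (plus frozen and any provided side
    chains) as PDB ATOM/TER records."""
    lines = []
    serial = 1
    for k, pos in enumerate(template.positions):
        res3 = AA1_TO_3[pos.native_type]
        entries = [(n, pos.backbone[n], _element_of(n))
                   for n in ("N", "CA", "C", "O", "H") if n in pos.backbone]
        extra = (sidechains or {}).get(k, pos.frozen_sidechain or [])
        entries += [(a.name, a.coords, a.element) for a in extra]
        for name, xyz, element in entries:
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{res3} "
                f"{template.chain_id}{pos.index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")
            serial += 1
    lines.append(f"TER   {serial:5d}      "
                 f"{AA1_TO_3[template.positions[-1].native_type]} "
                 f"{template.chain_id}{template.positions[-1].index:4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _element_of(name: str) -> str:
    return name[0] if name[0] in "CNOSH" else name[0]


# --------------------------------------------------------------------------
# Bonds and exclusions over a whole residue (used by energetics)
# --------------------------------------------------------------------------

def residue_bonds(aa: str) -> list[tuple[str, str]]:
    """Within-residue bonds over the united-atom set (backbone included)."""
    return list(get_topology(aa).bonds)


#: Inter-residue excluded name pairs across a peptide bond (prev, next):
#: 1-2 and 1-3 neighbours through C(prev)-N(next).
INTER_RESIDUE_EXCLUSIONS = [
    ("C", "N"), ("C", "CA"), ("C", "H"), ("C", "CD"),  # CD: proline ring
    ("CA", "N"), ("O", "N"),
]


def excluded_pairs(names_bonds: list[tuple[str, str]],
                   atom_names: list[str]) -> set[tuple[int, int]]:
    """Index pairs at bond-graph distance <= 2 (1-2 and 1-3 exclusions)."""
    index: dict[str, int] = {}
    for i, n in enumerate(atom_names):
        index.setdefault(n, i)
    adj: dict[int, set[int]] = {i: set() for i in range(len(atom_names))}
    for a, b in names_bonds:
        if a in index and b in index:
            adj[index[a]].add(index[b])
            adj[index[b]].add(index[a])
    out: set[tuple[int, int]] = set()
    for i in adj:
        for j in adj[i]:
            out.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    out.add((min(i, k), max(i, k)))
    return out
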