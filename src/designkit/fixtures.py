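"""Synthetic inputs for the whole pipeline.

Everything the package needs can be generated here, deterministically per
seed: ideal-geometry toy structures (helix / strand / hairpin), planted
multiple sequence alignments with known couplings and subfamily patterns,
and labelled homologue/decoy search databases.  No external downloads or
binary fixtures are required anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import MSA, GAP
from .structure import (
    AA1,
    BackboneTemplate,
    ParameterSet,
    StructureError,
    build_chain_backbone,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "PlantedMSASpec",
    "make_structure",
    "make_planted_msa",
    "make_search_database",
]

_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
}
#: Chain-reversing turn used in the middle of hairpin fixtures.
_TURN = ((60.0, 30.0), (90.0, 0.0))


@dataclass(frozen=True)
class FixtureSpec:
    """A toy structure request: secondary-structure kind, length, optional
    sequence (default poly-Ala), seed and coordinate jitter (A)."""

    kind: str = "helix"
    length: int = 8
    sequence: str | None = None
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.length < 2:
            raise StructureError("length must be >= 2")
        if self.noise_sigma < 0:
            raise StructureError("noise_sigma must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise StructureError("sequence length mismatch")


def make_structure(spec: FixtureSpec,
                   parameters: ParameterSet | None = None,
                   pdb_path=None) -> BackboneTemplate:
    """Build an ideal-geometry backbone template (and optionally write it
    as a PDB file).  Deterministic per seed."""
    seq = spec.sequence or "A" * spec.length
    if spec.kind in _PHI_PSI:
        phi_psi = [_PHI_PSI[spec.kind]] * spec.length
    elif spec.kind == "hairpin":
        half = (spec.length - len(_TURN)) // 2
        rest = spec.length - len(_TURN) - half
        phi_psi = ([_PHI_PSI["strand"]] * half + list(_TURN)
                   + [_PHI_PSI["strand"]] * rest)
    else:
        raise StructureError(f"unknown fixture kind {spec.kind!r}")
    template = build_chain_backbone(seq, phi_psi, parameters)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for pos in template.positions:
            for name in pos.backbone:
                pos.backbone[name] = (pos.backbone[name]
                                      + rng.normal(0, spec.noise_sigma, 3))
    if pdb_path is not None:
        write_pdb(template, pdb_path)
    return template


# --------------------------------------------------------------------------
# Planted alignments
# --------------------------------------------------------------------------

@dataclass
class PlantedMSASpec:
    """A synthetic alignment with known ground truth.

    background: per-column type-frequency dicts (None = flat over a small
    default pool); coupled_pairs: list of (i, j, [(aa_i, aa_j, prob), ...])
    joint distributions overriding the background at those columns;
    subfamilies: optional (weights, patterns) where patterns maps positions
    to fixed types per subfamily; gap_rate inserts gaps uniformly."""

    n_sequences: int = 200
    length: int = 20
    background: list | None = None
    coupled_pairs: list = field(default_factory=list)
    subfamily_weights: list | None = None
    subfamily_patterns: list | None = None
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.subfamily_weights is not None:
            if abs(sum(self.subfamily_weights) - 1.0) > 1e-9:
                raise StructureError("subfamily weights must sum to 1")
            if (self.subfamily_patterns is None
                    or len(self.subfamily_patterns)
                    != len(self.subfamily_weights)):
                raise StructureError(
                    "subfamily weights and patterns must align")
        for (_, _, joint) in self.coupled_pairs:
            tot = sum(p for _, _, p in joint)
            if abs(tot - 1.0) > 1e-9:
                raise StructureError("coupled-pair joint must sum to 1")


_DEFAULT_POOL = "AVLSTDEKRN"


def make_planted_msa(spec: PlantedMSASpec):
    """Sample the alignment; returns (MSA, truth) where truth records the
    coupled pairs, subfamily labels and pattern definitions."""
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    backgrounds = []
    for c in range(L):
        if spec.background is not None and spec.background[c]:
            items = sorted(spec.background[c].items())
            types = [aa for aa, _ in items]
            p = np.array([f for _, f in items], dtype=float)
            backgrounds.append((types, p / p.sum()))
        else:
            backgrounds.append((list(_DEFAULT_POOL),
                                np.full(len(_DEFAULT_POOL),
                                        1.0 / len(_DEFAULT_POOL))))
    coupled_cols = {}
    for (i, j, joint) in spec.coupled_pairs:
        coupled_cols[(i, j)] = joint
    labels = []
    seqs = []
    for _ in range(spec.n_sequences):
        if spec.subfamily_weights is not None:
            fam = int(rng.choice(len(spec.subfamily_weights),
                                 p=spec.subfamily_weights))
        else:
            fam = 0
        labels.append(fam)
        seq = [None] * L
        for (i, j), joint in coupled_cols.items():
            k = int(rng.choice(len(joint), p=[p for _, _, p in joint]))
            seq[i], seq[j] = joint[k][0], joint[k][1]
        for c in range(L):
            if seq[c] is None:
                types, p = backgrounds[c]
                seq[c] = types[int(rng.choice(len(types), p=p))]
        if spec.subfamily_patterns is not None:
            for pos, aa in spec.subfamily_patterns[fam].items():
                seq[pos] = aa
        if spec.gap_rate > 0:
            mask = rng.random(L) < spec.gap_rate
            seq = [GAP if m else aa for aa, m in zip(seq, mask)]
        seqs.append("".join(seq))
    truth = {
        "coupled_pairs": [(i, j) for (i, j, _) in spec.coupled_pairs],
        "subfamily_labels": labels,
        "subfamily_patterns": spec.subfamily_patterns,
    }
    return MSA(seqs), truth


# --------------------------------------------------------------------------
# Search databases
# --------------------------------------------------------------------------

def make_search_database(source, n_true: int, n_decoys: int,
                         seed: int = 0, mutate_rate: float = 0.0,
                         decoy_model: str = "shuffle"):
    """A labelled FASTA-style database of true homologues plus decoys.

    ``source`` is a list of sequences (e.g. profile samples or ensemble
    members) from which ``n_true`` targets are drawn (optionally point-
    mutated at ``mutate_rate``); decoys are per-sequence shuffles
    ("shuffle") or i.i.d. draws from the pooled composition
    ("background").  Returns (records, labels) with records as (id, seq)
    and labels mapping id -> True (homologue) / False (decoy)."""
    source = [s.replace(GAP, "") for s in source]
    if n_true > len(source):
        raise StructureError("n_true exceeds available source sequences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(source))
    records, labels = [], {}
    pool = "".join(source)
    for t in range(n_true):
        seq = list(source[order[t]])
        if mutate_rate > 0:
            for c in range(len(seq)):
                if rng.random() < mutate_rate:
                    seq[c] = AA1[rng.integers(len(AA1))]
        rid = f"true_{t}"
        records.append((rid, "".join(seq)))
        labels[rid] = True
    for d in range(n_decoys):
        src = source[int(rng.integers(len(source)))]
        if decoy_model == "shuffle":
            arr = list(src)
            rng.shuffle(arr)
            seq = "".join(arr)
        elif decoy_model == "background":
            seq = "".join(pool[int(rng.integers(len(pool)))]
                          for _ in range(len(src)))
        else:
            raise StructureError(f"unknown decoy model {decoy_model!r}")
        rid = f"decoy_{d}"
        records.append((rid, seq))
        labels[rid] = False
    return records, labels
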