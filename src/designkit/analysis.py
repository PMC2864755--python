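"""Sequence-ensemble statistics.

Tools to compare designed sequence ensembles with natural families:

* identity and profile-weighted BLOSUM similarity scores,
* overlap between designed and natural score distributions,
* position-dependent residual entropy S_l = -sum_t f_l(t) ln f_l(t) under
  reduced amino-acid alphabets (the exponentiated value e^{S_l} reads as an
  effective number of residue classes per position),
* mutual-information ("covariance") matrices over position pairs,
* extraction of frequent correlated flavor patterns and pattern subsets.

The reduced alphabets group the 20 types into physicochemical classes:
nine classes {LVIMC} {FY} {W} {G} {A} {STP} {EDNQ} {KR} {H}, or six classes
{LVIMC} {FYW} {G} {ASTP} {EDNQ} {KRH}.  Entropies and mutual information
are in nats (natural log).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import AA1

__all__ = [
    "GAP",
    "AnalysisError",
    "MSA",
    "SubstitutionMatrix",
    "ReducedAlphabet",
    "get_alphabet",
    "CovarianceMatrix",
    "PatternSpec",
    "identity_score",
    "similarity_score",
    "score_overlap",
    "positional_entropy",
    "mutual_information_matrix",
    "top_patterns",
    "subset_by_pattern",
]

GAP = "-"


class AnalysisError(ValueError):
    pass


# --------------------------------------------------------------------------
# Alignments
# --------------------------------------------------------------------------

class MSA:
    """An aligned set of sequences over the 20 types plus the gap symbol.

    Per-column frequencies include the gap fraction; entropy and mutual
    information exclude gaps and renormalize (designed ensembles carry no
    gaps, natural alignments do)."""

    def __init__(self, sequences, ids=None):
        sequences = [str(s).upper() for s in sequences]
        if not sequences:
            raise AnalysisError("empty alignment")
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise AnalysisError("aligned sequences must have equal length")
        alphabet = set(AA1) | {GAP, "X"}
        for s in sequences:
            bad = set(s) - alphabet
            if bad:
                raise AnalysisError(f"unknown symbols in alignment: {bad}")
        self.sequences = sequences
        self.ids = list(ids) if ids else [f"seq{i}" for i in
                                          range(len(sequences))]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def depth(self) -> int:
        return len(self.sequences)

    def column(self, c: int) -> str:
        return "".join(s[c] for s in self.sequences)

    def frequencies(self, c: int, include_gaps: bool = True
                    ) -> dict[str, float]:
        counts = Counter(self.column(c))
        counts.pop("X", None)
        if not include_gaps:
            counts.pop(GAP, None)
        total = sum(counts.values())
        if total == 0:
            return {}
        return {aa: n / total for aa, n in sorted(counts.items())}

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(seqs, ids)

    def to_fasta(self, path) -> None:
        lines = []
        for i, s in zip(self.ids, self.sequences):
            lines.append(f">{i}")
            lines.append(s)
        Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Substitution matrix
# --------------------------------------------------------------------------

class SubstitutionMatrix:
    """20x20 substitution scores plus a flat gap score (default -5)."""

    def __init__(self, scores: dict[tuple[str, str], float],
                 gap_score: float = -5.0, name: str = "custom"):
        self.scores = scores
        self.gap_score = gap_score
        self.name = name

    def score(self, a: str, b: str) -> float:
        if a == GAP or b == GAP:
            return self.gap_score
        return self.scores[(a, b)]

    @classmethod
    def blosum62(cls, gap_score: float = -5.0) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        scores = {(a, b): float(m[a, b]) for a in AA1 for b in AA1}
        return cls(scores, gap_score, name="BLOSUM62")

    @classmethod
    def from_ncbi(cls, path, gap_score: float = -5.0
                  ) -> "SubstitutionMatrix":
        """Read a matrix in the standard NCBI text layout."""
        from Bio.Align import substitution_matrices

        m = substitution_matrices.read(str(path))
        scores = {(a, b): float(m[a, b]) for a in AA1 for b in AA1}
        return cls(scores, gap_score, name=Path(path).name)


# --------------------------------------------------------------------------
# Reduced alphabets
# --------------------------------------------------------------------------

NINE_CLASSES = ("LVIMC", "FY", "W", "G", "A", "STP", "EDNQ", "KR", "H")
SIX_CLASSES = ("LVIMC", "FYW", "G", "ASTP", "EDNQ", "KRH")


@dataclass(frozen=True)
class ReducedAlphabet:
    """A partition of the 20 amino-acid types into classes ("flavors")."""

    id: str
    classes: tuple[str, ...]

    def __post_init__(self):
        joined = "".join(self.classes)
        if sorted(joined) != sorted(AA1):
            raise AnalysisError(
                f"alphabet {self.id!r} is not a partition of the 20 types")

    @property
    def mapping(self) -> dict[str, int]:
        return {aa: k for k, cls in enumerate(self.classes) for aa in cls}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def of_type(self, aa: str) -> int:
        try:
            return self.mapping[aa]
        except KeyError:
            raise AnalysisError(f"unknown type {aa!r}") from None

    def of_sequence(self, seq: str) -> tuple[int, ...]:
        m = self.mapping
        return tuple(m[aa] for aa in seq)

    def members(self, flavor: int) -> str:
        return self.classes[flavor]


_ALPHABETS = {
    "nine": ReducedAlphabet("nine", NINE_CLASSES),
    "six": ReducedAlphabet("six", SIX_CLASSES),
    "identity20": ReducedAlphabet("identity20", tuple(AA1)),
}


def get_alphabet(name: str) -> ReducedAlphabet:
    try:
        return _ALPHABETS[name]
    except KeyError:
        raise AnalysisError(
            f"unknown alphabet {name!r}; choose from {sorted(_ALPHABETS)}"
        ) from None


# --------------------------------------------------------------------------
# Scores
# --------------------------------------------------------------------------

def identity_score(seq_a: str, seq_b: str) -> float:
    """Percent identity between two ungapped, equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise AnalysisError("sequences differ in length")
    if not seq_a:
        raise AnalysisError("empty sequences")
    matches = sum(a == b for a, b in zip(seq_a, seq_b))
    return 100.0 * matches / len(seq_a)


def similarity_score(seq: str, msa: MSA,
                     matrix: SubstitutionMatrix | None = None):
    """Profile-weighted substitution score of ``seq`` against an MSA.

    score = sum_l sum_a f_l(a) B(seq_l, a), where f_l includes the gap
    fraction and B(x, gap) is the flat gap score.  Returns (total,
    per-column array)."""
    matrix = matrix or SubstitutionMatrix.blosum62()
    if len(seq) != msa.length:
        raise AnalysisError(
            f"query length {len(seq)} != alignment length {msa.length}")
    per_col = np.zeros(msa.length)
    for c in range(msa.length):
        freqs = msa.frequencies(c, include_gaps=True)
        per_col[c] = sum(f * matrix.score(seq[c], a)
                         for a, f in freqs.items())
    return float(per_col.sum()), per_col


def score_overlap(scores_a, scores_b, method: str = "min_threshold"
                  ) -> float:
    """Overlap (%) between two score samples.

    ``min_threshold``: fraction of scores_a at or above min(scores_b) - the
    adopted reading of distribution overlap for design-vs-natural scores.
    ``coefficient``: two-sample distribution overlap coefficient
    (histogram intersection), an alternative definition."""
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both score samples must be non-empty")
    if method == "min_threshold":
        return 100.0 * float((a >= b.min()).mean())
    if method == "coefficient":
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        edges = np.linspace(lo, hi, 21)
        pa, _ = np.histogram(a, bins=edges, density=False)
        pb, _ = np.histogram(b, bins=edges, density=False)
        return 100.0 * float(np.minimum(pa / a.size, pb / b.size).sum())
    raise AnalysisError(f"unknown overlap method {method!r}")


# --------------------------------------------------------------------------
# Entropy and mutual information
# --------------------------------------------------------------------------

def _column_class_freqs(msa: MSA, c: int, alphabet: ReducedAlphabet):
    counts = np.zeros(alphabet.n_classes)
    mapping = alphabet.mapping
    for aa in msa.column(c):
        if aa in mapping:
            counts[mapping[aa]] += 1
    total = counts.sum()
    return counts / total if total > 0 else None


def positional_entropy(msa: MSA, alphabet: ReducedAlphabet | str = "nine",
                       positions=None, summarize: str = "exp"):
    """Per-column entropy S_l (nats) under a reduced alphabet and its
    exponential e^{S_l}; gaps are excluded and columns renormalized.

    Returns (S array, e^S array, summary), where the summary averages
    e^{S_l} arithmetically over the requested positions (``summarize =
    'log'`` averages S_l and exponentiates instead).  All-gap columns are
    NaN and excluded from the summary."""
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    S = np.full(msa.length, np.nan)
    for c in range(msa.length):
        f = _column_class_freqs(msa, c, alphabet)
        if f is None:
            continue
        nz = f[f > 0]
        S[c] = float(-(nz * np.log(nz)).sum())
    expS = np.exp(S)
    sel = np.arange(msa.length) if positions is None else np.asarray(
        list(positions), dtype=int)
    vals = expS[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise AnalysisError("no scorable columns in selection")
    if summarize == "exp":
        summary = float(vals.mean())
    elif summarize == "log":
        summary = float(np.exp(np.log(vals).mean()))
    else:
        raise AnalysisError(f"unknown summary mode {summarize!r}")
    return S, expS, summary


@dataclass
class CovarianceMatrix:
    """L x L mutual-information matrix (nats); diagonal = column entropy."""

    values: np.ndarray
    alphabet_id: str

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def argmax_offdiag(self) -> tuple[int, int]:
        v = self.values.copy()
        np.fill_diagonal(v, -np.inf)
        i, j = np.unravel_index(np.argmax(v), v.shape)
        return (int(min(i, j)), int(max(i, j)))

    def to_tsv(self, path) -> None:
        lines = ["\t".join(f"{x:.6f}" for x in row) for row in self.values]
        Path(path).write_text("\n".join(lines) + "\n")


def mutual_information_matrix(msa: MSA,
                              alphabet: ReducedAlphabet | str = "nine"
                              ) -> CovarianceMatrix:
    """Mutual information C_ij = sum_ab P_ij(a,b) ln[P_ij(a,b) /
    (P_i(a) P_j(b))] between all column pairs, by direct counting.

    Gapped rows are dropped per column pair; absent types contribute 0.
    The diagonal holds the column entropy."""
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    if msa.depth < 2:
        raise AnalysisError("mutual information needs >= 2 sequences")
    mapping = alphabet.mapping
    K = alphabet.n_classes
    L = msa.length
    # encode columns; -1 = gap/unknown
    enc = np.full((msa.depth, L), -1, dtype=int)
    for r, s in enumerate(msa.sequences):
        for c, aa in enumerate(s):
            enc[r, c] = mapping.get(aa, -1)
    C = np.zeros((L, L))
    for i in range(L):
        xi = enc[:, i]
        for j in range(i, L):
            xj = enc[:, j]
            ok = (xi >= 0) & (xj >= 0)
            n = int(ok.sum())
            if n == 0:
                continue
            joint = np.zeros((K, K))
            np.add.at(joint, (xi[ok], xj[ok]), 1.0)
            joint /= n
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            nz = joint > 0
            denom = np.outer(pi, pj)
            mi = float((joint[nz] * np.log(joint[nz] / denom[nz])).sum())
            if i == j:
                nzp = pi[pi > 0]
                C[i, i] = float(-(nzp * np.log(nzp)).sum())
            else:
                C[i, j] = C[j, i] = mi
    return CovarianceMatrix(values=C, alphabet_id=alphabet.id)


# --------------------------------------------------------------------------
# Correlated patterns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSpec:
    """A flavor pattern at a set of positions, with its ensemble
    frequency."""

    positions: tuple[int, ...]
    flavors: tuple[int, ...]
    frequency: float
    alphabet_id: str = "nine"

    def matches(self, sequence: str, alphabet: ReducedAlphabet) -> bool:
        return all(alphabet.of_type(sequence[p]) == f
                   for p, f in zip(self.positions, self.flavors))

    def label(self, alphabet: ReducedAlphabet) -> str:
        """Representative string: first member of each class."""
        return "".join(alphabet.members(f)[0] for f in self.flavors)


def _sequences_of(ensemble):
    if hasattr(ensemble, "sequences"):
        seqs = ensemble.sequences
        return list(seqs() if callable(seqs) else seqs)
    return list(ensemble)


def top_patterns(ensemble, positions, alphabet: ReducedAlphabet | str =
                 "nine", k: int = 10) -> list[PatternSpec]:
    """The k most frequent flavor patterns at ``positions`` (0-based) in
    the ensemble, with frequencies; ties break lexicographically."""
    if k <= 0:
        raise AnalysisError("k must be positive")
    if isinstance(alphabet, str):
        alphabet = get_alphabet(alphabet)
    seqs = _sequences_of(ensemble)
    if not seqs:
        raise AnalysisError("empty ensemble")
    positions = tuple(int(p) for p in positions)
    counts = Counter(
        tuple(alphabet.of_type(s[p]) for p in positions) for s in seqs)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(seqs)
    return [PatternSpec(positions=positions, flavors=flav,
                        frequency=c / n, alphabet_id=alphabet.id)
            for flav, c in ranked[:k]]


def subset_by_pattern(ensemble, pattern: PatternSpec,
                      complement: bool = False):
    """Members of the ensemble whose flavor-reduced sequence matches the
    pattern at all its positions (or the non-matching complement).

    Returns a list of records/sequences of the same kind as the input."""
    alphabet = get_alphabet(pattern.alphabet_id)
    if hasattr(ensemble, "records"):
        items = ensemble.records
        seq_of = lambda r: r.sequence  # noqa: E731
    else:
        items = list(ensemble)
        seq_of = lambda r: r  # noqa: E731
    out = [r for r in items
           if pattern.matches(seq_of(r), alphabet) != complement]
    return out
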