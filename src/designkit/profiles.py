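"""PSSM construction and internal profile search.

A position-specific scoring matrix is built from an aligned sequence set
with background-frequency pseudocounts:

    p_a = (c_a + beta * q_a) / (N + beta),   score = 2 * log2(p_a / q_a)

(half-bit convention).  The matrix can be exported for external search
tools (ASCII PSSM layout, TSV, or the aligned FASTA itself) or used with
the built-in ungapped sliding-window search: per-target best window scores
are converted to E-values with an extreme-value (Gumbel) null fitted to a
seeded shuffled-database control - the internal, offline stand-in for an
external profile search step.  E-values from this calibration are
self-consistent but not comparable to any external tool's statistics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as _stats

from .analysis import GAP, AnalysisError, get_alphabet
from .structure import AA1

__all__ = [
    "BACKGROUND_FREQS",
    "PSSM",
    "SearchHit",
    "RetrievalReport",
    "build_pssm",
    "export_pssm",
    "parse_pssm",
    "profile_search",
    "pattern_retrieval_experiment",
]

#: Amino-acid background frequencies (Robinson & Robinson counts, as used
#: by standard search tools), renormalized over the 20 types.
BACKGROUND_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AA1)}


@dataclass
class PSSM:
    """Per-position log-odds scores (half bits), with the frequencies they
    derive from and provenance metadata."""

    scores: np.ndarray                # L x 20, half-bit log odds
    probs: np.ndarray                 # L x 20 pseudocounted frequencies
    background: np.ndarray            # 20
    consensus: str
    pseudocount_weight: float
    source_hash: str = ""

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def window_scores(self, seq: str) -> np.ndarray:
        """Scores of every length-L window of ``seq`` (empty if shorter)."""
        L = self.length
        n = len(seq)
        if n < L:
            return np.zeros(0)
        enc = np.array([_AA_INDEX.get(a, -1) for a in seq])
        out = np.zeros(n - L + 1)
        for off in range(n - L + 1):
            w = enc[off:off + L]
            ok = w >= 0
            out[off] = self.scores[np.arange(L)[ok], w[ok]].sum()
        return out


def build_pssm(sequences, background: dict[str, float] | None = None,
               pseudocount_weight: float = 1.0) -> PSSM:
    """Build a PSSM from aligned sequences with pseudocounts.

    Gap characters contribute nothing to the counts.  ``pseudocount_weight``
    (beta) must be positive - with beta = 0 unobserved types would score
    -infinity."""
    sequences = [str(s).upper() for s in sequences]
    if not sequences:
        raise AnalysisError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise AnalysisError("sequences must be aligned (equal length)")
    if pseudocount_weight <= 0:
        raise AnalysisError("pseudocount weight must be > 0")
    bg = background or BACKGROUND_FREQS
    q = np.array([bg.get(aa, 0.0) for aa in AA1], dtype=float)
    if (q <= 0).any():
        raise AnalysisError("background frequencies must be positive")
    q = q / q.sum()
    beta = pseudocount_weight
    probs = np.zeros((L, 20))
    consensus = []
    for c in range(L):
        counts = np.zeros(20)
        n = 0
        for s in sequences:
            aa = s[c]
            if aa in _AA_INDEX:
                counts[_AA_INDEX[aa]] += 1
                n += 1
        probs[c] = (counts + beta * q) / (n + beta)
        consensus.append(AA1[int(np.argmax(counts))] if n else "A")
    scores = 2.0 * np.log2(probs / q)
    import hashlib

    h = hashlib.sha256("\n".join(sequences).encode()).hexdigest()[:16]
    return PSSM(scores=scores, probs=probs, background=q,
                consensus="".join(consensus), pseudocount_weight=beta,
                source_hash=h)


# --------------------------------------------------------------------------
# Export / import
# --------------------------------------------------------------------------

def export_pssm(pssm: PSSM, path, dialect: str = "ascii-pssm",
                sequences=None) -> None:
    """Write the PSSM in one of the supported dialects.

    ``ascii-pssm`` mimics the classic search-tool ASCII layout (position,
    consensus residue, 20 rounded scores); ``tsv`` is L rows x 20 columns
    of unrounded scores; ``aligned-fasta`` writes the source sequences
    (required) so an external tool can derive its own profile."""
    path = Path(path)
    if dialect == "ascii-pssm":
        buf = io.StringIO()
        buf.write("# designkit position-specific scoring matrix"
                  " (half bits)\n")
        buf.write(f"# consensus: {pssm.consensus}\n")
        buf.write("pos res " + " ".join(f"{aa:>4s}" for aa in AA1) + "\n")
        for i in range(pssm.length):
            row = " ".join(f"{int(round(x)):4d}" for x in pssm.scores[i])
            buf.write(f"{i + 1:3d} {pssm.consensus[i]:>3s} {row}\n")
        path.write_text(buf.getvalue())
    elif dialect == "tsv":
        lines = ["\t".join(AA1)]
        for i in range(pssm.length):
            lines.append("\t".join(f"{x:.6f}" for x in pssm.scores[i]))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "aligned-fasta":
        if sequences is None:
            raise AnalysisError(
                "aligned-fasta export needs the source sequences")
        lines = []
        for i, s in enumerate(sequences):
            lines.append(f">seq_{i}")
            lines.append(str(s))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise AnalysisError(f"unknown PSSM dialect {dialect!r}")


def parse_pssm(path, dialect: str = "tsv") -> np.ndarray:
    """Read back exported scores (tsv: unrounded; ascii-pssm: rounded)."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if dialect == "tsv":
        return np.array([[float(x) for x in ln.split("\t")]
                         for ln in lines[1:]])
    if dialect == "ascii-pssm":
        rows = []
        for ln in lines[1:]:
            parts = ln.split()
            rows.append([float(x) for x in parts[2:22]])
        return np.array(rows)
    raise AnalysisError(f"unknown PSSM dialect {dialect!r}")


# --------------------------------------------------------------------------
# Internal profile search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchHit:
    target_id: str
    score: float        # best window score, half bits
    evalue: float
    span: tuple[int, int]


@dataclass
class SearchResult:
    hits: list[SearchHit]
    lam: float          # fitted Gumbel 1/scale
    mu: float           # fitted Gumbel location
    n_targets: int


def _load_database(database):
    if isinstance(database, (str, Path)):
        from Bio import SeqIO

        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(database), "fasta")]
    return [(rid, str(seq).upper()) for rid, seq in database]


def _best_scores(pssm: PSSM, records):
    best = np.full(len(records), -np.inf)
    spans = [(0, 0)] * len(records)
    for t, (_, seq) in enumerate(records):
        w = pssm.window_scores(seq)
        if w.size:
            off = int(np.argmax(w))
            best[t] = w[off]
            spans[t] = (off, off + pssm.length)
    return best, spans


def profile_search(pssm: PSSM, database, e_threshold: float = 0.1,
                   seed: int = 0, n_shuffles: int = 20,
                   return_result: bool = False):
    """Ungapped sliding-window search of a FASTA database (path or list of
    (id, seq)) with the PSSM.

    The null model is built by residue-shuffling every target
    ``n_shuffles`` times (seeded) and fitting a Gumbel distribution to the
    per-target best scores; a hit's E-value is N_targets * P_null(S >= s).
    Hits with E <= ``e_threshold`` are returned sorted by E ascending.
    """
    records = _load_database(database)
    if not records:
        raise AnalysisError("empty database")
    best, spans = _best_scores(pssm, records)
    scorable = np.isfinite(best)
    if not scorable.any():
        return ([], SearchResult([], math.nan, math.nan, 0)) \
            if return_result else []
    rng = np.random.default_rng(seed)
    null_scores = []
    for _, seq in records:
        arr = np.array(list(seq))
        for _ in range(n_shuffles):
            rng.shuffle(arr)
            w = pssm.window_scores("".join(arr))
            if w.size:
                null_scores.append(w.max())
    null_scores = np.asarray(null_scores)
    if null_scores.size < 10:
        raise AnalysisError("too few scorable targets to calibrate null")
    mu, beta = _fit_gumbel(null_scores)
    n_t = int(scorable.sum())
    hits = []
    for t, (rid, _) in enumerate(records):
        if not scorable[t]:
            continue
        p = math.exp(-math.exp(-(best[t] - mu) / beta))  # CDF
        evalue = n_t * (1.0 - p)
        if evalue <= e_threshold:
            hits.append(SearchHit(target_id=rid, score=float(best[t]),
                                  evalue=float(evalue), span=spans[t]))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    if return_result:
        return hits, SearchResult(hits, 1.0 / beta, mu, n_t)
    return hits


def _fit_gumbel(samples: np.ndarray):
    """Maximum-likelihood Gumbel(mu, beta) fit for right-tail maxima."""
    mu, beta = _stats.gumbel_r.fit(samples)
    return float(mu), float(max(beta, 1e-9))


# --------------------------------------------------------------------------
# Pattern-subset retrieval protocol
# --------------------------------------------------------------------------

@dataclass
class RetrievalReport:
    """Outcome of the pattern-subset retrieval experiment.

    per_subset maps a subset label to {"tp": ids, "fp": ids}; cumulative
    holds the union over subsets, pooled the control run."""

    per_subset: dict
    cumulative_tp: set
    cumulative_fp: set
    pooled_tp: set
    pooled_fp: set

    def counts(self) -> dict:
        out = {label: (len(v["tp"]), len(v["fp"]))
               for label, v in self.per_subset.items()}
        out["cumulative"] = (len(self.cumulative_tp),
                             len(self.cumulative_fp))
        out["pooled"] = (len(self.pooled_tp), len(self.pooled_fp))
        return out


def pattern_retrieval_experiment(ensemble, patterns, database, labels,
                                 sample_size: int = 50, repeats: int = 10,
                                 e_threshold: float = 1.0, seed: int = 0,
                                 pseudocount_weight: float = 1.0
                                 ) -> RetrievalReport:
    """Per-pattern homologue retrieval with pooled control.

    For every pattern: isolate the matching ensemble subset, then
    ``repeats`` times sample ``sample_size`` sequences, build a PSSM and
    search the database; retrieved true/false positives (per ``labels``)
    are accumulated as unions.  An extra subset of sequences matching no
    pattern is included, and a pooled control samples from the whole
    ensemble with repeats scaled to the total number of subset queries.
    """
    from .analysis import subset_by_pattern

    if not patterns:
        raise AnalysisError("empty pattern list")
    seqs_of = lambda items: [getattr(r, "sequence", r) for r in items]  # noqa: E731
    all_items = list(getattr(ensemble, "records", ensemble))
    subsets = {}
    matched_any = set()
    for k, pat in enumerate(patterns):
        sub = subset_by_pattern(all_items, pat)
        subsets[f"pattern_{k}"] = seqs_of(sub)
        matched_any.update(id(x) for x in sub)
    none_sub = [x for x in all_items if id(x) not in matched_any]
    if none_sub:
        subsets["none"] = seqs_of(none_sub)
    rng = np.random.default_rng(seed)
    per_subset = {}
    cum_tp, cum_fp = set(), set()
    n_queries = 0
    for label, seqs in subsets.items():
        tp, fp = set(), set()
        for rep in range(repeats):
            n_queries += 1
            replace = len(seqs) < sample_size
            idx = rng.choice(len(seqs), size=min(sample_size, len(seqs))
                             if not replace else sample_size,
                             replace=replace)
            sample = [seqs[i] for i in idx]
            pssm = build_pssm(sample,
                              pseudocount_weight=pseudocount_weight)
            hits = profile_search(pssm, database, e_threshold,
                                  seed=int(rng.integers(2 ** 31)))
            for h in hits:
                (tp if labels.get(h.target_id, False) else fp).add(
                    h.target_id)
        per_subset[label] = {"tp": tp, "fp": fp}
        cum_tp |= tp
        cum_fp |= fp
    pooled_tp, pooled_fp = set(), set()
    all_seqs = seqs_of(all_items)
    for rep in range(n_queries):
        idx = rng.choice(len(all_seqs),
                         size=min(sample_size, len(all_seqs)),
                         replace=len(all_seqs) < sample_size)
        sample = [all_seqs[i] for i in idx]
        pssm = build_pssm(sample, pseudocount_weight=pseudocount_weight)
        hits = profile_search(pssm, database, e_threshold,
                              seed=int(rng.integers(2 ** 31)))
        for h in hits:
            (pooled_tp if labels.get(h.target_id, False)
             else pooled_fp).add(h.target_id)
    return RetrievalReport(per_subset=per_subset, cumulative_tp=cum_tp,
                           cumulative_fp=cum_fp, pooled_tp=pooled_tp,
                           pooled_fp=pooled_fp)
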