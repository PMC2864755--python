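"""Ensemble statistics: scores, entropies, mutual information, patterns."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import designkit as dk
from designkit.analysis import (
    AnalysisError,
    MSA,
    SubstitutionMatrix,
    get_alphabet,
    mutual_information_matrix,
    positional_entropy,
    score_overlap,
    similarity_score,
    top_patterns,
    subset_by_pattern,
)

B62 = SubstitutionMatrix.blosum62()


# -- identity --------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ("ACDE", "ACDE", 100.0),
    ("AAAA", "VVVV", 0.0),
    ("ACDE", "ACDF", 75.0),
])
def test_identity_examples(a, b, expected):
    assert dk.identity_score(a, b) == pytest.approx(expected)


def test_identity_length_mismatch_errors():
    with pytest.raises(AnalysisError):
        dk.identity_score("AA", "AAA")


# -- similarity ------------------------------------------------------------

def test_similarity_vs_self_is_blosum_diagonal():
    msa = MSA(["AC"])
    total, per_col = similarity_score("AC", msa, B62)
    assert total == pytest.approx(4.0 + 9.0)  # B(A,A) + B(C,C)
    assert per_col.tolist() == [4.0, 9.0]


def test_similarity_single_sequence_equals_pairwise_scorer():
    """Against a one-sequence MSA the profile score reduces to the plain
    pairwise BLOSUM sum (independent scorer from Biopython)."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    query = "AVLDKRMF"
    target = "AVIDERLF"
    msa = MSA([target])
    total, _ = similarity_score(query, msa, B62)
    expected = sum(float(m[q, t]) for q, t in zip(query, target))
    assert total == pytest.approx(expected)


def test_similarity_gap_column_contributes_gap_score():
    msa = MSA(["A-", "A-"])
    total, per_col = similarity_score("AA", msa, B62)
    assert per_col[1] == pytest.approx(-5.0)


def test_similarity_mixed_column():
    msa = MSA(["A", "V"])
    total, _ = similarity_score("A", msa, B62)
    assert total == pytest.approx(0.5 * 4.0 + 0.5 * 0.0)


def test_similarity_unaligned_length_errors():
    with pytest.raises(AnalysisError):
        similarity_score("AAA", MSA(["AA"]), B62)


# -- overlap ---------------------------------------------------------------

def test_score_overlap_examples():
    assert score_overlap([5, 6, 7], [1, 2]) == pytest.approx(100.0)
    assert score_overlap([0, 1], [5, 6]) == pytest.approx(0.0)
    assert score_overlap([1, 2, 3], [2, 9]) == pytest.approx(200 / 3)


def test_score_overlap_alternative_definition_bounded():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 200)
    b = rng.normal(0.5, 1, 200)
    c = score_overlap(a, b, method="coefficient")
    assert 0.0 <= c <= 100.0


# -- entropy ---------------------------------------------------------------

def test_entropy_single_class_column():
    msa = MSA(["A", "A", "A"])
    S, expS, summary = positional_entropy(msa, "nine")
    assert S[0] == pytest.approx(0.0)
    assert expS[0] == pytest.approx(1.0)


def test_entropy_uniform_over_nine_classes():
    column = "LFWGASEKH"  # one member of each nine-class group
    msa = MSA([c for c in column])
    S, expS, summary = positional_entropy(msa, "nine")
    assert expS[0] == pytest.approx(9.0, rel=1e-9)


def test_entropy_class_merge_fy():
    msa = MSA(["F", "Y", "F", "Y"])
    _, expS, _ = positional_entropy(msa, "nine")
    assert expS[0] == pytest.approx(1.0)
    _, expS20, _ = positional_entropy(msa, "identity20")
    assert expS20[0] == pytest.approx(2.0)


def test_entropy_gap_handling():
    msa = MSA(["A-", "A-", "V-"])
    S, expS, summary = positional_entropy(msa, "nine")
    assert np.isnan(S[1])  # all-gap column flagged
    assert summary == pytest.approx(expS[0])


@settings(max_examples=25, deadline=None)
@given(st_.lists(st_.text(alphabet="AVLDKRFY", min_size=6, max_size=6),
                 min_size=2, max_size=12))
def test_entropy_bounds_property(seqs):
    msa = MSA(seqs)
    for alpha in ("nine", "six", "identity20"):
        _, expS, _ = positional_entropy(msa, alpha)
        ok = ~np.isnan(expS)
        assert (expS[ok] >= 1.0 - 1e-9).all()
        assert (expS[ok] <= get_alphabet(alpha).n_classes + 1e-9).all()


# -- mutual information ----------------------------------------------------

def test_mi_perfectly_coupled_binary_columns():
    seqs = ["AK", "VD"] * 250
    msa = MSA(seqs)
    C = mutual_information_matrix(msa, "nine")
    assert C.values[0, 1] == pytest.approx(math.log(2.0), rel=1e-9)
    assert C.values[0, 0] == pytest.approx(math.log(2.0), rel=1e-9)


def test_mi_independent_columns_near_zero():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("AVLD"), 2)) for _ in range(4000)]
    C = mutual_information_matrix(MSA(seqs), "nine")
    assert C.values[0, 1] < 0.01


def test_mi_symmetric_and_nonnegative():
    rng = np.random.default_rng(2)
    seqs = ["".join(rng.choice(list("AVLDKRFY"), 6)) for _ in range(80)]
    C = mutual_information_matrix(MSA(seqs), "nine")
    assert np.allclose(C.values, C.values.T)
    assert (C.values >= -1e-12).all()


@settings(max_examples=15, deadline=None)
@given(st_.integers(min_value=0, max_value=10_000))
def test_mi_alphabet_coarsening_monotone(seed):
    """Data processing: merging classes cannot increase MI, so
    MI(six) <= MI(nine) <= MI(20 types), column-pair-wise."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("LVIMCFYWGASTPEDNQKRH"), 5))
            for _ in range(40)]
    msa = MSA(seqs)
    c6 = mutual_information_matrix(msa, "six").values
    c9 = mutual_information_matrix(msa, "nine").values
    c20 = mutual_information_matrix(msa, "identity20").values
    off = ~np.eye(5, dtype=bool)
    assert (c6[off] <= c9[off] + 1e-9).all()
    assert (c9[off] <= c20[off] + 1e-9).all()


def test_mi_planted_pair_is_argmax():
    spec = dk.PlantedMSASpec(
        n_sequences=500, length=15, seed=3,
        coupled_pairs=[(4, 11, [("A", "K", 0.5), ("V", "D", 0.5)])])
    msa, truth = dk.make_planted_msa(spec)
    C = mutual_information_matrix(msa, "nine")
    assert C.argmax_offdiag() == (4, 11)


def test_mi_requires_two_sequences():
    with pytest.raises(AnalysisError):
        mutual_information_matrix(MSA(["AV"]))


# -- alphabets -------------------------------------------------------------

def test_alphabet_partitions():
    nine = get_alphabet("nine")
    six = get_alphabet("six")
    assert nine.n_classes == 9 and six.n_classes == 6
    assert nine.of_type("F") == nine.of_type("Y") != nine.of_type("W")
    assert six.of_type("F") == six.of_type("W")
    assert six.of_type("K") == six.of_type("H")
    assert nine.of_type("K") != nine.of_type("H")


# -- patterns --------------------------------------------------------------

def test_top_patterns_single_sequence():
    pats = top_patterns(["AVLDK"], positions=[0, 2], k=5)
    assert len(pats) == 1
    assert pats[0].frequency == pytest.approx(1.0)


def test_pattern_frequencies_partition():
    rng = np.random.default_rng(4)
    seqs = ["".join(rng.choice(list("FYWAK"), 4)) for _ in range(100)]
    pats = top_patterns(seqs, positions=[0, 1], k=1000)
    assert sum(p.frequency for p in pats) == pytest.approx(1.0)
    union = sum(len(subset_by_pattern(seqs, p)) for p in pats)
    assert union == len(seqs)


def test_planted_subfamily_patterns_recovered():
    spec = dk.PlantedMSASpec(
        n_sequences=600, length=12, seed=9,
        subfamily_weights=[0.6, 0.4],
        subfamily_patterns=[
            {1: "H", 3: "D", 5: "W"},
            {1: "D", 3: "L", 5: "W"},
        ])
    msa, truth = dk.make_planted_msa(spec)
    nine = get_alphabet("nine")
    pats = top_patterns(msa.sequences, positions=[1, 3, 5],
                        alphabet="nine", k=2)
    freqs = sorted((p.frequency for p in pats), reverse=True)
    labels = np.asarray(truth["subfamily_labels"])
    realized = sorted(((labels == k).mean() for k in (0, 1)), reverse=True)
    # patterns are deterministic per member: frequencies match the realized
    # subfamily split exactly, which itself is 0.6/0.4 up to sampling error
    assert freqs[0] == pytest.approx(realized[0], abs=1e-12)
    assert freqs[1] == pytest.approx(realized[1], abs=1e-12)
    assert realized[0] == pytest.approx(0.6, abs=0.08)
    flavors = {p.flavors for p in pats}
    expected = {
        tuple(nine.of_type(aa) for aa in ("H", "D", "W")),
        tuple(nine.of_type(aa) for aa in ("D", "L", "W")),
    }
    assert flavors == expected


def test_subset_by_pattern_consistency_and_complement():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("FYAK"), 3)) for _ in range(200)]
    pats = top_patterns(seqs, positions=[0, 2], k=3)
    for p in pats:
        sub = subset_by_pattern(seqs, p)
        assert len(sub) == round(p.frequency * len(seqs))
        comp = subset_by_pattern(seqs, p, complement=True)
        assert len(sub) + len(comp) == len(seqs)


def test_top_patterns_invalid_k():
    with pytest.raises(AnalysisError):
        top_patterns(["AV"], positions=[0], k=0)
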