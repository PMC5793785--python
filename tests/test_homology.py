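"""Cross-species uORF homology: alignment, Jaccard, classification."""

import numpy as np
import pytest

from uorfseqr.candidates import CandidateUORF
from uorfseqr.homology import (
    HOXD70,
    SubstitutionMatrix,
    align_uorf_to_tl,
    classify_homologs,
    homolog_triplets,
    jaccard_index,
    position_homologs,
    sequence_homologs,
)

RNG = np.random.default_rng(0)


def _random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_identical_substring_alignment():
    uorf = "ATGCATCGATTAA"
    tl = "CCCCC" + uorf + "GGGGG"
    _, mapped, score, _ = align_uorf_to_tl(uorf, tl, n_shuffles=0)
    assert mapped == (5, 5 + len(uorf))
    expected = sum(HOXD70[(b, b)] for b in uorf)
    assert score == expected


def test_reversed_uorf_scores_below_identity():
    rng = np.random.default_rng(1)
    uorf = _random_seq(21, rng)
    tl = "CC" + uorf + "AA"
    _, _, s_fwd, _ = align_uorf_to_tl(uorf, tl, n_shuffles=0)
    _, _, s_rev, _ = align_uorf_to_tl(uorf[::-1], tl, n_shuffles=0)
    assert s_rev < s_fwd


def test_z_score_near_zero_for_unrelated_sequences():
    rng = np.random.default_rng(2)
    for seed in range(3):
        uorf = _random_seq(24, rng)
        tl = _random_seq(120, rng)
        _, _, _, z = align_uorf_to_tl(uorf, tl, n_shuffles=100, rng=seed)
        assert z is not None and abs(z) < 3


def test_z_flagged_missing_when_shuffles_degenerate():
    # homopolymer uORF: every shuffle is identical -> sd 0 -> z is None
    _, _, _, z = align_uorf_to_tl("AAAAAAAAA", "CCAAAAAAAAACC", n_shuffles=20, rng=0)
    assert z is None


@pytest.mark.parametrize(
    "a,b,expected",
    [(((0, 10), (0, 10)), None, 1.0),
     (((0, 10), (20, 30)), None, 0.0),
     (((0, 10), (5, 15)), None, 5 / 15)],
)
def test_jaccard(a, b, expected):
    ia, ib = a
    assert jaccard_index(ia, ib) == pytest.approx(expected)
    assert jaccard_index(ib, ia) == pytest.approx(expected)  # symmetric


def test_substitution_matrix_symmetry_enforced():
    bad = dict(HOXD70)
    bad[("A", "C")] = 5
    with pytest.raises(ValueError):
        SubstitutionMatrix(bad)


def _call(gene, start, stop):
    return CandidateUORF(gene, start, stop, "ATG", stop - start + 1)


def _species_pair(shift=0, divergent=False, leader_len=90):
    rng = np.random.default_rng(7)
    uorf = "ATGCCTGACGTAGATTCATAA"  # 21 nt
    la = _random_seq(30, rng) + uorf + _random_seq(leader_len - 30 - len(uorf), rng)
    if divergent:
        lb = _random_seq(leader_len, rng)
    else:
        lb = la
    calls_a = [_call("gene1", 30, 50)]
    calls_b = [_call("gene1", 30 + shift, 50 + shift)]
    return calls_a, calls_b, {"gene1": "gene1"}, {"gene1": la}, {"gene1": lb}


def test_identical_species_sequence_homolog_jaccard_one():
    calls_a, calls_b, pairs, tla, tlb = _species_pair()
    out = sequence_homologs(calls_a, calls_b, pairs, tla, tlb, rng=0)
    assert len(out) == 1
    assert out[0].jaccard == 1.0
    assert out[0].homology_class == "sequence"


def test_half_overlap_fails_default_threshold():
    calls_a, calls_b, pairs, tla, tlb = _species_pair(shift=7)
    # mapped interval [30,51) vs call [37,58): intersection 14, union 28
    out = sequence_homologs(calls_a, calls_b, pairs, tla, tlb, rng=0)
    assert out == []
    loose = sequence_homologs(calls_a, calls_b, pairs, tla, tlb, threshold=0.0, rng=0)
    assert len(loose) == 1


def test_position_homologs_or_rule():
    lens_a = {"gene1": 90}
    lens_b = {"gene1": 90}
    pairs = {"gene1": "gene1"}
    a = [_call("gene1", 40, 60)]
    # starts differ by 2 -> pair
    assert position_homologs(a, [_call("gene1", 42, 62)], pairs, lens_a, lens_b)
    # starts and stops differ by 6 -> no pair
    assert not position_homologs(a, [_call("gene1", 46, 66)], pairs, lens_a, lens_b)
    # starts differ by 9 but stops by 0 -> pair under OR semantics
    b = [_call("gene1", 49, 60)]
    assert position_homologs(a, b, pairs, lens_a, lens_b)
    # AND semantics rejects the same pair
    assert not position_homologs(a, b, pairs, lens_a, lens_b, require_both=True)


def test_sequence_takes_precedence_over_position():
    # identical leaders: the pair satisfies both definitions
    calls_a, calls_b, pairs, tla, tlb = _species_pair()
    out = classify_homologs(calls_a, calls_b, pairs, tla, tlb, rng=0)
    assert len(out) == 1
    assert out[0].homology_class == "sequence"


def test_divergent_but_position_matched_is_positional():
    calls_a, calls_b, pairs, tla, tlb = _species_pair(shift=3, divergent=True)
    out = classify_homologs(calls_a, calls_b, pairs, tla, tlb, rng=0)
    assert [p.homology_class for p in out] == ["position"]


def test_triplets_require_all_three_species():
    ab = [type("P", (), {"uorf_a": _call("g", 0, 8), "uorf_b": _call("g", 0, 8)})()]
    bc = [type("P", (), {"uorf_a": _call("g", 0, 8), "uorf_b": _call("g", 0, 8)})()]
    assert len(homolog_triplets(ab, bc, [])) == 1
    assert len(homolog_triplets(ab, [], [])) == 0
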