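"""uORF enumeration against a brute-force oracle and overlap resolution."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uorfseqr.candidates import (
    NCC_CODONS,
    START_CODONS,
    STOP_CODONS,
    CandidateUORF,
    enumerate_candidates,
    resolve_overlaps,
)


def oracle_enumerate(leader, context=None):
    """Plain position-scan reference: start codon, walk frame to first stop."""
    context = leader if context is None else context
    out = []
    if len(leader) < 3:  # degenerate leaders yield no candidates
        return out
    for i in range(len(leader)):
        if context[i : i + 3] not in START_CODONS:
            continue
        j = i + 3
        while j + 3 <= len(context):
            if context[j : j + 3] in STOP_CODONS:
                out.append((i, j + 2, context[i : i + 3], j + 2 >= len(leader)))
                break
            j += 3
    return out


def _as_tuples(cands):
    return [(c.start_pos, c.stop_pos, c.start_codon, c.overlaps_morf) for c in cands]


def test_simple_aug_uorf():
    cands = enumerate_candidates("ATGAAATAA")
    assert _as_tuples(cands) == [(0, 8, "ATG", False)]
    assert cands[0].length_nt == 9


def test_ncc_uug_uorf():
    cands = enumerate_candidates("TTGTAACCC")
    assert cands[0].start_codon == "TTG"
    assert cands[0].length_nt == 6


def test_agg_is_not_a_start():
    # AGG has an in-frame stop but is the non-initiating null codon
    cands = enumerate_candidates("AGGAAATAACC")
    assert all(c.start_codon != "AGG" for c in cands)
    assert len(NCC_CODONS) == 7  # the seven near-cognate triplets


def test_stop_in_morf_flagged():
    leader = "CCATGCC"  # ATG at 2, no stop inside the leader
    context = leader + "ATAACCC"  # first in-frame stop at context 8..10
    cands = enumerate_candidates(leader, context)
    assert _as_tuples(cands) == [(2, 10, "ATG", True)]


def test_short_leader_empty():
    assert enumerate_candidates("AT") == []


def test_no_stop_no_candidate():
    # N-terminal extensions (no in-frame stop) are not uORFs
    assert enumerate_candidates("ATGAAAAAA") == []


def test_oracle_equivalence_random_battery():
    rng = np.random.default_rng(123)
    for _ in range(300):
        n = int(rng.integers(0, 120))
        leader = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
        morf = "".join("ACGT"[b] for b in rng.integers(0, 4, 60))
        got = _as_tuples(enumerate_candidates(leader, leader + morf))
        assert got == oracle_enumerate(leader, leader + morf)


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=80))
def test_oracle_equivalence_property(leader):
    assert _as_tuples(enumerate_candidates(leader)) == oracle_enumerate(leader)


def _cand(gene, start, stop):
    codon = "ATG"
    return CandidateUORF(gene, start, stop, codon, stop - start + 1)


def test_resolve_nested_pair():
    a, b = _cand("g", 0, 8), _cand("g", 3, 8)
    kept = resolve_overlaps([(a, 5.0), (b, 3.0)])
    assert [c.start_pos for c, _ in kept] == [0]


def test_resolve_disjoint_pair():
    kept = resolve_overlaps([(_cand("g", 0, 8), 5.0), (_cand("g", 12, 20), 3.0)])
    assert len(kept) == 2


def test_resolve_three_mutually_overlapping():
    # 9 and 7 overlap, 8 disjoint from 9 but overlaps 7 -> retain 9 and 8
    a = _cand("g", 0, 8)     # score 9
    b = _cand("g", 12, 20)   # score 8, disjoint from a
    c = _cand("g", 6, 17)    # score 7, overlaps both
    kept = resolve_overlaps([(a, 9.0), (b, 8.0), (c, 7.0)])
    assert sorted(x.start_pos for x, _ in kept) == [0, 12]


def test_resolve_different_genes_do_not_clash():
    kept = resolve_overlaps([(_cand("g1", 0, 8), 5.0), (_cand("g2", 0, 8), 3.0)])
    assert len(kept) == 2


def test_resolve_greedy_optimality_small_instances():
    """Greedy by score: no retained set admits a skipped higher scorer."""
    rng = np.random.default_rng(5)
    for _ in range(30):
        cands = []
        for k in range(6):
            start = int(rng.integers(0, 30))
            stop = start + 3 * int(rng.integers(1, 5)) - 1
            cands.append((_cand("g", start, stop), float(rng.integers(1, 100))))
        scores = {id(c): s for c, s in cands}
        kept = resolve_overlaps(cands)
        kept_ids = {id(c) for c, _ in kept}
        for cand, score in cands:
            if id(cand) in kept_ids:
                continue
            # every skipped candidate overlaps a retained one with >= score
            clash = [
                kc for kc, ks in kept
                if kc.start_pos <= cand.stop_pos and cand.start_pos <= kc.stop_pos
            ]
            assert clash
            assert max(scores[id(kc)] for kc in clash) >= score


def test_candidate_invariants():
    with pytest.raises(ValueError):
        CandidateUORF("g", 0, 7, "ATG", 8)  # length not a codon multiple
    with pytest.raises(ValueError):
        CandidateUORF("g", 0, 8, "AAG", 9)  # AAG not in the allowed start set
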