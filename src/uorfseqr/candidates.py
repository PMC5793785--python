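"""Candidate uORF enumeration and overlap resolution.

A candidate uORF is an AUG or near-cognate start codon within the
transcript leader together with its first in-frame stop codon. The
near-cognate set has seven members (UUG, CUG, GUG, ACG, AUA, AUU, AUC);
AGG and AAG are treated as non-initiating. Stops may fall downstream of
the leader (inside the main ORF); such candidates are flagged
``overlaps_morf`` and excluded from default calling output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

START_CODONS: tuple[str, ...] = ("ATG", "TTG", "CTG", "GTG", "ACG", "ATA", "ATT", "ATC")
NCC_CODONS: tuple[str, ...] = START_CODONS[1:]
STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codon_id(codon: str) -> int:
    return 16 * _BASE_CODE[codon[0]] + 4 * _BASE_CODE[codon[1]] + _BASE_CODE[codon[2]]


_START_IDS = frozenset(_codon_id(c) for c in START_CODONS)
_STOP_IDS = frozenset(_codon_id(c) for c in STOP_CODONS)


def to_rna(codon: str) -> str:
    """Print form: DNA codon -> RNA codon (ATG -> AUG)."""
    return codon.replace("T", "U")


@dataclass(frozen=True)
class CandidateUORF:
    """An enumerated uORF in distal-TSS transcript coordinates.

    ``start_pos`` is the first nucleotide of the start codon,
    ``stop_pos`` the last nucleotide of the stop codon (inclusive).
    """

    gene_id: str
    start_pos: int
    stop_pos: int
    start_codon: str
    length_nt: int
    overlaps_morf: bool = False

    def __post_init__(self) -> None:
        if self.start_codon not in START_CODONS:
            raise ValueError(f"{self.start_codon} is not an allowed start codon")
        if (self.stop_pos - self.start_pos + 1) % 3 != 0:
            raise ValueError("uORF length must be a multiple of 3")

    @property
    def uid(self) -> str:
        return f"{self.gene_id}:{self.start_pos}-{self.stop_pos}"

    @property
    def interval(self) -> tuple[int, int]:
        """Half-open transcript interval [start, stop_pos + 1)."""
        return (self.start_pos, self.stop_pos + 1)


def enumerate_candidates(leader_seq: str, morf_context_seq: str | None = None,
                         gene_id: str = "") -> list[CandidateUORF]:
    """Scan a transcript leader for start codons with in-frame stops.

    ``leader_seq`` runs from the most distal TSS to the nucleotide
    before the mORF start. ``morf_context_seq`` is the leader followed
    by downstream (mORF) sequence so that stop codons may be sought past
    the leader boundary; it defaults to the leader alone. One candidate
    is produced per qualifying start position, ending at the FIRST
    in-frame stop; starts whose stop lies at/after the mORF start are
    flagged ``overlaps_morf``. Start positions lie within the leader.
    """
    leader_len = len(leader_seq)
    context = leader_seq if morf_context_seq is None else morf_context_seq
    if not context.startswith(leader_seq):
        raise ValueError("morf_context_seq must begin with leader_seq")
    if leader_len < 3 or len(context) < 3:
        return []

    codes = np.full(len(context), -1, dtype=np.int64)
    for base, val in _BASE_CODE.items():
        codes[np.frombuffer(context.encode(), dtype=np.uint8) == ord(base)] = val
    valid = codes >= 0
    n_codons = len(context) - 2
    tri_ok = valid[:n_codons] & valid[1 : n_codons + 1] & valid[2 : n_codons + 2]
    tri = 16 * codes[:n_codons] + 4 * codes[1 : n_codons + 1] + codes[2 : n_codons + 2]
    tri[~tri_ok] = -1

    start_ids = np.array(sorted(_START_IDS))
    stop_ids = np.array(sorted(_STOP_IDS))
    start_positions = np.flatnonzero(np.isin(tri, start_ids) & (np.arange(n_codons) < leader_len))
    stop_positions = np.flatnonzero(np.isin(tri, stop_ids))

    # first in-frame stop per start, by frame
    stops_by_frame = {f: stop_positions[stop_positions % 3 == f] for f in range(3)}
    out: list[CandidateUORF] = []
    for s in start_positions:
        frame_stops = stops_by_frame[int(s) % 3]
        k = np.searchsorted(frame_stops, s + 3)
        if k == len(frame_stops):
            continue  # no in-frame stop downstream: N-terminal extension, not a uORF
        j = int(frame_stops[k])
        stop_pos = j + 2
        out.append(
            CandidateUORF(
                gene_id=gene_id,
                start_pos=int(s),
                stop_pos=stop_pos,
                start_codon=context[s : s + 3],
                length_nt=stop_pos - int(s) + 1,
                overlaps_morf=stop_pos >= leader_len,
            )
        )
    return out


def resolve_overlaps(scored_candidates):
    """Greedy resolution of overlapping/nested calls within each gene.

    ``scored_candidates`` is a sequence of ``(candidate, score)`` pairs.
    Candidates are taken in descending score order (ties: longer first,
    then more upstream); one is retained iff its [start, stop] interval
    does not overlap any already-retained candidate of the same gene.
    Returns the retained ``(candidate, score)`` pairs in input score order.
    """
    order = sorted(
        scored_candidates,
        key=lambda cs: (-cs[1], -cs[0].length_nt, cs[0].start_pos, cs[0].gene_id),
    )
    retained: list = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for cand, score in order:
        lo, hi = cand.start_pos, cand.stop_pos
        clash = any(lo <= e and s <= hi for s, e in occupied.get(cand.gene_id, ()))
        if not clash:
            retained.append((cand, score))
            occupied.setdefault(cand.gene_id, []).append((lo, hi))
    return retained
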