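"""Cross-species uORF homology classification.

Two modes of uORF conservation are recognised between homologous genes
of two species. A *sequence homolog*: the uORF's nucleotide sequence,
locally aligned into the other species' transcript leader under the
HOXD70 substitution matrix, lands on an interval overlapping a called
uORF there with a Jaccard index >= 0.6 (alignment Z-scores against a
mononucleotide-shuffle null break placement ties). A *positional
homolog*: start or stop codon distances from the main ORF agree within
5 nt. A pair satisfying both definitions is labelled sequence
(precedence rule), so every cross-species pair is sequence, position,
or unpaired -- never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_JACCARD = 0.6
DEFAULT_POSITION_TOL = 5
DEFAULT_SHUFFLES = 100

#: HOXD70 nucleotide substitution scores (Chiaromonte-Yap-Miller), the
#: matrix used by BLASTZ-style genomic alignment; gap open/extend follow
#: the same tradition.
HOXD70 = {
    ("A", "A"): 91, ("A", "C"): -114, ("A", "G"): -31, ("A", "T"): -123,
    ("C", "A"): -114, ("C", "C"): 100, ("C", "G"): -125, ("C", "T"): -31,
    ("G", "A"): -31, ("G", "C"): -125, ("G", "G"): 100, ("G", "T"): -114,
    ("T", "A"): -123, ("T", "C"): -31, ("T", "G"): -114, ("T", "T"): 91,
}
GAP_OPEN = -400.0
GAP_EXTEND = -30.0


@dataclass
class SubstitutionMatrix:
    """4x4 symmetric nucleotide scores plus affine gap penalties."""

    scores: dict = None
    gap_open: float = GAP_OPEN
    gap_extend: float = GAP_EXTEND

    def __post_init__(self) -> None:
        if self.scores is None:
            self.scores = dict(HOXD70)
        for (a, b), v in self.scores.items():
            if self.scores[(b, a)] != v:
                raise ValueError("substitution matrix must be symmetric")

    def to_biopython(self):
        alphabet = "ACGT"
        arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                arr[a, b] = self.scores[(a, b)]
        return arr


@dataclass
class HomologPair:
    """A cross-species link between two uORF calls of a homolog gene pair."""

    uorf_a: object
    uorf_b: object
    homology_class: str  # "sequence" | "position"
    jaccard: float = float("nan")
    alignment_score: float = float("nan")
    z_score: float | None = None


def _make_aligner(matrix: SubstitutionMatrix) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix.to_biopython()
    aligner.open_gap_score = matrix.gap_open
    aligner.extend_gap_score = matrix.gap_extend
    return aligner


def align_uorf_to_tl(uorf_seq: str, other_tl_seq: str,
                     matrix: SubstitutionMatrix | None = None,
                     n_shuffles: int = DEFAULT_SHUFFLES,
                     rng=None):
    """Locally align a uORF into a homologous transcript leader.

    Returns ``(alignment, mapped_interval, score, z_score)`` where
    ``mapped_interval`` is the half-open interval of leader positions
    covered by aligned uORF residues. The Z-score compares the score
    against ``n_shuffles`` mononucleotide shuffles of the uORF aligned
    to the same leader; it is None when the shuffle scores have zero
    spread. When several placements tie on score the aligner's first is
    reported; ties between *pairings* are broken on Z downstream.
    """
    if not uorf_seq or not other_tl_seq:
        raise ValueError("both sequences must be non-empty")
    matrix = matrix or SubstitutionMatrix()
    aligner = _make_aligner(matrix)
    rng = np.random.default_rng(rng)
    alignments = aligner.align(other_tl_seq, uorf_seq)
    score = float(alignments.score)
    best = alignments[0]
    target_blocks = best.aligned[0]
    mapped = (int(target_blocks[0][0]), int(target_blocks[-1][1]))

    z = None
    if n_shuffles > 0:
        letters = np.frombuffer(uorf_seq.encode(), dtype=np.uint8)
        null_scores = np.empty(n_shuffles)
        for i in range(n_shuffles):
            shuffled = rng.permutation(letters).tobytes().decode()
            null_scores[i] = aligner.score(other_tl_seq, shuffled)
        sd = null_scores.std()
        if sd > 0:
            z = float((score - null_scores.mean()) / sd)
    return best, mapped, score, z


def jaccard_index(interval_a, interval_b) -> float:
    """|intersection| / |union| of two half-open nucleotide intervals."""
    a0, a1 = interval_a
    b0, b1 = interval_b
    inter = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - inter
    if union <= 0:
        return 0.0
    return inter / union


def sequence_homologs(calls_a, calls_b, gene_pairs: dict,
                      tl_seqs_a: dict, tl_seqs_b: dict,
                      threshold: float = DEFAULT_JACCARD,
                      matrix: SubstitutionMatrix | None = None,
                      n_shuffles: int = DEFAULT_SHUFFLES,
                      rng=None) -> list[HomologPair]:
    """Pair uORF calls across species by aligned-interval overlap.

    ``gene_pairs`` maps gene ids of species A to homologous gene ids of
    species B; ``tl_seqs_*`` map gene id -> distal leader sequence. Each
    A call is aligned into its homolog's leader and paired with the best
    (max Jaccard, tie -> max Z, then most upstream) B call reaching the
    Jaccard threshold against the mapped interval.
    """
    rng = np.random.default_rng(rng)
    by_gene_b: dict[str, list] = {}
    for call in calls_b:
        by_gene_b.setdefault(call.gene_id, []).append(call)
    pairs = []
    for call in calls_a:
        gene_b = gene_pairs.get(call.gene_id)
        if gene_b is None or gene_b not in tl_seqs_b or not by_gene_b.get(gene_b):
            continue
        leader_a = tl_seqs_a[call.gene_id]
        uorf_seq = leader_a[call.start_pos : call.stop_pos + 1]
        if not uorf_seq:
            continue
        _, mapped, score, z = align_uorf_to_tl(
            uorf_seq, tl_seqs_b[gene_b], matrix, n_shuffles, rng
        )
        best = None
        for other in by_gene_b[gene_b]:
            jac = jaccard_index(mapped, other.interval)
            if jac >= threshold:
                key = (jac, z if z is not None else -np.inf, -other.start_pos)
                if best is None or key > best[0]:
                    best = (key, other, jac)
        if best is not None:
            pairs.append(
                HomologPair(call, best[1], "sequence", jaccard=best[2],
                            alignment_score=score, z_score=z)
            )
    return pairs


def position_homologs(calls_a, calls_b, gene_pairs: dict,
                      leader_lens_a: dict, leader_lens_b: dict,
                      tol_nt: int = DEFAULT_POSITION_TOL,
                      require_both: bool = False,
                      exclude=()) -> list[HomologPair]:
    """Pair uORF calls whose start/stop distances to the mORF agree.

    Distances are measured upstream of the main-ORF start (leader length
    minus transcript position). A pair qualifies when the start OR the
    stop distances agree within ``tol_nt`` (AND semantics via
    ``require_both``). uORFs in ``exclude`` (already sequence-classified)
    are skipped; each A call keeps its closest qualifying partner.
    """
    excluded = {c.uid for c in exclude}
    by_gene_b: dict[str, list] = {}
    for call in calls_b:
        by_gene_b.setdefault(call.gene_id, []).append(call)
    pairs = []
    for call in calls_a:
        if call.uid in excluded:
            continue
        gene_b = gene_pairs.get(call.gene_id)
        if gene_b is None or not by_gene_b.get(gene_b):
            continue
        la = leader_lens_a[call.gene_id]
        d_start_a = la - call.start_pos
        d_stop_a = la - call.stop_pos - 1
        best = None
        for other in by_gene_b[gene_b]:
            if other.uid in excluded:
                continue
            lb = leader_lens_b[other.gene_id]
            d_start = abs(d_start_a - (lb - other.start_pos))
            d_stop = abs(d_stop_a - (lb - other.stop_pos - 1))
            if require_both:
                ok = d_start <= tol_nt and d_stop <= tol_nt
            else:
                ok = d_start <= tol_nt or d_stop <= tol_nt
            if ok and (best is None or d_start + d_stop < best[0]):
                best = (d_start + d_stop, other)
        if best is not None:
            pairs.append(HomologPair(call, best[1], "position"))
    return pairs


def classify_homologs(calls_a, calls_b, gene_pairs: dict,
                      tl_seqs_a: dict, tl_seqs_b: dict,
                      jaccard_threshold: float = DEFAULT_JACCARD,
                      tol_nt: int = DEFAULT_POSITION_TOL,
                      require_both: bool = False,
                      matrix: SubstitutionMatrix | None = None,
                      n_shuffles: int = DEFAULT_SHUFFLES,
                      rng=None) -> list[HomologPair]:
    """Sequence homology first, positional homology on the remainder.

    uORFs already in a sequence pair are excluded from the positional
    pass, so the two classes partition the paired uORFs (sequence takes
    precedence when both definitions hold).
    """
    seq_pairs = sequence_homologs(
        calls_a, calls_b, gene_pairs, tl_seqs_a, tl_seqs_b,
        jaccard_threshold, matrix, n_shuffles, rng,
    )
    taken = [p.uorf_a for p in seq_pairs] + [p.uorf_b for p in seq_pairs]
    leader_lens_a = {g: len(s) for g, s in tl_seqs_a.items()}
    leader_lens_b = {g: len(s) for g, s in tl_seqs_b.items()}
    pos_pairs = position_homologs(
        calls_a, calls_b, gene_pairs, leader_lens_a, leader_lens_b,
        tol_nt, require_both, exclude=taken,
    )
    return seq_pairs + pos_pairs


def homolog_triplets(pairs_ab, pairs_bc, pairs_ac) -> list[set]:
    """uORFs linked across all three species.

    Builds a graph of pairwise homolog links over (species, uORF id)
    nodes; a triplet is a connected component spanning all three
    species. Returns the list of such components.
    """
    graph = nx.Graph()
    for species_pair, pairs in (("AB", pairs_ab), ("BC", pairs_bc), ("AC", pairs_ac)):
        sa, sb = species_pair
        for p in pairs:
            graph.add_edge((sa, p.uorf_a.uid), (sb, p.uorf_b.uid))
    triplets = []
    for component in nx.connected_components(graph):
        if {species for species, _ in component} == {"A", "B", "C"}:
            triplets.append(component)
    return triplets


def shared_fraction_by_start_type(calls_by_species: dict, pairs_by_species_pair: dict) -> dict:
    """Fraction of uORFs shared between >= 2 species, per start-codon class.

    Classes: AUG, UUG, and other NCC. A uORF counts as shared when it
    appears in any homolog pair. Returns class -> (n_shared, n_total,
    fraction).
    """
    shared_ids = set()
    for (sa, sb), pairs in pairs_by_species_pair.items():
        for p in pairs:
            shared_ids.add((sa, p.uorf_a.uid))
            shared_ids.add((sb, p.uorf_b.uid))

    def start_class(codon: str) -> str:
        if codon == "ATG":
            return "AUG"
        if codon == "TTG":
            return "UUG"
        return "other NCC"

    out = {}
    for cls in ("AUG", "UUG", "other NCC"):
        total = 0
        shared = 0
        for species, calls in calls_by_species.items():
            for c in calls:
                if start_class(c.start_codon) == cls:
                    total += 1
                    if (species, c.uid) in shared_ids:
                        shared += 1
        out[cls] = (shared, total, shared / total if total else float("nan"))
    return out
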