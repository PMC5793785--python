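"""Ribosome P-site assignment from footprint alignments.

Each ribosome footprint is reduced to one inferred P-site nucleotide:
the genomic 5' end of the footprint plus a read-length-specific offset
(strand-aware). Counts are accumulated per transcript, per replicate,
in distal-TSS transcript coordinates covering leader + main ORF.
Footprint lengths absent from the offset table are dropped and counted;
multi-mapped reads (NH > 1) are dropped outright -- uORFs are short, and
mapping ambiguity is toxic at that scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: default footprint-length -> P-site offset from the 5' end
DEFAULT_OFFSETS = {28: 12, 29: 13, 30: 13}


@dataclass
class OffsetTable:
    """Mapping read length -> P-site offset from the footprint 5' end."""

    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 10 <= off <= 15:
                raise ValueError(f"offset {off} for length {length} outside [10, 15]")

    def get(self, read_length: int):
        return self.offsets.get(read_length)


@dataclass
class PsiteTrack:
    """Per-gene, per-replicate P-site counts in transcript coordinates."""

    gene_id: str
    replicate_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("P-site counts must be non-negative")


def _transcript_trees(models):
    """IntervalTree per (chrom, strand) over each gene's leader+mORF span."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in models:
        if m.strand == "+":
            lo, hi = m.distal_tss, m.morf_stop + 1
        else:
            lo, hi = m.morf_stop, m.distal_tss + 1
        trees.setdefault((m.chrom, m.strand), IntervalTree()).addi(lo, hi, m)
    return trees


def assign_psites(alignments, offset_table: OffsetTable | dict, models,
                  replicate_id: str = "rep1") -> dict[str, PsiteTrack]:
    """Build P-site tracks for every model from a SAM/BAM of footprints.

    ``alignments`` is a path or an open :class:`pysam.AlignmentFile`.
    Every retained footprint contributes +1 at (genomic 5' end +
    offset), strand-aware; P-sites falling outside a transcript are
    ignored. Returns one all-zero track per gene when no read maps.
    """
    if isinstance(offset_table, dict):
        offset_table = OffsetTable(dict(offset_table))
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        close = True
    trees = _transcript_trees(models)
    tracks = {
        m.gene_id: PsiteTrack(m.gene_id, replicate_id, np.zeros(m.transcript_length, dtype=int))
        for m in models
    }
    n_dropped_len = 0
    n_multi = 0
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                n_multi += 1
                continue
            length = read.query_length or read.reference_length
            offset = offset_table.get(length)
            if offset is None:
                n_dropped_len += 1
                continue
            if read.is_reverse:
                strand = "-"
                psite = (read.reference_end - 1) - offset
            else:
                strand = "+"
                psite = read.reference_start + offset
            tree = trees.get((read.reference_name, strand))
            if tree is None:
                continue
            for hit in tree[psite]:
                model = hit.data
                t = model.to_transcript(psite)
                if 0 <= t < model.transcript_length:
                    tracks[model.gene_id].counts[t] += 1
    finally:
        if close:
            alignments.close()
    if n_dropped_len or n_multi:
        logger.info(
            "assign_psites[%s]: dropped %d reads with untabulated lengths, %d multi-mapped",
            replicate_id, n_dropped_len, n_multi,
        )
    return tracks


def rna_coverage(alignments, models) -> dict[str, np.ndarray]:
    """Full-read RNA-seq coverage per transcript (leader + mORF).

    Unlike footprints, RNA-seq reads contribute +1 over every aligned
    base; the result feeds abundance features and TE only.
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        close = True
    trees = _transcript_trees(models)
    cov = {m.gene_id: np.zeros(m.transcript_length, dtype=int) for m in models}
    by_id = {m.gene_id: m for m in models}
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            strand = "-" if read.is_reverse else "+"
            tree = trees.get((read.reference_name, strand))
            if tree is None:
                continue
            for block_start, block_end in read.get_blocks():
                for hit in tree[block_start:block_end]:
                    model = hit.data
                    arr = cov[model.gene_id]
                    for g in range(max(block_start, hit.begin), min(block_end, hit.end)):
                        t = model.to_transcript(g)
                        if 0 <= t < model.transcript_length:
                            arr[t] += 1
    finally:
        if close:
            alignments.close()
    return cov


def calibrate_offsets(alignments, models, lengths=(26, 27, 28, 29, 30, 31),
                      min_reads: int = 50) -> OffsetTable:
    """Estimate P-site offsets as the mode of (mORF start - read 5' end).

    For each footprint length, reads whose 5' end lies within 18 nt
    upstream of an annotated mORF start vote for offset = distance to
    the start codon; the per-length mode (restricted to [10, 15]) wins.
    Lengths with < ``min_reads`` votes fall back to the defaults.
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        close = True
    starts = {}
    for m in models:
        starts.setdefault((m.chrom, m.strand), []).append(m.morf_start)
    starts = {k: np.array(sorted(v)) for k, v in starts.items()}
    votes: dict[int, list[int]] = {length: [] for length in lengths}
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            length = read.query_length or read.reference_length
            if length not in votes:
                continue
            if read.is_reverse:
                five, strand = read.reference_end - 1, "-"
            else:
                five, strand = read.reference_start, "+"
            arr = starts.get((read.reference_name, strand))
            if arr is None:
                continue
            idx = np.searchsorted(arr, five)
            for j in (idx - 1, idx):
                if 0 <= j < arr.size:
                    dist = arr[j] - five if strand == "+" else five - arr[j]
                    if 10 <= dist <= 15:
                        votes[length].append(int(dist))
    finally:
        if close:
            alignments.close()
    table = dict(DEFAULT_OFFSETS)
    for length, vals in votes.items():
        if len(vals) >= min_reads:
            table[length] = int(np.bincount(vals).argmax())
    return OffsetTable(table)


def orf_frame_fraction(track, orf_interval) -> float | None:
    """Fraction of P-sites in frame 0 of an ORF.

    ``orf_interval`` is (start, stop) inclusive in the track's
    coordinates; the length must be a positive multiple of 3. Returns
    None when the ORF holds zero P-sites.
    """
    counts = track.counts if isinstance(track, PsiteTrack) else np.asarray(track)
    start, stop = orf_interval
    length = stop - start + 1
    if length < 3 or length % 3 != 0:
        raise ValueError("ORF length must be a positive multiple of 3")
    region = counts[start : stop + 1]
    total = region.sum()
    if total == 0:
        return None
    return float(region[0::3].sum() / total)
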