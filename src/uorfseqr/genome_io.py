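"""Genome, annotation, and interval I/O with a single coordinate contract.

All in-memory coordinates are 0-based; intervals are half-open
``[start, end)``; single-nucleotide sites (TSS, pA, codon positions) are
0-based positions of one nucleotide. GFF3 files are converted from/to
their native 1-based inclusive convention at the I/O boundary only; BED
and bedGraph are already 0-based half-open and pass through unchanged.

Transcript coordinates place position 0 at the most distal annotated TSS
and increase 5'->3' along the mRNA regardless of genomic strand. The
main-ORF start codon therefore begins at transcript position
``leader_length``.

Sequences are stored as DNA over {A, C, G, T, N}; RNA input (U) is
converted to T on read. Reports elsewhere print the RNA form (AUG, UUG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A lookup outside the bounds of a sequence or track."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSequence:
    """One chromosome/contig held as an upper-case DNA string."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for {self.chrom_name}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Return ``sequence[start:end]``; out-of-bounds access is an error."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise CoordinateError(
                f"slice [{start}, {end}) outside {self.chrom_name} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start:end]


@dataclass
class TranscriptModel:
    """A gene with its main ORF, leader isoforms, and 3' end.

    ``morf_start`` is the genomic position of the first nucleotide of the
    main-ORF start codon; ``morf_stop`` the genomic position of the last
    nucleotide of the stop codon. On the minus strand morf_start >
    morf_stop numerically. ``tl_isoforms`` / ``pa_sites`` are
    (position, usage_fraction) pairs whose fractions sum to 1 per end.
    """

    gene_id: str
    chrom: str
    strand: str
    morf_start: int
    morf_stop: int
    tl_isoforms: list[tuple[int, float]] = field(default_factory=list)
    pa_sites: list[tuple[int, float]] = field(default_factory=list)
    utr3_interval: GenomicInterval | None = None

    # -- derived geometry -------------------------------------------------
    @property
    def distal_tss(self) -> int:
        """Most upstream (strand-aware) TSS."""
        positions = [p for p, _ in self.tl_isoforms]
        return min(positions) if self.strand == "+" else max(positions)

    def leader_length_of(self, tss: int) -> int:
        """Leader length of the isoform starting at ``tss``."""
        if self.strand == "+":
            return self.morf_start - tss
        return tss - self.morf_start

    @property
    def leader_length(self) -> int:
        return self.leader_length_of(self.distal_tss)

    @property
    def morf_length(self) -> int:
        return abs(self.morf_stop - self.morf_start) + 1

    @property
    def transcript_length(self) -> int:
        """Leader + main ORF (the span P-site tracks cover)."""
        return self.leader_length + self.morf_length

    def to_transcript(self, genomic_pos: int) -> int:
        """Map a genomic position into distal-TSS transcript coordinates."""
        if self.strand == "+":
            return genomic_pos - self.distal_tss
        return self.distal_tss - genomic_pos

    def to_genomic(self, transcript_pos: int) -> int:
        if self.strand == "+":
            return self.distal_tss + transcript_pos
        return self.distal_tss - transcript_pos

    def tss_offsets(self) -> list[tuple[int, float]]:
        """(transcript offset of each TSS, usage fraction)."""
        return [(self.to_transcript(p), f) for p, f in self.tl_isoforms]

    def validate(self) -> None:
        for name, pairs in (("tl_isoforms", self.tl_isoforms), ("pa_sites", self.pa_sites)):
            if pairs:
                total = sum(f for _, f in pairs)
                if not all(0.0 <= f <= 1.0 for _, f in pairs) or abs(total - 1.0) > 1e-6:
                    raise ValueError(f"{self.gene_id}: {name} fractions must sum to 1")
        for tss, _ in self.tl_isoforms:
            if self.leader_length_of(tss) < 0:
                raise ValueError(f"{self.gene_id}: TSS {tss} not upstream of mORF start")
        for pa, _ in self.pa_sites:
            down = pa - self.morf_stop if self.strand == "+" else self.morf_stop - pa
            if down < 0:
                raise ValueError(f"{self.gene_id}: pA {pa} not downstream of mORF stop")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(fasta_path) -> dict[str, GenomeSequence]:
    """Load a genome FASTA into a chrom -> :class:`GenomeSequence` mapping.

    Bases are upper-cased and U is converted to T.
    """
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {record.id!r} has an empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {record.id!r} has non-nucleotide characters {bad}")
        genome[record.id] = GenomeSequence(record.id, seq)
    if not genome:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return genome


def write_genome(genome: dict[str, GenomeSequence], fasta_path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name].sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 + BED transcript models
# ---------------------------------------------------------------------------

def _read_site_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return df


def read_transcript_models(gff3_path, tl_bed_path, pa_bed_path) -> list[TranscriptModel]:
    """Assemble transcript models from a GFF3 plus TSS and pA cluster BEDs.

    The BED ``name`` column carries the gene id and the ``score`` column a
    usage count; usage fractions are renormalised to sum to 1 per gene and
    per end. Genes lacking a usable TSS or pA are excluded (logged), as
    are genes whose CDS is split by introns (simple gene structure is
    assumed; splicing-aware leaders are out of scope). TSS records that
    are not strand-aware upstream of the mORF start are rejected with a
    warning.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    tss_df = _read_site_bed(tl_bed_path)
    pa_df = _read_site_bed(pa_bed_path)
    tss_by_gene = dict(tuple(tss_df.groupby("name", sort=False)))
    pa_by_gene = dict(tuple(pa_df.groupby("name", sort=False)))

    models: list[TranscriptModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        gid = gene.id
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS; skipped", gid)
            n_skipped += 1
            continue
        if len(cds) > 1:
            logger.warning("gene %s has a multi-segment CDS (intron); excluded", gid)
            n_skipped += 1
            continue
        seg = cds[0]
        strand = seg.strand
        start0, end0 = seg.start - 1, seg.end  # to 0-based half-open
        if strand == "+":
            morf_start, morf_stop = start0, end0 - 1
        else:
            morf_start, morf_stop = end0 - 1, start0

        model = TranscriptModel(gid, gene.seqid, strand, morf_start, morf_stop)

        tss_rows = tss_by_gene.get(gid)
        if tss_rows is not None:
            for _, row in tss_rows.iterrows():
                pos = int(row.start)
                if model.leader_length_of(pos) <= 0:
                    logger.warning(
                        "gene %s: TSS %d not upstream of mORF start; record rejected",
                        gid, pos,
                    )
                    continue
                model.tl_isoforms.append((pos, float(row.score)))
        pa_rows = pa_by_gene.get(gid)
        if pa_rows is not None:
            for _, row in pa_rows.iterrows():
                pos = int(row.start)
                down = pos - morf_stop if strand == "+" else morf_stop - pos
                if down <= 0:
                    logger.warning("gene %s: pA %d not downstream of mORF stop; rejected", gid, pos)
                    continue
                model.pa_sites.append((pos, float(row.score)))

        if not model.tl_isoforms:
            logger.warning("gene %s has no TSS record; excluded", gid)
            n_skipped += 1
            continue
        if not model.pa_sites:
            logger.warning("gene %s has no pA record; excluded", gid)
            n_skipped += 1
            continue

        for attr in ("tl_isoforms", "pa_sites"):
            pairs = getattr(model, attr)
            total = sum(c for _, c in pairs)
            setattr(model, attr, [(p, c / total) for p, c in pairs])

        # 3' UTR: stop codon end to the most distal pA
        pa_positions = [p for p, _ in model.pa_sites]
        if strand == "+":
            distal_pa = max(pa_positions)
            model.utr3_interval = GenomicInterval(gene.seqid, strand, morf_stop + 1, distal_pa + 1)
        else:
            distal_pa = min(pa_positions)
            model.utr3_interval = GenomicInterval(gene.seqid, strand, distal_pa, morf_stop)
        model.validate()
        models.append(model)
    if n_skipped:
        logger.info("read_transcript_models: %d genes excluded", n_skipped)
    return models


def write_transcript_models(models, gff3_path, tl_bed_path, pa_bed_path) -> None:
    """Write models as GFF3 (gene + CDS) and TSS/pA BED6 files.

    Round-trips exactly with :func:`read_transcript_models` (coordinates
    exact; usage fractions re-normalised on read).
    """
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(m.morf_start, m.morf_stop)
            hi = max(m.morf_start, m.morf_stop)
            ends = [p for p, _ in m.tl_isoforms] + [p for p, _ in m.pa_sites]
            span_lo = min([lo] + ends)
            span_hi = max([hi] + ends)
            fh.write(
                f"{m.chrom}\tuorfseqr\tgene\t{span_lo + 1}\t{span_hi + 1}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tuorfseqr\tCDS\t{lo + 1}\t{hi + 1}\t.\t{m.strand}\t0\t"
                f"ID={m.gene_id}.cds;Parent={m.gene_id}\n"
            )
    with open(tl_bed_path, "w") as fh:
        for m in models:
            for pos, frac in m.tl_isoforms:
                fh.write(f"{m.chrom}\t{pos}\t{pos + 1}\t{m.gene_id}\t{frac:.9g}\t{m.strand}\n")
    with open(pa_bed_path, "w") as fh:
        for m in models:
            for pos, frac in m.pa_sites:
                fh.write(f"{m.chrom}\t{pos}\t{pos + 1}\t{m.gene_id}\t{frac:.9g}\t{m.strand}\n")


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def tl_sequence(model: TranscriptModel, genome: dict[str, GenomeSequence],
                tss_choice="distal") -> str:
    """Transcript-leader sequence (5'->3') from a chosen TSS to the mORF start.

    ``tss_choice`` is a genomic TSS position from the model or ``"distal"``
    for the most upstream isoform. An empty leader returns "".
    """
    if tss_choice == "distal":
        tss = model.distal_tss
    else:
        tss = int(tss_choice)
        if tss not in {p for p, _ in model.tl_isoforms}:
            raise ValueError(f"{model.gene_id}: {tss} is not an annotated TSS")
    chrom = genome[model.chrom]
    if model.strand == "+":
        return chrom.slice(tss, model.morf_start)
    return revcomp(chrom.slice(model.morf_start + 1, tss + 1))


def morf_sequence(model: TranscriptModel, genome: dict[str, GenomeSequence]) -> str:
    chrom = genome[model.chrom]
    if model.strand == "+":
        return chrom.slice(model.morf_start, model.morf_stop + 1)
    return revcomp(chrom.slice(model.morf_stop, model.morf_start + 1))


def utr3_sequence(model: TranscriptModel, genome: dict[str, GenomeSequence]) -> str:
    iv = model.utr3_interval
    if iv is None:
        return ""
    chrom = genome[model.chrom]
    raw = chrom.slice(iv.start, iv.end)
    return raw if model.strand == "+" else revcomp(raw)
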