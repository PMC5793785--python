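"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data regime the pipeline is built for:

* a compact yeast-like genome of single-exon genes on both strands,
  with lognormal transcript-leader lengths (median ~50 nt), 1-3 TSS
  clusters per gene with Dirichlet usage, and 1-2 pA sites;
* end-seq pileups: sparse, very high read-end spikes at the true
  TSS/pA positions (+-2 nt jitter) over a low Poisson background;
* replicate Ribo-seq P-site tracks with 3-nt periodicity over main
  ORFs and planted uORFs, start-codon-strength differences
  (AUG > UUG > other near-cognates), uniform leader noise, and
  independent Poisson replicate-to-replicate variation, plus an
  RNA-seq coverage track;
* one to three homologous "species": later species are derived from
  the first by point mutation at a configured divergence rate while
  preserving the start/stop codons of uORFs flagged as shared (and the
  reading-frame integrity of their bodies); private uORFs are knocked
  out in the other species with the non-initiating AGG codon.

Every planted uORF satisfies the candidate invariants, so it is
guaranteed to appear in ``enumerate_candidates`` output of its own
leader. Identical config + seed reproduces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .candidates import STOP_CODONS, enumerate_candidates
from .end_seq import EndPileup
from .genome_io import (GenomeSequence, GenomicInterval, TranscriptModel,
                        morf_sequence, revcomp, tl_sequence)
from .regression import GeneData

BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)

SPECIES_NAMES = ("A", "B", "C")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic transcriptome and profiling experiment.

    Defaults describe the regime the pipeline targets: ~50-nt median
    leaders, half the genes carrying one translated uORF at 5x the
    leader noise density with 0.9 in-frame fraction, three Ribo-seq
    replicates, and AUG-initiated uORFs denser than UUG than other
    near-cognates.
    """

    seed: int
    n_genes: int = 50
    n_species: int = 1

    # transcript geometry
    leader_median_nt: float = 50.0
    leader_sigma: float = 0.45
    leader_min_nt: int = 24
    leader_max_nt: int = 300
    morf_codons: tuple[int, int] = (100, 200)
    utr3_nt: tuple[int, int] = (60, 120)
    max_tss_clusters: int = 3
    tss_usage_alpha: float = 2.0
    max_pa_sites: int = 2

    # planted uORFs
    planted_fraction: float = 0.5
    uorf_codons: tuple[int, int] = (5, 12)  # total codons including the stop
    start_codon_mix: dict = field(
        default_factory=lambda: {
            "ATG": 0.35, "TTG": 0.35, "CTG": 0.06, "GTG": 0.06,
            "ACG": 0.06, "ATA": 0.04, "ATT": 0.04, "ATC": 0.04,
        }
    )
    density_multiplier: float = 5.0  # uORF P-site density over leader noise
    codon_factors: dict = field(
        default_factory=lambda: {"ATG": 1.0, "TTG": 0.8, "other": 0.6}
    )
    shared_fraction: float = 0.8  # of planted uORFs kept across species

    # profiling
    n_replicates: int = 3
    periodicity: float = 0.9          # in-frame fraction of translated regions
    leader_noise_rate: float = 0.5    # P-sites per nt per replicate
    morf_density: float = 2.0         # P-sites per nt per replicate
    start_boost: float = 2.0          # extra weight on the first uORF codon
    gene_rate_sigma: float = 0.3      # lognormal gene-to-gene expression spread
    rna_rate: float = 5.0             # RNA coverage per nt (single pooled track)

    # end-seq
    end_depth: int = 1000             # reads per gene per end assay
    end_background: float = 0.02      # background read-ends per nt
    divergence: float = 0.1           # per-nt mutation rate between species

    def codon_factor(self, codon: str) -> float:
        return self.codon_factors.get(codon, self.codon_factors["other"])


@dataclass
class SpeciesSim:
    name: str
    genome: dict[str, GenomeSequence]
    models: list[TranscriptModel]


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _lognormal_leader(rng, cfg: SimulationConfig) -> int:
    raw = np.exp(rng.normal(np.log(cfg.leader_median_nt), cfg.leader_sigma))
    return int(np.clip(round(raw), cfg.leader_min_nt, cfg.leader_max_nt))


def _sample_codon(rng, mix: dict) -> str:
    codons = sorted(mix)
    probs = np.array([mix[c] for c in codons], dtype=float)
    return codons[rng.choice(len(codons), p=probs / probs.sum())]


def generate_transcriptome(config: SimulationConfig):
    """Build the genomes, transcript models, and planted-uORF truth table.

    Returns ``(species, truth)`` where ``species`` maps species name to
    :class:`SpeciesSim` and ``truth`` is a DataFrame with one row per
    (species, planted uORF): gene, transcript coordinates, start codon,
    density multiplier, and the shared flag.
    """
    rng = np.random.default_rng(config.seed)
    pad = 100
    gap = 100
    chrom_name = "chr1"

    blocks: list[str] = []  # transcript-oriented gene blocks
    layouts = []            # (offset, block_len, strand, L, morf_len, utr3_len)
    planted = []            # per-gene planted dict or None
    offset = gap
    for gi in range(config.n_genes):
        L = _lognormal_leader(rng, config)
        n_codons = int(rng.integers(config.morf_codons[0], config.morf_codons[1] + 1))
        utr3_len = int(rng.integers(config.utr3_nt[0], config.utr3_nt[1] + 1))
        leader = list(_random_seq(rng, L))

        plant = None
        min_codons, max_codons = config.uorf_codons
        if rng.random() < config.planted_fraction and L >= 3 * min_codons + 4:
            u_c = int(rng.integers(min_codons, max_codons + 1))
            u_c = min(u_c, (L - 4) // 3)
            s = int(rng.integers(2, L - 3 * u_c - 1))
            codon = _sample_codon(rng, config.start_codon_mix)
            body = [
                _NONSTOP_CODONS[i]
                for i in rng.integers(0, len(_NONSTOP_CODONS), u_c - 2)
            ]
            stop = STOP_CODONS[rng.integers(0, 3)]
            uorf_seq = codon + "".join(body) + stop
            leader[s : s + 3 * u_c] = list(uorf_seq)
            shared = bool(rng.random() < config.shared_fraction) if config.n_species > 1 else False
            plant = {
                "start_pos": s,
                "stop_pos": s + 3 * u_c - 1,
                "codon": codon,
                "shared": shared,
            }

        morf = "ATG" + "".join(
            _NONSTOP_CODONS[i]
            for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
        ) + "TAA"
        utr3 = _random_seq(rng, utr3_len)
        block = pad * "T" + "".join(leader) + morf + utr3 + pad * "T"
        # pads are poly-T so they cannot extend uORFs with spurious starts
        block = _pad_shuffle(rng, block, pad)
        strand = "+" if gi % 2 == 0 else "-"
        blocks.append(block)
        layouts.append((offset, len(block), strand, L, len(morf), utr3_len))
        planted.append(plant)
        offset += len(block) + gap

    chrom_len = offset
    base_seq = list(_random_seq(rng, chrom_len))
    for (off, blen, strand, *_), block in zip(layouts, blocks):
        inserted = block if strand == "+" else revcomp(block)
        base_seq[off : off + blen] = list(inserted)
    seq_a = "".join(base_seq)

    models_a = []
    for gi, (off, blen, strand, L, morf_len, utr3_len) in enumerate(layouts):
        gid = f"gene{gi:04d}"

        def g(block_pos: int) -> int:
            # transcript-oriented block position -> genomic position
            return off + block_pos if strand == "+" else off + blen - 1 - block_pos

        pad = (blen - L - morf_len - utr3_len) // 2
        tss_positions = [g(pad)]
        n_tss = int(rng.integers(1, config.max_tss_clusters + 1))
        if n_tss > 1 and L > 20:
            extra = rng.choice(np.arange(8, L - 8), size=min(n_tss - 1, L - 16),
                               replace=False)
            tss_positions += [g(pad + int(e)) for e in sorted(extra)]
        usage = rng.dirichlet(np.full(len(tss_positions), config.tss_usage_alpha))
        # the distal TSS keeps the largest usage share so the distal
        # leader is the dominant isoform, as in real TL-seq data
        usage = np.sort(usage)[::-1]
        tl_isoforms = list(zip(tss_positions, usage.tolist()))

        morf_start = g(pad + L)
        morf_stop = g(pad + L + morf_len - 1)
        n_pa = int(rng.integers(1, config.max_pa_sites + 1))
        pa_block = [pad + L + morf_len + utr3_len - 1]
        if n_pa > 1 and utr3_len > 20:
            pa_block.append(pad + L + morf_len + int(rng.integers(8, utr3_len - 8)))
        pa_usage = rng.dirichlet(np.full(len(pa_block), config.tss_usage_alpha))
        pa_sites = [(g(p), u) for p, u in zip(pa_block, pa_usage.tolist())]

        model = TranscriptModel(
            gene_id=gid, chrom=chrom_name, strand=strand,
            morf_start=morf_start, morf_stop=morf_stop,
            tl_isoforms=tl_isoforms, pa_sites=pa_sites,
        )
        pa_positions = [p for p, _ in pa_sites]
        if strand == "+":
            model.utr3_interval = GenomicInterval(
                chrom_name, strand, morf_stop + 1, max(pa_positions) + 1
            )
        else:
            model.utr3_interval = GenomicInterval(
                chrom_name, strand, min(pa_positions), morf_stop
            )
        model.validate()
        models_a.append(model)

    species = {"A": SpeciesSim("A", {chrom_name: GenomeSequence(chrom_name, seq_a)}, models_a)}
    truth_rows = []
    for gi, plant in enumerate(planted):
        if plant is None:
            continue
        cfg_mult = config.density_multiplier * config.codon_factor(plant["codon"])
        truth_rows.append(
            {"species": "A", "gene_id": models_a[gi].gene_id, **plant, "multiplier": cfg_mult}
        )

    for si in range(1, config.n_species):
        name = SPECIES_NAMES[si]
        seq_b, models_b = _derive_species(rng, config, seq_a, models_a, planted, chrom_name)
        species[name] = SpeciesSim(name, {chrom_name: GenomeSequence(chrom_name, seq_b)}, models_b)
        for gi, plant in enumerate(planted):
            if plant is None or not plant["shared"]:
                continue
            cfg_mult = config.density_multiplier * config.codon_factor(plant["codon"])
            truth_rows.append(
                {"species": name, "gene_id": models_b[gi].gene_id, **plant,
                 "multiplier": cfg_mult}
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "gene_id", "start_pos", "stop_pos", "codon", "shared",
                 "multiplier"],
    )
    return species, truth


def _pad_shuffle(rng, block: str, pad: int) -> str:
    """Replace poly-T pads with random sequence free of start codons."""
    safe = "".join("CT"[i] for i in rng.integers(0, 2, pad))
    safe2 = "".join("CT"[i] for i in rng.integers(0, 2, pad))
    return safe + block[pad:-pad] + safe2


def _derive_species(rng, config, seq_a: str, models_a, planted, chrom_name):
    """Point-mutate species A into a diverged sibling.

    Protected from mutation: every mORF start/stop codon, and the
    start/stop codons of shared planted uORFs. Private planted uORFs
    are knocked out with the non-initiating AGG codon. After mutation,
    any stop codon created inside a shared uORF body is reverted so the
    planted stop stays the first in-frame stop.
    """
    seq = np.frombuffer(seq_a.encode(), dtype=np.uint8).copy()
    protected = np.zeros(seq.size, dtype=bool)

    def protect_codon(model, t0):
        for t in range(t0, t0 + 3):
            protected[model.to_genomic(t)] = True

    for gi, model in enumerate(models_a):
        L = model.leader_length
        protect_codon(model, L)                       # mORF start
        protect_codon(model, L + model.morf_length - 3)  # mORF stop
        plant = planted[gi]
        if plant is not None and plant["shared"]:
            protect_codon(model, plant["start_pos"])
            protect_codon(model, plant["stop_pos"] - 2)

    mutate = (rng.random(seq.size) < config.divergence) & ~protected
    idx = np.flatnonzero(mutate)
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)  # byte values already sorted
    shifts = rng.integers(1, 4, idx.size)
    cur_idx = np.searchsorted(codes, seq[idx])
    seq[idx] = codes[(cur_idx + shifts) % 4]

    def write_transcript_codon(model, t0, codon: str):
        for j, b in enumerate(codon):
            gpos = model.to_genomic(t0 + j)
            out = b if model.strand == "+" else revcomp(b)
            seq[gpos] = ord(out)

    seq_a_bytes = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    for gi, model in enumerate(models_a):
        plant = planted[gi]
        if plant is None:
            continue
        if not plant["shared"]:
            write_transcript_codon(model, plant["start_pos"], "AGG")
            continue
        # repair stop codons mutated into existence inside the body
        for t0 in range(plant["start_pos"] + 3, plant["stop_pos"] - 2, 3):
            gpos = [model.to_genomic(t0 + j) for j in range(3)]
            codon = "".join(chr(seq[p]) for p in gpos)
            if model.strand == "-":
                codon = revcomp(codon)
            if codon in STOP_CODONS:
                for p in gpos:
                    seq[p] = seq_a_bytes[p]

    models_b = [
        replace(m, tl_isoforms=list(m.tl_isoforms), pa_sites=list(m.pa_sites))
        for m in models_a
    ]  # same coordinates: point mutations only, no indels
    return seq.tobytes().decode(), models_b


# ---------------------------------------------------------------------------
# End-seq simulation
# ---------------------------------------------------------------------------

_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_JITTER_PROBS = np.array([0.1, 0.2, 0.4, 0.2, 0.1])


def simulate_end_seq(species: SpeciesSim, depth: int = 1000, seed=0,
                     background: float = 0.02):
    """Simulate TL-seq (5') and pA-seq (3') read-end pileups.

    Read ends = genome-wide Poisson(background) noise plus, per gene,
    a Multinomial(depth x usage) draw over its true sites with +-2 nt
    jitter. Returns ``(five_prime, three_prime)`` mappings
    (chrom, strand) -> :class:`EndPileup`.
    """
    rng = np.random.default_rng(seed)
    chrom_lens = {name: len(g) for name, g in species.genome.items()}
    five = {}
    three = {}
    for chrom, n in sorted(chrom_lens.items()):
        for strand in "+-":
            five[(chrom, strand)] = EndPileup(chrom, strand, rng.poisson(background, n))
            three[(chrom, strand)] = EndPileup(chrom, strand, rng.poisson(background, n))

    def scatter(pileup, positions, usage):
        reads = rng.multinomial(depth, usage)
        for pos, k in zip(positions, reads):
            if k == 0:
                continue
            jit = rng.multinomial(k, _JITTER_PROBS)
            for o, kk in zip(_JITTER_OFFSETS, jit):
                tgt = pos + o
                if 0 <= tgt < pileup.counts.size:
                    pileup.counts[tgt] += kk

    for model in species.models:
        key = (model.chrom, model.strand)
        tss = [p for p, _ in model.tl_isoforms]
        scatter(five[key], tss, [f for _, f in model.tl_isoforms])
        pas = [p for p, _ in model.pa_sites]
        scatter(three[key], pas, [f for _, f in model.pa_sites])
    return five, three


# ---------------------------------------------------------------------------
# Ribo-seq / RNA-seq simulation
# ---------------------------------------------------------------------------

def _periodic_profile(length: int, per_nt: float, inframe: float) -> np.ndarray:
    """Per-position Poisson means with 3-nt periodicity.

    Average density is ``per_nt``; a fraction ``inframe`` of the mass
    sits on frame-0 positions.
    """
    prof = np.empty(length)
    per_codon = 3.0 * per_nt
    prof[0::3] = per_codon * inframe
    prof[1::3] = per_codon * (1.0 - inframe) / 2.0
    prof[2::3] = per_codon * (1.0 - inframe) / 2.0
    return prof


def simulate_profiling(species: SpeciesSim, truth: pd.DataFrame,
                       config: SimulationConfig, seed=0):
    """Replicate P-site tracks and an RNA coverage track per gene.

    Main ORFs receive periodic P-sites at gene-specific (lognormal)
    rates; leaders receive uniform noise; planted uORFs add
    multiplier x noise-density periodic occupancy with a boosted first
    codon. Replicates are independent Poisson draws around the shared
    per-gene mean profile.
    """
    rng = np.random.default_rng(seed)
    rows = truth[truth["species"] == species.name] if len(truth) else truth
    planted_by_gene: dict[str, list] = {}
    if len(rows):
        for _, row in rows.iterrows():
            planted_by_gene.setdefault(row["gene_id"], []).append(row)

    tracks: dict[str, dict[str, np.ndarray]] = {}
    rna: dict[str, np.ndarray] = {}
    for model in species.models:
        L = model.leader_length
        T = model.transcript_length
        gene_factor = float(np.exp(rng.normal(0.0, config.gene_rate_sigma)))
        mean = np.zeros(T)
        mean[:L] = config.leader_noise_rate
        mean[L:] = _periodic_profile(T - L, config.morf_density * gene_factor,
                                     config.periodicity)
        for row in planted_by_gene.get(model.gene_id, ()):
            s, e = int(row["start_pos"]), int(row["stop_pos"])
            per_nt = float(row["multiplier"]) * config.leader_noise_rate
            prof = _periodic_profile(e - s + 1, per_nt, config.periodicity)
            prof[0:3] *= config.start_boost
            # translated uORFs replace (not add to) the leader noise, so
            # their density is exactly multiplier x the leader background
            mean[s : e + 1] = prof
        reps = {}
        for r in range(config.n_replicates):
            reps[f"rep{r + 1}"] = rng.poisson(mean)
        tracks[model.gene_id] = reps
        rna[model.gene_id] = rng.poisson(config.rna_rate * gene_factor, T)
    return tracks, rna


# ---------------------------------------------------------------------------
# Bundling for the caller
# ---------------------------------------------------------------------------

def build_gene_data(species: SpeciesSim, tracks, rna) -> dict[str, GeneData]:
    """Enumerate candidates per gene and package tracks for calling."""
    genes: dict[str, GeneData] = {}
    for model in species.models:
        leader = tl_sequence(model, species.genome)
        context = leader + morf_sequence(model, species.genome)
        cands = enumerate_candidates(leader, context, gene_id=model.gene_id)
        genes[model.gene_id] = GeneData(
            gene_id=model.gene_id,
            leader_len=model.leader_length,
            candidates=cands,
            psite_tracks=tracks[model.gene_id],
            rna=rna[model.gene_id],
        )
    return genes


def simulate_experiment(config: SimulationConfig):
    """One-call convenience: transcriptomes, profiling, and GeneData.

    Returns ``(species, truth, gene_data)`` where ``gene_data`` maps
    species name -> {gene_id -> GeneData}. Seeds for profiling are
    derived deterministically from ``config.seed`` per species.
    """
    species, truth = generate_transcriptome(config)
    gene_data = {}
    for si, name in enumerate(sorted(species)):
        sp = species[name]
        tracks, rna = simulate_profiling(sp, truth, config,
                                         seed=config.seed + 10_000 * (si + 1))
        gene_data[name] = build_gene_data(sp, tracks, rna)
    return species, truth, gene_data
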