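import numpy as np
import pytest

from uorfseqr.genome_io import (
    CoordinateError,
    GenomicInterval,
    read_genome,
    read_transcript_models,
    revcomp,
    tl_sequence,
    write_genome,
    write_transcript_models,
)


def test_read_genome_identity_and_normalization(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\nACGTACGT\n>chr2\nacgtnn\nuuu\n")
    genome = read_genome(fa)
    assert set(genome) == {"chr1", "chr2"}
    assert len(genome["chr1"]) == 8
    assert genome["chr2"].sequence == "ACGTNNTTT"  # upper-cased, U -> T


def test_read_genome_empty_file_errors(tmp_path):
    fa = tmp_path / "empty.fa"
    fa.write_text("")
    with pytest.raises(ValueError):
        read_genome(fa)


def test_read_genome_bad_characters_error(tmp_path):
    fa = tmp_path / "bad.fa"
    fa.write_text(">chr1\nACGTXX\n")
    with pytest.raises(ValueError, match="chr1"):
        read_genome(fa)


def test_sequence_slice_bounds(toy_genome):
    chrom = toy_genome["chr1"]
    assert len(chrom.slice(0, 10)) == 10
    with pytest.raises(CoordinateError):
        chrom.slice(290, 310)


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", "+", 10, 10)
    assert len(GenomicInterval("chr1", "-", 5, 9)) == 4


def _write_fixture(tmp_path, tss_scores=(3.0, 1.0)):
    gff = tmp_path / "m.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t50\t200\t.\t+\t.\tID=gA\n"
        "chr1\tsrc\tCDS\t131\t160\t.\t+\t0\tID=gA.c;Parent=gA\n"
        "chr1\tsrc\tgene\t50\t220\t.\t-\t.\tID=gB\n"
        "chr1\tsrc\tCDS\t101\t130\t.\t-\t0\tID=gB.c;Parent=gB\n"
        "chr1\tsrc\tgene\t250\t300\t.\t+\t.\tID=gNoTss\n"
        "chr1\tsrc\tCDS\t261\t290\t.\t+\t0\tID=gN.c;Parent=gNoTss\n"
    )
    tl = tmp_path / "tss.bed"
    tl.write_text(
        f"chr1\t100\t101\tgA\t{tss_scores[0]}\t+\n"
        f"chr1\t110\t111\tgA\t{tss_scores[1]}\t+\n"
        "chr1\t170\t171\tgB\t5\t-\n"   # minus strand: TSS numerically above mORF start
        "chr1\t90\t91\tgB\t1\t-\n"     # not upstream on -, must be rejected
    )
    pa = tmp_path / "pa.bed"
    pa.write_text(
        "chr1\t190\t191\tgA\t4\t+\n"
        "chr1\t80\t81\tgB\t2\t-\n"
        "chr1\t295\t296\tgNoTss\t2\t+\n"
    )
    return gff, tl, pa


def test_read_transcript_models_usage_and_strand_rules(tmp_path):
    gff, tl, pa = _write_fixture(tmp_path)
    models = {m.gene_id: m for m in read_transcript_models(gff, tl, pa)}
    # gene without TSS excluded
    assert set(models) == {"gA", "gB"}
    # usage counts 3,1 -> fractions 0.75 / 0.25
    assert [f for _, f in models["gA"].tl_isoforms] == pytest.approx([0.75, 0.25])
    # minus strand: TSS at coordinate > morf_start accepted, the other rejected
    assert [p for p, _ in models["gB"].tl_isoforms] == [170]
    assert models["gB"].strand == "-"
    assert models["gB"].morf_start == 129  # last base of CDS on minus strand
    assert models["gB"].leader_length == 170 - 129


def test_model_round_trip(tmp_path):
    gff, tl, pa = _write_fixture(tmp_path)
    models = read_transcript_models(gff, tl, pa)
    out = tmp_path / "rt"
    out.mkdir()
    write_transcript_models(models, out / "m.gff3", out / "tss.bed", out / "pa.bed")
    back = read_transcript_models(out / "m.gff3", out / "tss.bed", out / "pa.bed")
    assert len(back) == len(models)
    for a, b in zip(sorted(models, key=lambda m: m.gene_id),
                    sorted(back, key=lambda m: m.gene_id)):
        assert (a.gene_id, a.chrom, a.strand) == (b.gene_id, b.chrom, b.strand)
        assert (a.morf_start, a.morf_stop) == (b.morf_start, b.morf_stop)
        assert [p for p, _ in a.tl_isoforms] == [p for p, _ in b.tl_isoforms]
        assert [p for p, _ in a.pa_sites] == [p for p, _ in b.pa_sites]
        for (_, fa), (_, fb) in zip(a.tl_isoforms, b.tl_isoforms):
            assert fa == pytest.approx(fb)


def test_tl_sequence_plus_minus_and_distal(toy_genome, plus_model, minus_model):
    chrom = toy_genome["chr1"].sequence
    leader_plus = tl_sequence(plus_model, toy_genome)
    assert leader_plus == chrom[100:130]
    assert len(leader_plus) == plus_model.leader_length
    # strand symmetry: the minus leader is the reverse complement of its slice
    leader_minus = tl_sequence(minus_model, toy_genome)
    assert leader_minus == revcomp(chrom[170:200])
    assert len(leader_minus) == minus_model.leader_length
    # explicit proximal TSS choice
    assert tl_sequence(plus_model, toy_genome, 110) == chrom[110:130]
    with pytest.raises(ValueError):
        tl_sequence(plus_model, toy_genome, 105)


def test_tl_sequence_empty_leader(toy_genome, plus_model):
    plus_model.tl_isoforms = [(130, 1.0)]
    assert tl_sequence(plus_model, toy_genome) == ""


def test_tl_sequence_length_matches_model_on_simulation(small_experiment):
    from uorfseqr.genome_io import tl_sequence as tls

    _, species, _, _ = small_experiment
    sp = species["A"]
    for model in sp.models:
        assert len(tls(model, sp.genome)) == model.leader_length


def test_genome_write_read_round_trip(tmp_path, toy_genome):
    fa = tmp_path / "out.fa"
    write_genome(toy_genome, fa)
    back = read_genome(fa)
    assert back["chr1"].sequence == toy_genome["chr1"].sequence
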