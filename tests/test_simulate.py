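"""Synthetic-data generator: determinism, planted truth, noise models."""

import numpy as np
import pytest

from uorfseqr.candidates import enumerate_candidates
from uorfseqr.genome_io import morf_sequence, tl_sequence
from uorfseqr.psite import orf_frame_fraction
from uorfseqr.simulate import (
    SimulationConfig,
    build_gene_data,
    generate_transcriptome,
    simulate_end_seq,
    simulate_experiment,
    simulate_profiling,
)


def test_generator_determinism():
    cfg = SimulationConfig(seed=42, n_genes=12, n_species=2)
    s1, t1 = generate_transcriptome(cfg)
    s2, t2 = generate_transcriptome(cfg)
    for name in s1:
        assert s1[name].genome["chr1"].sequence == s2[name].genome["chr1"].sequence
    assert t1.equals(t2)
    tr1, rna1 = simulate_profiling(s1["A"], t1, cfg, seed=99)
    tr2, rna2 = simulate_profiling(s2["A"], t2, cfg, seed=99)
    for gid in tr1:
        for rep in tr1[gid]:
            assert np.array_equal(tr1[gid][rep], tr2[gid][rep])
        assert np.array_equal(rna1[gid], rna2[gid])


def test_planted_fraction_zero_empty_truth():
    cfg = SimulationConfig(seed=1, n_genes=10, planted_fraction=0.0)
    _, truth = generate_transcriptome(cfg)
    assert truth.empty


def test_zero_divergence_identical_leaders():
    cfg = SimulationConfig(seed=3, n_genes=12, n_species=2, divergence=0.0,
                           shared_fraction=1.0)
    species, truth = generate_transcriptome(cfg)
    for ma, mb in zip(species["A"].models, species["B"].models):
        la = tl_sequence(ma, species["A"].genome)
        lb = tl_sequence(mb, species["B"].genome)
        assert la == lb


def test_every_planted_uorf_is_enumerable():
    """Generator/enumerator consistency on both species."""
    cfg = SimulationConfig(seed=5, n_genes=25, n_species=2)
    species, truth = generate_transcriptome(cfg)
    for row in truth.itertuples():
        sp = species[row.species]
        model = next(m for m in sp.models if m.gene_id == row.gene_id)
        leader = tl_sequence(model, sp.genome)
        context = leader + morf_sequence(model, sp.genome)
        cands = {(c.start_pos, c.stop_pos, c.start_codon)
                 for c in enumerate_candidates(leader, context)}
        assert (row.start_pos, row.stop_pos, row.codon) in cands


def test_private_uorfs_knocked_out_in_sibling():
    cfg = SimulationConfig(seed=8, n_genes=30, n_species=2, shared_fraction=0.0)
    species, truth = generate_transcriptome(cfg)
    assert set(truth["species"]) == {"A"}
    for row in truth.itertuples():
        model = next(m for m in species["B"].models if m.gene_id == row.gene_id)
        leader = tl_sequence(model, species["B"].genome)
        assert leader[row.start_pos : row.start_pos + 3] == "AGG"


def test_end_seq_depth_zero_pure_background():
    cfg = SimulationConfig(seed=2, n_genes=8)
    species, _ = generate_transcriptome(cfg)
    five, _ = simulate_end_seq(species["A"], depth=0, seed=0, background=0.02)
    total = sum(p.counts.sum() for p in five.values())
    n = sum(p.counts.size for p in five.values())
    assert total < 0.04 * n + 5 * np.sqrt(0.04 * n)  # Poisson-scale background only


def test_end_seq_concentrates_at_tss():
    cfg = SimulationConfig(seed=4, n_genes=6, max_tss_clusters=1)
    species, _ = generate_transcriptome(cfg)
    five, _ = simulate_end_seq(species["A"], depth=1000, seed=1, background=0.0)
    for model in species.get("A").models:
        pile = five[(model.chrom, model.strand)]
        tss = model.distal_tss
        near = pile.counts[tss - 2 : tss + 3].sum()
        assert near >= 900  # jitter keeps ~100% of reads within +-2 nt


def test_end_seq_seed_sensitivity():
    cfg = SimulationConfig(seed=4, n_genes=6)
    species, _ = generate_transcriptome(cfg)
    a, _ = simulate_end_seq(species["A"], depth=500, seed=1)
    b, _ = simulate_end_seq(species["A"], depth=500, seed=2)
    assert any(
        not np.array_equal(a[k].counts, b[k].counts) for k in a
    )


def test_profiling_null_mode_leader_noise_only():
    cfg = SimulationConfig(seed=6, n_genes=15, density_multiplier=0.0,
                           planted_fraction=0.0)
    species, truth = generate_transcriptome(cfg)
    tracks, _ = simulate_profiling(species["A"], truth, cfg, seed=0)
    rates = []
    for model in species["A"].models:
        L = model.leader_length
        for rep in tracks[model.gene_id].values():
            rates.append(rep[:L].mean())
    # leaders hold only uniform noise at the configured rate
    assert np.mean(rates) == pytest.approx(cfg.leader_noise_rate, rel=0.15)


def test_profiling_periodicity_parameter():
    cfg = SimulationConfig(seed=7, n_genes=40, periodicity=1 / 3,
                           planted_fraction=1.0, density_multiplier=8.0)
    species, truth, gene_data = simulate_experiment(cfg)
    fracs = []
    for row in truth[truth.species == "A"].itertuples():
        pooled = gene_data["A"][row.gene_id].pooled()
        frac = orf_frame_fraction(pooled, (row.start_pos, row.stop_pos))
        if frac is not None:
            fracs.append(frac)
    assert np.mean(fracs) == pytest.approx(1 / 3, abs=0.05)


def test_profiling_high_periodicity():
    cfg = SimulationConfig(seed=7, n_genes=40, planted_fraction=1.0)
    species, truth, gene_data = simulate_experiment(cfg)
    fracs = [
        orf_frame_fraction(gene_data["A"][r.gene_id].pooled(), (r.start_pos, r.stop_pos))
        for r in truth[truth.species == "A"].itertuples()
    ]
    assert np.mean([f for f in fracs if f is not None]) == pytest.approx(0.9, abs=0.05)


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimulationConfig()
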