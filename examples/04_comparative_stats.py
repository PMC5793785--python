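"""Descriptive comparisons: triplet usage, transcript inclusion, TE, metagene.

Reproduces the downstream analyses on synthetic data: observed/expected
triplet ratios of leaders versus 3' UTRs, TSS-usage-weighted transcript
inclusion of called uORFs, rank-sum comparison of translation
efficiencies, and an RBP-style metagene around uORF start codons with a
1000-fold sampled background.
"""

import numpy as np

from uorfseqr.genome_io import tl_sequence, utr3_sequence
from uorfseqr.regression import call_uorfs
from uorfseqr.simulate import SimulationConfig, simulate_experiment
from uorfseqr.stats import (MetageneRecord, rbp_metagene, te_group_compare,
                            transcript_inclusion, triplet_oe)

cfg = SimulationConfig(seed=9, n_genes=40, n_species=1)
species, truth, gene_data = simulate_experiment(cfg)
sp = species["A"]

tl = [tl_sequence(m, sp.genome) for m in sp.models]
u3 = [utr3_sequence(m, sp.genome) for m in sp.models]
oe = triplet_oe(tl, u3)
print("triplet observed/expected (leader vs 3' UTR):")
for tri in ("ATG", "TTG", "CTG"):
    print(f"  {tri.replace('T', 'U'):4s} OE = {oe.loc[tri, 'oe']:.2f}")

res = call_uorfs(gene_data["A"], beta=0.05, n_permutations=10, seed=900)
models = {m.gene_id: m for m in sp.models}
inclusion = [transcript_inclusion(c.candidate, models[c.candidate.gene_id])
             for c in res.calls]
values = [r.inclusion_fraction for r in inclusion]
print(f"\ntranscript inclusion of {len(values)} called uORFs: "
      f"median {np.median(values):.2f}, minority fraction "
      f"{np.mean([r.minority for r in inclusion]):.2f}")

rng = np.random.default_rng(9)
te = {"with uORF": rng.lognormal(-0.3, 0.4, 60),
      "without uORF": rng.lognormal(0.0, 0.4, 60)}
cmp = te_group_compare(te)
print(f"\nTE rank-sum comparison (synthetic groups): adjusted p = "
      f"{cmp['p_adjusted'].iloc[0]:.2e}")

records = []
for c in res.calls[:30]:
    model = models[c.candidate.gene_id]
    L = model.leader_length
    sites = [(max(0, c.candidate.start_pos - 7), max(1, c.candidate.start_pos - 2))]
    records.append(MetageneRecord(c.candidate.start_pos, (0, L), sites))
prof = rbp_metagene(records, half_window_nt=15, n_samples=1000, seed=9)
peak = prof.offsets[np.argmax(prof.observed - prof.expected_mean)]
print(f"\nmetagene: strongest enrichment over the sampled background at "
      f"step {peak:+d} nt from the start codon")
print()
print("Leaders carrying planted uORFs are mildly enriched for start-codon")
print("triplets (OE > 1); other triplets sit near 1. Binding sites planted")
print("just upstream of start codons surface as a negative-offset metagene")
print("peak above the resampled background.")
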