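"""Classify uORF homologs between two diverged synthetic species.

Two species share a transcriptome ancestor; point mutations at 10% per
site separate them, but shared planted uORFs keep their start and stop
codons. Calls in both species are paired by local alignment (HOXD70
matrix, Jaccard >= 0.6 on the aligned interval) or, failing that, by
start/stop position within 5 nt of the main ORF -- sequence homology
takes precedence.
"""

from uorfseqr.genome_io import tl_sequence
from uorfseqr.homology import classify_homologs, shared_fraction_by_start_type
from uorfseqr.regression import call_uorfs
from uorfseqr.simulate import SimulationConfig, simulate_experiment

cfg = SimulationConfig(seed=3, n_genes=40, n_species=2)
species, truth, gene_data = simulate_experiment(cfg)

calls = {}
for name in ("A", "B"):
    res = call_uorfs(gene_data[name], beta=0.05, n_permutations=10, seed=300)
    calls[name] = [c.candidate for c in res.calls]
    print(f"species {name}: {len(calls[name])} uORFs called")

tls = {n: {m.gene_id: tl_sequence(m, species[n].genome) for m in species[n].models}
       for n in ("A", "B")}
pairs = classify_homologs(calls["A"], calls["B"], {g: g for g in tls["A"]},
                          tls["A"], tls["B"], rng=0)
n_seq = sum(p.homology_class == "sequence" for p in pairs)
n_pos = sum(p.homology_class == "position" for p in pairs)
n_shared_truth = int(truth[truth.species == "A"]["shared"].sum())

print(f"homolog pairs: {len(pairs)} ({n_seq} sequence, {n_pos} position)")
print(f"planted shared uORFs: {n_shared_truth}")
shared = shared_fraction_by_start_type(
    {"A": calls["A"], "B": calls["B"]}, {("A", "B"): pairs}
)
for cls, (n_sh, n_tot, frac) in shared.items():
    print(f"  {cls:10s}: {n_sh}/{n_tot} shared ({100 * frac:.1f}%)")
print()
print("Sequence pairs recover planted shared uORFs despite 10% divergence;")
print("the per-start-type shared fractions mirror the planted codon mix.")
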