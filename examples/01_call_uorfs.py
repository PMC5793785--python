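"""Call uORFs on synthetic ribosome profiling with planted ground truth.

Generates a 50-gene transcriptome in which half the genes carry one
translated uORF (AUG or near-cognate start), builds three replicate
P-site tracks, fits the detection regression, scores every candidate
against the leader-permutation null, and calls uORFs at FDR 0.05.
"""

from uorfseqr.regression import call_uorfs
from uorfseqr.simulate import SimulationConfig, simulate_experiment

cfg = SimulationConfig(seed=1, n_genes=50, n_species=1)
species, truth, gene_data = simulate_experiment(cfg)

result = call_uorfs(gene_data["A"], beta=0.05, n_permutations=10, seed=101)

called = {(c.candidate.gene_id, c.candidate.start_pos, c.candidate.stop_pos)
          for c in result.calls}
planted = {(r.gene_id, r.start_pos, r.stop_pos)
           for r in truth[truth.species == "A"].itertuples()}
tp = len(called & planted)

print(f"candidates scored:       {result.n_candidates}")
print(f"planted uORFs:           {len(planted)}")
print(f"called at FDR 0.05:      {len(called)}")
print(f"true positives:          {tp}")
print(f"sensitivity:             {tp / len(planted):.2f}")
print(f"realized FDR:            {(len(called) - tp) / max(len(called), 1):.2f}")
print(f"regression R^2:          {result.model.r_squared:.3f}")
print()
print("Sensitivity is the fraction of planted uORFs recovered at exactly")
print("their planted coordinates; realized FDR is the fraction of calls")
print("that hit no planted uORF. The regression R^2 reports how well the")
print("18 features predict the replicate detection fraction.")
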