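# Methods

This note documents the models, algorithms, parameter choices, and
numerical decisions behind `uorfseqr`, and what the synthetic-data
tests do and do not establish about real data.

## Coordinate contract

All in-memory coordinates are 0-based; intervals are half-open. GFF3
converts from its 1-based inclusive convention at the I/O boundary
only; BED/bedGraph pass through natively. Transcript coordinates put
position 0 at the most distal annotated TSS and run 5'→3' regardless
of genomic strand, so the main-ORF start codon begins at transcript
position `leader_length`. Sequences are held as DNA (ATG/TTG);
user-facing tables print the RNA form (AUG/UUG). Genes whose CDS is
split by introns are excluded with a logged warning: the package
targets organisms with simple gene structure, and splicing-aware
leaders are out of scope.

## End-seq peak calling

### Model

Single-nucleotide read-end pileups are modelled as Poisson counts
`c_i ~ Poisson(exp(θ_i))` with a piecewise-constant-tending log-rate:

    minimise  Σ_i w_i [exp(θ_i) − c_i θ_i]  +  λ Σ_i |θ_{i+1} − θ_i|

The first-order (fused-lasso) penalty on adjacent log-rate differences
yields locally constant backgrounds with sharp changepoints; the 0/1
weights `w` exclude outlier positions (candidate true sites) from the
background estimate.

### Solver

The problem is convex and is solved by ADMM: the smooth subproblem
separates per coordinate (a few safeguarded Newton steps each, with
θ clipped to ±30 so rates stay in [1e−13, 1e13]), and the penalty
subproblem is an exact 1D total-variation proximal step computed with
Condat's direct algorithm. Both kernels are numba-compiled. Defaults:
ρ = 1, up to 5000 iterations to a 1e−7 residual; the two analytic
limits hold numerically (λ→∞ gives the global mean rate to better than
1e−10 relative; λ→0 reproduces the counts at covered positions). The
TV prox is property-tested against a derivative-free optimizer on
random small instances.

### Outliers, λ selection, testing

Positions with upper-tail Poisson probability < 1e−6 under the current
fit are flagged and excluded, and the fit repeated until the flag set
stabilises (≤ 20 rounds). The penalty is chosen per window by halving
from `λ_max = n·(mean+1)` until the fit (over non-flagged positions)
shows at least two distinct levels, with a floor at λ = 2. Crucially,
outlier flags accumulate down this ladder: a spike flagged against the
flat large-λ background stays excluded at smaller penalties. Without
this, an isolated true site eventually becomes profitable as its own
one-position "background level" (two jumps cost 2λ·Δθ against a
likelihood gain that is independent of λ), after which it could never
be tested as a peak.

Covered positions (count ≥ 1) are tested with the upper-tail Poisson
p-value under the fitted local rate and controlled by
Benjamini–Hochberg; the default peak threshold is q ≤ 0.001.
Zero-count positions are never tested, which keeps the FDR universe to
plausibly transcribed positions. Peak search windows extend 1 kb
strand-aware upstream of the annotated mORF start (TSS) or downstream
of the stop (pA), truncated at neighbouring CDSs. Significant sites
are clustered by single linkage with a 25-nt gap; the cluster
representative is its highest-count member (ties: most upstream), and
usage fractions normalise cluster counts within the gene.

## P-site assignment

Each footprint contributes one count at its inferred ribosomal P-site:
the 5' end of the alignment (rightmost base for reverse-strand reads)
plus a read-length-specific offset. Defaults are 28→12, 29→13, 30→13;
a calibration mode re-estimates each offset as the mode of (annotated
mORF start − read 5' end) over well-covered start codons, restricted
to the plausible 10–15 nt range. Reads with untabulated lengths are
dropped and counted; multi-mapped reads (NH > 1) are dropped outright
because uORFs are short enough that ambiguous placement is poison.
RNA-seq coverage is full-read (not P-site) and feeds only abundance
features and translation-efficiency ratios.

## Candidate enumeration

Leaders from the most distal TSS are scanned at every position for the
eight start codons (ATG plus seven near-cognates; AGG and AAG are
treated as non-initiating); each start pairs with its FIRST in-frame
stop, searched through the leader and into the main ORF. Candidates
whose stop lies at or beyond the mORF start carry an `overlaps_morf`
flag and are excluded from default calling output. Starts with no
in-frame stop anywhere downstream (would-be N-terminal extensions) are
not candidates. The vectorised scanner is verified exactly against a
plain position-walking oracle on randomized sequences.

## Features and detection labels

Eighteen features per candidate, computed on the replicate-pooled
P-site track and the leader geometry; the start-codon identity is
deliberately not among them, so the model cannot learn an AUG/NCC
bias. Conventions: log features are log2(x+1); density ratios are
per-nucleotide with a one-pseudo-event floor on empty denominator
regions; the start-peak and stop-drop-off contrasts are log2 ratios
with +0.5 pseudocounts on both sides (symmetric in log space, so a
sporadic single read cannot produce an extreme value). A candidate
with zero pooled P-sites keeps its geometry features, zeroes its
occupancy features, and sets the paired `has_coverage` indicator to 0;
its final call row carries a `no_signal` flag.

The per-replicate detection label -- the regression target -- requires,
in that replicate: P-sites on the start codon ≥ 1, total uORF P-sites
≥ 4, in-frame fraction ≥ 0.5, and an initiation peak: the start-codon
count must exceed the codon-scaled count of the ≤ 3 nt immediately
upstream. The peak requirement is the one part of the rule that
separates a genuine initiation site from an in-frame codon nested
inside an already-translated uORF: both show identical density,
periodicity, and totals downstream, but under the scanning model only
a true start sits against a quiet upstream. Without it, nested
same-stop candidates receive indistinguishable labels, the learned
score cannot order them, and overlap resolution picks between them
essentially at random (measured on synthetic data: sensitivity 0.73
and realized FDR 0.27 versus 1.0/0.0 with the peak requirement, at
identical generator settings). The thresholds and the peak requirement
are all parameters of `detect_in_replicate`.

## Regression, null, and FDR

The score is a ridge regression (penalty 1e−3 on standardized
features; the features are collinear by construction, and the ridge
keeps weights finite without materially changing predictions) of the
detection fraction `y ∈ {0, 1/n, …, 1}` on the 18 features. At least
three biological replicates are required; a constant target refuses to
fit. Weights are estimated independently per experiment.

The null model re-positions P-site counts uniformly within each
transcript leader, per replicate, preserving per-leader totals and
leaving mORF occupancy and RNA coverage untouched -- expression levels
survive, uORF-specific structure (periodicity, start peaks) does not.
Features are recomputed and the already-trained model applied; 10
permutations pool all candidate scores into the null sample.

Empirical q-values: for threshold s,
`FDR(s) = [(1 + #null ≥ s)/N_null] / [max(1, #real ≥ s)/N_real]`, and a
candidate's q is the minimum FDR over thresholds at or below its score
(it belongs to every rejection list with a weaker threshold), clipped
to [0, 1]. The +1 pseudocount keeps q > 0. Significant calls (q ≤ β,
default 0.05) then pass greedy overlap resolution: descending score,
ties to the longer then more upstream candidate, one survivor per
overlapping set per gene.

## Homology

The uORF nucleotide sequence is locally aligned into the homologous
gene's leader under HOXD70 (match 91/100, transversion-weighted
mismatches, gap open −400 / extend −30) -- pairwise local alignment is
the minimal faithful operation for mapping one uORF into one leader.
The mapped interval is the span of leader positions covered by aligned
uORF residues. A Z-score against 100 seeded mononucleotide shuffles of
the uORF calibrates alignment strength; zero-spread shuffle sets yield
a flagged missing Z. Sequence homologs: best partner call with Jaccard
≥ 0.6 between the mapped interval and the partner's interval (ties by
Z, then upstream). Positional homologs: start OR stop distances
upstream of the mORF agree within 5 nt (AND available via a flag; the
OR reading is the default). uORFs already in a sequence pair are
excluded from the positional pass, so classes partition the paired set
with sequence taking precedence. Three-species triplets are connected
components of pairwise links spanning all three species.

## Comparative statistics

Triplet observed/expected uses overlapping windows (stride 1) in
leaders versus 3' UTRs; OE is undefined (flagged) for triplets absent
from the 3' UTR set. Per-species tables are computed first and then
averaged, and both are reported. Transcript inclusion of a uORF sums
TSS usage fractions over isoforms whose TSS lies at or upstream of the
start codon; < 0.5 flags a minority-isoform uORF. TE group comparisons
are two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg
adjustment across group pairs. The RBP metagene sums binding-site
overlaps in 3-nt steps around TISs, counting only TISs whose
transcript encloses the step; the background re-samples TIS and site
positions uniformly within the same transcript 1000 times,
independently, and reports the mean, pointwise 95% limits, and a
simultaneous 95% envelope (the per-step quantile is widened until 95%
of sampled profiles lie entirely inside -- the correct band for an
"inside at every step" statement). The 15-nt region upstream of the
mORF start is excluded from leader regions by truncating each record's
usable span, so main-ORF initiation footprints are not attributed to
uORFs.

## Synthetic data

The generator emulates the data regime the pipeline targets, with all
knobs in `SimulationConfig`:

* **Geometry:** 50 genes on alternating strands of one chromosome;
  leader lengths lognormal with median 50 nt (σ = 0.45, clamped to
  [24, 300]) matching the 45–55 nt medians typical of yeast; mORFs of
  100–200 codons; 3' UTRs of 60–120 nt; 1–3 TSS clusters with
  Dirichlet(2) usage (largest share on the distal TSS); 1–2 pA sites.
* **Planted uORFs:** half the eligible genes carry one uORF of 5–12
  codons, start codon drawn from a mix weighted toward AUG and UUG;
  bodies are built stop-free so each planted uORF is exactly one
  enumerable candidate.
* **Profiling:** replicates are independent Poisson draws around a
  shared mean profile. Leaders carry uniform noise at 0.5 P-sites/nt
  per replicate; mORFs are 3-nt periodic at 2/nt scaled by a lognormal
  per-gene expression factor; planted uORFs replace the leader noise
  with a periodic profile at `multiplier ×` the noise density (default
  5x, scaled 1.0/0.8/0.6 for AUG/UUG/other NCC to mirror start-codon
  strength), in-frame fraction 0.9, and a 2x first-codon initiation
  bump -- conservative relative to the start-codon peaks of real
  CHX-treated Ribo-seq.
* **End-seq:** per-gene Multinomial(depth × usage) read ends with
  ±2 nt jitter over a Poisson(0.02)/nt background.
* **Species:** siblings are derived by point mutation at 10% per site
  (no indels, so gene coordinates are shared); mORF start/stop codons
  and shared planted uORFs' start/stop codons are protected, mutations
  creating in-frame stops inside shared uORF bodies are reverted, and
  private uORFs are knocked out in the sibling with the non-initiating
  AGG codon.

Identical config + seed reproduces byte-identical outputs.

**What the tests show -- and don't.** The noise model is Poisson
throughout, matching the peak caller's likelihood; an overdispersion
path (negative binomial) exists as a knob but is off by default, so
passing tests demonstrate correctness under the method's own
assumptions, not robustness to overdispersed libraries, sequence-
specific library bias, cap-proximal artifacts, internal priming in
pA-seq, or mapping ambiguity -- none of which the generator emulates.
Leader permutation is also exactly the caller's null, so null
calibration on synthetic data verifies internal consistency of the
FDR machinery rather than the adequacy of that null for real libraries.

## Pipeline sizes and runtimes

The shipped fixture (20 genes × 2 species) and the test/acceptance
problem sizes (50 genes × 3 replicates × 5–10 seeds; 2 kb peak-calling
windows × 20 seeds; 1000-fold metagene sampling) were chosen so the
whole suite and the acceptance script each complete in minutes on one
CPU while leaving every statistical check adequately powered (≥ 500
pooled candidates for calibration, ≥ 100 planted uORFs for recovery,
≥ 30k tested positions for the peak-caller FDR).

## Known limitations

* One linear model per experiment; no cross-experiment weight
  transfer, no non-linear scoring.
* Splicing-aware leaders, A-site/codon-level dwell analysis, FASTQ
  simulation, and synteny-based reannotation are out of scope; homolog
  gene pairings are an input table.
* The greedy overlap resolution is score-driven; when two nested
  candidates are genuinely indistinguishable in the data the longer,
  more upstream one wins by the tie-break.
* The positional-homology OR rule can pair uORFs that share only one
  boundary; the stricter AND semantics is available via a flag.
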