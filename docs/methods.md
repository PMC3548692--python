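# Methods

## Scoring model

A SNP's priority is σ(**w**) = Σⱼ wⱼ fⱼ over the selected features, with
weights wⱼ ∈ [0, 1] and normalized feature scores fⱼ ∈ [0, 1]. The
raw-to-score normalization is this package's own convention (the linear
combination constrains only how scores combine, not how raw annotations
become scores):

- **binary** features (track membership): 0 or 1;
- **categorical** features map labels through an ordinal score table; the
  shipped localization table encodes the damage ordering frame shift 1.0 >
  missense 0.9 > start codon 0.85 > UTR-3/UTR-5 0.6 > near-gene 0.4 >
  intron 0.2 > intergenic/unknown 0.1, and ships as editable
  configuration, never hard-coded;
- **continuous** features are min-max scaled to the declared range and
  clipped (MAF uses [0, 0.5], the folded-spectrum maximum);
- a **missing** annotation scores 0: absence of evidence contributes no
  score mass to a sum-based score, while storage keeps missing distinct
  from zero for auditability;
- a **contextual** (tissue/cell-line) value scores its selected context,
  or the arithmetic mean over the contexts observed in the track when no
  context is chosen.

Keeping every fⱼ in [0, 1] makes weights directly comparable with the
optimizer's [0, 1] sampling range. Ranking is σ descending with ties
broken by rsid ascending, so output order is a pure function of the
input; the percentile cut retains ⌈p/100 · N⌉ entries. σ is emitted as
the raw weighted sum, not rescaled by Σwⱼ — users comparing runs with
different feature selections should rescale themselves if needed.

Coordinates are 0-based half-open internally; TSV inputs may declare
1-based inclusive columns per row, VCF positions are converted on read.
SNP–gene association extends each gene interval symmetrically by the
flanking distance (default 100 000 bp, clipped at zero), ignores strand,
and keeps every overlapping gene — a SNP inside two genes' windows
contributes to both genes' candidate sets, including during optimization.

## Weight optimization

For disease *d* with candidate universe S (every SNP within the flanking
window of its genes) and certified set A ⊆ S (certified SNPs outside S
are dropped with a logged count), the retained set at relative threshold
ε is Y = {σᵢ > ε · max σ} (strict comparison). The threshold is relative
to the score maximum so the retained set is invariant under rescaling of
**w** — an absolute cutoff could not be, given weights of arbitrary
scale.

Fitness is 1 − mean per-disease sensitivity (a pooled-count aggregate is
available behind a flag), subject to |Y|/|S| < T_r per training disease.
Infeasible configurations receive the **graded penalty**
2.0 + max_d(|Y_d|/|S_d| − T_r): every infeasible value dominates the
feasible range [0, 1], preserving selection ordering, while the graded
term gives the search a descent direction through the infeasible region.
This matters in practice: with dense annotation rates most random weight
vectors retain far more than a quarter of S, so a flat sentinel would
leave the whole initial population tied and reduce the optimizer to
random drift. At ε = 0.3, T_r = 0.25 under the generator defaults the
constraint is near-active at the optimum (background pass rates sit just
above a quarter), so best fitness may legitimately remain in the penalty
band while the learned direction — which features matter — is already
correct; held-out sensitivity is evaluated regardless of feasibility.

The generational scheme (defaults): population 120; 10 fresh uniform
individuals, the 10 lowest-fitness individuals carried unmodified, 100
recombinants of the top 50. Recombination is uniform crossover with
per-coefficient mutation probability 0.05; the mutation step is Gaussian
(sd 0.1) truncated at ±3 sd, and coefficients are clipped to [0, 1] —
truncation gives the exact envelope invariant `child ∈
[min(parents) − 0.3, max(parents) + 0.3] ∩ [0, 1]`. Ties in fitness are
broken by original population index, so runs are reproducible; all
randomness flows from a single integer seed, and the LOOCV driver derives
per-run sub-seeds deterministically from (master seed, cell indices,
held-out index) via `numpy` seed sequences.

Cross-validation holds out each disease once per (ε, T_r) cell: 16
diseases × 10 ε steps × 4 T_r steps = 640 training runs for the full
grid. Reports carry per-run sensitivity/specificity/accuracy on the
held-out disease and per-cell means. Specificity with an empty negative
retention (TN + FP = 0) is defined as 1.0.

One registry-size note: the optimizer treats the registry length as
configurable rather than fixing n = 30 or 31; sources disagree on whether
one feature (plausibly the OMIM-pathology flag, to avoid circularity
during optimization) is excluded from the learned vector, and this
package does not resolve that — users can deselect any feature.

## Ontology similarity and expansion

The OBO parser keeps is_a and part_of edges (others are dropped with a
count), excludes obsolete terms, and rejects cyclic graphs. Wang
similarity propagates S-values from each term through its ancestor
closure — S(term) = 1, multiplied per edge by a contribution factor
(defaults 0.8 is_a / 0.6 part_of, configurable), maximum over paths — and
compares two terms by the shared fraction of total semantic value. Rel
similarity estimates p(term) from the annotation corpus with ancestor
propagation (no external IC tables), IC = −ln p, and scores a pair by
2·IC(c*)/(IC(t₁)+IC(t₂)) · (1 − p(c*)) at the most informative common
ancestor c*; similarity through the root is 0 by the rarity factor.

Gene-level similarity is the best-match average over the genes' direct
annotation sets, the aggregation published with the Wang measure's
reference implementation; it is used for both measures (whether the
original tool aggregated Rel by BMA or by max is not recoverable).
Expansion adds every annotated gene whose best similarity against a seed
reaches the threshold (max over seeds); an optional top-k cap bounds the
additions. Unannotated seeds are skipped with a warning. The default
namespace is biological_process.

## Enrichment

The genes carrying the SNPs that survive the percentile cut form the top
set; counting is gene-level (several top SNPs in one gene count once).
Each category with at least one top gene is tested with the
hypergeometric upper tail P(X ≥ k) (categories with zero overlap are
skipped to keep the test count m honest; a flag includes them at p = 1),
and p-values are BH-adjusted per source — pathway, ontology term and
disorder families are corrected separately, mirroring their separate
interfaces. The background universe is the loaded category map's full
gene universe, not only the input genes.

## Synthetic data

The generator emulates the study design the optimizer expects: a panel of
diseases (default 16) with disjoint gene sets (an overlap fraction is
settable), genes tiled on disjoint 250 kb intervals of one chromosome
(20 kb bodies, so 100 kb flanking windows never cross diseases), and a
configurable number of SNPs placed uniformly within each gene's window
(default 40/gene, 10 certified per disease).

The planted signal is a two-rate model on binary features: certified
SNPs carry each of the 5 informative features at rate p₁ = 0.8,
background SNPs at p₀ = 0.2; the 24 noise features fire at p₀ for
everyone, and MAF plus localization complete the default 31-feature
registry. This is the simplest signal a linear score can exploit, which
keeps the weight-recovery experiment well-posed; a continuous variant
(class-shifted Gaussians through min-max scaling) sits behind a flag.
The toy ontology is a rooted tree (default depth 3, branching 3 → 40
terms) with periodic part_of edges; each disease owns a distinct leaf
pair shared by its genes, so within-disease gene similarity exceeds
between-disease similarity by construction. Everything is deterministic
under the seed, to the byte, including file ordering.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: linkage disequilibrium and
haplotype structure, realistic allele-frequency spectra, correlated
annotation tracks, genome-scale SNP densities, annotation biases of real
databases, or any particular genome build's coordinates. Recovery
results on planted signal are a correctness check of the optimizer, not
an estimate of real-world sensitivity.

## Problem sizes and numerical choices

The recovery experiment runs a proportionally scaled scheme — population
40 (3 random / 3 elite / 34 recombinants, elite pool 17), 30 generations
— over an 8-disease panel, ten seeds; the package chose these sizes so
the whole experiment completes in seconds while leaving the planted
signal comfortably recoverable. The full 640-run grid is exercised with
a fixed-weight trainer when only the protocol is under test. The
hypergeometric oracle comparison enumerates all draws for population
sizes up to 10–12 (tolerance 1e−12; observed agreement ~1e−16). Degenerate
inputs are defined, not crashed: all-zero scores give T_ε = 0 with a
warning; a benchmark without certified SNPs is excluded from fitness with
a warning; an empty top gene set yields an explicit empty enrichment
result.

## Known limitations

- The published default weights are reproduced as shipped configuration;
  re-deriving them requires the original disease/annotation warehouse,
  which is out of scope by design.
- Real-ontology similarity values depend on the ontology release and
  annotation corpus; the fixtures demonstrate the workflow, not any
  specific published similarity score.
- Only over-representation (upper tail) is tested, not depletion.
- No LD-awareness: nearby SNPs are scored independently.
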