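# varprio

Gene-centric SNP prioritization for disease studies: given a list of genes
(or rs identifiers, or an ontology biological-process term), score every
SNP in the genes' flanking windows by a weighted combination of
biomolecular annotations, rank them, and test the top of the list for
pathway/disorder over-representation. Intended for researchers in medical
genetics who need to re-score GWAS hits against prior biological
knowledge, or to pre-select candidate SNPs for disease-oriented
genotyping panels.

## The model

Each SNP *i* carries a vector of normalized feature scores
*f*₁…*f*ₙ ∈ [0, 1] — localization class, minor-allele frequency,
epigenetic track membership, protein-level annotations, and so on. Its
prioritization score is the weighted linear combination

σᵢ(**w**) = w₁f₁ + w₂f₂ + … + wₙfₙ,  wⱼ ∈ [0, 1].

The shipped default weights (31 features) were learned by a genetic
algorithm against disease benchmarks: for a disease with candidate SNP
universe *S* (all SNPs within 100 kb of its genes) and certified disease
SNP set *A* ⊆ *S*, the high-scoring set is

Y = { sᵢ ∈ S : σᵢ(**w**) > T_ε },  T_ε = ε · maxᵢ σᵢ(**w**),

and the optimizer minimizes 1 − sensitivity = 1 − |A ∩ Y| / |A|, subject
to the filtering constraint |Y| / |S| < T_r (violations receive a graded
penalty ≥ 2, strictly worse than any feasible fitness). Generations hold
120 individuals: 10 fresh random, the 10 best carried unmodified, and 100
recombinants of the top 50. Model assessment is leave-one-disease-out
cross-validation swept over ε ∈ {0.1, …, 1.0} and
T_r ∈ {0.25, 0.5, 0.75, 1.0}.

Input gene sets can be expanded through ontology semantic similarity
(Wang S-value propagation with is_a/part_of contribution factors, or the
Schlicker Rel measure on corpus information content), aggregated to gene
level by best-match average. Enrichment of the genes carrying
top-percentile SNPs uses the hypergeometric upper tail with
Benjamini–Hochberg FDR correction.

Because the original multi-database annotation warehouse is not
redistributable, the package ships a synthetic-data generator
(`varprio.synthetic`) that emulates the store, the disease benchmarks and
the ontology with a planted, recoverable signal; every reader format is
plain text (TSV/BED/VCF/OBO/GMT/YAML).

## Worked example

`examples/01_simulate_and_rank.py` simulates a small store and ranks the
SNPs of two genes:

```
50 SNPs ranked for genes G001, G002

rank  rsid        sigma   genes
   1  rs1000006  6.5172  G001
   2  rs1000010  6.1705  G001
   3  rs1000047  5.8980  G002
```

σ is the weighted sum of each SNP's normalized feature scores; the genes
column lists every input gene whose 100 kb flanking window contains the
SNP. `examples/04_enrich_top_snps.py` then tests the genes carrying the
top quartile of that list against disorder categories:

```
category     k  K  n   N   p-value   q-value
disease_01  3  3  3  12  0.0045   0.0045
```

— all 3 top genes fall in the 3-gene disease_01 panel out of a 12-gene
universe, hypergeometric upper tail p = C(3,3)·C(9,0)/C(12,3) ≈ 0.0045.

The other examples cover ontology expansion
(`02_expand_gene_set.py`) and GA weight learning with LOOCV
(`03_learn_weights.py`). The same workflows are available from the shell
via the `varprio` command (`simulate`, `rank`, `optimize`, `expand`,
`enrich`).

## Layout

- `src/varprio/annotation_store.py` — gene/SNP/track readers, flanking-region SNP↔gene maps, raw feature matrix
- `src/varprio/scoring.py` — normalization, σ, ranking, percentile cut
- `src/varprio/ontology.py` — OBO DAG, Wang/Rel similarity, expansion
- `src/varprio/ga.py` — fitness, GA operators, LOOCV grid
- `src/varprio/enrichment.py` — hypergeometric tests, BH-FDR
- `src/varprio/synthetic.py` — fixture generator with planted signal
- `src/varprio/cli.py` — thin command-line layer
- `docs/methods.md` — model details, defaults, limitations
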