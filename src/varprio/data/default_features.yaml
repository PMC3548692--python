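# Default feature registry: the per-feature weights learned by the genetic
# algorithm against the 16-disease benchmark panel, shipped as the default
# scoring configuration.  Everything here is user-editable: weights, the
# ordinal scores of the localization classes, and value ranges.
features:
  - name: MAF
    section: SNPs and Genes
    value_kind: continuous
    value_range: [0.0, 0.5]
    weight: 0.3133
  - name: Localization
    section: SNPs and Genes
    value_kind: categorical
    category_scores:
      frame shift: 1.0
      missense: 0.9
      start codon: 0.85
      UTR-3: 0.6
      UTR-5: 0.6
      near-gene: 0.4
      intron: 0.2
      intergenic: 0.1
      unknown: 0.1
    weight: 0.7052
  - name: Essential Genes
    section: SNPs and Genes
    value_kind: binary
    weight: 0.2665
  - name: Phylo
    section: SNPs and Genes
    value_kind: continuous
    value_range: [0.0, 1.0]
    weight: 0.5797
  - name: Lamina associated domains
    section: SNPs and Genes
    value_kind: binary
    weight: 0.2444
  - name: Open Chromatin
    section: Epigenetics and transcription regulations
    value_kind: binary
    context_axis: tissue
    weight: 0.1596
  - name: Chromatin Structure
    section: Epigenetics and transcription regulations
    value_kind: binary
    context_axis: tissue
    weight: 0.7525
  - name: Methylation (seq regions)
    section: Epigenetics and transcription regulations
    value_kind: binary
    context_axis: tissue
    weight: 0.4009
  - name: Methylation
    section: Epigenetics and transcription regulations
    value_kind: binary
    context_axis: tissue
    weight: 0.3743
  - name: CpG Island
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.8992
  - name: DNase clusters
    section: Epigenetics and transcription regulations
    value_kind: binary
    context_axis: tissue
    weight: 0.9558
  - name: TSS (eponine)
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.3705
  - name: CpG islands, promoters, first exons
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.9665
  - name: FOX2 CLIP-seq
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.5608
  - name: TAF1 binding sites
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.2468
  - name: Intergenic regulatory elements
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.4006
  - name: TSS (SwitchGear)
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.6773
  - name: Regulatory regions (OregAnno)
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.8818
  - name: TFBS (TRANSFAC)
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.8243
  - name: TXN factor ChIP-Seq
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.4477
  - name: Enhancers (VISTA)
    section: Epigenetics and transcription regulations
    value_kind: binary
    weight: 0.9571
  - name: Alternative Splicing
    section: Translation regulations
    value_kind: binary
    weight: 0.7032
  - name: miRNA binding regions
    section: Translation regulations
    value_kind: binary
    weight: 0.8358
  - name: Hub protein
    section: Proteins
    value_kind: binary
    weight: 0.5796
  - name: Protein Domain
    section: Proteins
    value_kind: binary
    weight: 0.6316
  - name: PolyPhen
    section: Proteins
    value_kind: continuous
    value_range: [0.0, 1.0]
    weight: 0.5678
  - name: SNPs 3D
    section: Proteins
    value_kind: binary
    weight: 0.5977
  - name: LS-SNP
    section: Proteins
    value_kind: binary
    weight: 0.3158
  - name: Protein Interactions
    section: Proteins
    value_kind: binary
    weight: 0.3728
  - name: PTM
    section: Proteins
    value_kind: binary
    weight: 0.5399
  - name: Pathologies OMIM
    section: Disease
    value_kind: binary
    weight: 0.2904
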