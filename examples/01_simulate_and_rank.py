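"""Simulate a small annotation store and rank the SNPs of two genes.

Builds a synthetic world (genes on disjoint intervals, SNPs with planted
feature signal), loads it back through the store readers, and scores every
SNP within 100 kb of the two input genes with the registry's weights.
"""

import tempfile
from pathlib import Path

from varprio import SimulationSpec, simulate_all
from varprio.pipeline import AnnotationStore, rank_pipeline

with tempfile.TemporaryDirectory() as tmp:
    spec = SimulationSpec(n_diseases=4, snps_per_gene=25, seed=11)
    simulate_all(spec, tmp)
    store = AnnotationStore.load(Path(tmp) / "store")

    run = rank_pipeline(store, gene_tokens="G001,G002",
                        flank_bp=100_000, percentile=100)

    print(f"{len(run.ranked)} SNPs ranked for genes G001, G002\n")
    print("rank  rsid        sigma   genes")
    rsid_genes = run.gene_map.rsid_to_genes()
    for i, entry in enumerate(list(run.ranked)[:8], 1):
        genes = ",".join(f"G{g:03d}" for g in sorted(rsid_genes[entry.rsid]))
        print(f"{i:>4}  {entry.rsid}  {entry.sigma:.4f}  {genes}")

print("""
sigma is the weighted sum of the SNP's normalized feature scores; with the
synthetic registry (all weights 0.5) a SNP carrying many planted binary
annotations plus a damaging localization class rises to the top.  The gene
column shows which input gene's 100 kb flanking window contains the SNP.
""")
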