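"""End-to-end ranking workflow over an on-disk annotation store.

Stage order: extract the SNPs of the input genes (or of the genes annotated
to a biological process), optionally expand the gene set by ontology
similarity, normalize and score every SNP with the selected features and
weights, rank, and truncate at the requested percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation_store as store
from . import ontology as onto
from .errors import NoInputGenesError
from .registry import FeatureRegistry
from .scoring import RankedList, percentile_cut, score_and_rank

logger = logging.getLogger(__name__)


@dataclass
class AnnotationStore:
    """In-memory view of a fixture store directory."""

    genes: list[store.GeneRecord]
    snps: store.SnpTable
    registry: FeatureRegistry
    matrix: store.FeatureMatrix

    @classmethod
    def load(cls, store_dir: str | Path) -> "AnnotationStore":
        """Load genes.tsv, snps.tsv, registry.yaml and every tracks/ file."""
        store_dir = Path(store_dir)
        genes = store.load_gene_table(store_dir / "genes.tsv", format="tsv")
        snps = store.load_snp_table(store_dir / "snps.tsv", format="tsv")
        registry = FeatureRegistry.from_yaml(store_dir / "registry.yaml")
        tracks: dict[str, dict[str, object]] = {}
        tracks_dir = store_dir / "tracks"
        if tracks_dir.is_dir():
            for path in sorted(tracks_dir.iterdir()):
                name = path.stem
                if name in registry:
                    tracks[name] = store.load_feature_track(path, registry[name], snps)
        if "Localization" in registry and "Localization" not in tracks:
            tracks["Localization"] = store.track_from_function_class(snps)
        matrix = store.build_feature_matrix(snps, tracks, registry)
        return cls(genes=genes, snps=snps, registry=registry, matrix=matrix)


@dataclass
class RankRun:
    """Everything cmd_rank produces, kept for downstream enrichment."""

    ranked: RankedList
    gene_map: store.GeneSnpMap
    input_genes: list[store.GeneRecord]
    expansion: onto.ExpansionResult | None = None
    unresolved: list[str] = field(default_factory=list)


def rank_pipeline(
    st: AnnotationStore,
    gene_tokens: str | None = None,
    snp_tokens: str | None = None,
    process_term: str | None = None,
    flank_bp: int = 100_000,
    expansion: str = "off",
    expansion_threshold: float = 0.2,
    dag: onto.OntologyDag | None = None,
    corpus: onto.AnnotationCorpus | None = None,
    weights: np.ndarray | None = None,
    selected: list[str] | None = None,
    contexts: dict[str, str] | None = None,
    percentile: float = 100.0,
) -> RankRun:
    """Run extraction -> optional expansion -> scoring -> ranking -> cut."""
    modes = [m for m in (gene_tokens, snp_tokens, process_term) if m]
    if len(modes) != 1:
        raise ValueError("exactly one of genes, snps or process must be given")

    unresolved: list[str] = []
    expansion_result = None

    if snp_tokens:
        wanted = {t.strip() for t in snp_tokens.split(",") if t.strip()}
        chosen = [s for s in st.snps if s.rsid in wanted]
        missing = wanted - {s.rsid for s in chosen}
        if missing:
            logger.warning("unknown rsids skipped: %s", sorted(missing))
            unresolved = sorted(missing)
        if not chosen:
            raise NoInputGenesError("none of the input rsids are in the store")
        genes_for_map = st.genes
    else:
        if process_term:
            if dag is None or corpus is None:
                raise ValueError("process input requires an ontology and annotations")
            gene_ids = onto.genes_for_process(process_term, corpus, dag)
            tokens = ",".join(sorted(gene_ids))
        else:
            tokens = gene_tokens
        input_genes, unresolved = store.resolve_gene_ids(tokens, st.genes)

        if expansion != "off":
            if dag is None or corpus is None:
                raise ValueError("expansion requires an ontology and annotations")
            seed_ids = {str(g.gene_id) for g in input_genes}
            expansion_result = onto.expand_gene_set(
                seed_ids, corpus, dag, measure=expansion,
                threshold=expansion_threshold,
            )
            by_id = {str(g.gene_id): g for g in st.genes}
            input_genes = [by_id[g] for g in sorted(expansion_result.g2) if g in by_id]

        genes_for_map = input_genes
        gene_map_all = store.map_snps_to_genes(st.snps, input_genes, flank_bp)
        mapped = {r for _, r in gene_map_all.pairs}
        chosen = [s for s in st.snps if s.rsid in mapped]
        if not chosen:
            raise NoInputGenesError("no SNPs fall within the flanking windows")

    gene_map = store.map_snps_to_genes(chosen, genes_for_map, flank_bp)

    sub = store.FeatureMatrix(
        snps=[s.rsid for s in chosen], features=st.matrix.features
    )
    keep = set(sub.snps)
    sub.values = {k: v for k, v in st.matrix.values.items() if k[0] in keep}
    ranked = score_and_rank(sub, st.registry, weights=weights,
                            selected=selected, contexts=contexts)
    ranked = percentile_cut(ranked, percentile)
    return RankRun(
        ranked=ranked,
        gene_map=gene_map,
        input_genes=genes_for_map if not snp_tokens else [],
        expansion=expansion_result,
        unresolved=unresolved,
    )
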