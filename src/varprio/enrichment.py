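"""Gene-set over-representation of top-ranked SNPs.

The genes carrying the SNPs that survive the percentile cut form the "top"
set; for each category (pathway, ontology term, or genetic disorder) the
overlap k out of n top genes is tested against K of N universe genes with
the hypergeometric upper tail P(X >= k), and p-values are corrected per
source with Benjamini-Hochberg FDR.  Counting is at gene level: several
top SNPs in one gene count that gene once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_store import GeneSnpMap
from .scoring import RankedList, percentile_cut

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # survival function is computed from log-space binomials inside scipy
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CategoryMap:
    """Categories of one source with their annotated genes and the universe."""

    source: str                       # pathway | ontology_term | disorder
    categories: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if not self.categories:
            raise ValueError("category map with no categories")
        stray = set().union(*self.categories.values()) - self.universe
        if stray:
            raise ValueError(f"category genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_gmt(cls, path: str | Path, source: str = "pathway",
                 universe: set[str] | None = None) -> "CategoryMap":
        cats: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                cats[parts[0]] = {g for g in parts[2:] if g}
        uni = universe if universe is not None else set().union(*cats.values())
        return cls(source=source, categories=cats, universe=uni)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str = "pathway",
                 universe: set[str] | None = None) -> "CategoryMap":
        """Two-column TSV: category_id <TAB> gene_id."""
        cats: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cat, gene = line.split("\t")[:2]
                cats.setdefault(cat, set()).add(gene)
        uni = universe if universe is not None else set().union(*cats.values())
        return cls(source=source, categories=cats, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int          # top genes in category
    n: int          # top genes total (within universe)
    K: int          # universe genes in category
    N: int          # universe size
    p_value: float
    q_value: float


def enrich_top(
    ranked: RankedList,
    percentile: float,
    cmap: CategoryMap,
    gene_map: GeneSnpMap,
    include_empty: bool = False,
) -> list[EnrichmentResult]:
    """Test over-representation of each category among the genes that carry
    the top-percentile SNPs.  Categories with no top gene are skipped unless
    ``include_empty``; results sorted by q then p then category."""
    top = percentile_cut(ranked, percentile)
    rsid_genes = gene_map.rsid_to_genes()
    top_genes = {str(g) for e in top for g in rsid_genes.get(e.rsid, ())}
    top_genes &= cmap.universe
    if not top_genes:
        logger.warning("no top genes inside the %s universe: no tests", cmap.source)
        return []
    N = len(cmap.universe)
    n = len(top_genes)
    tested = []
    for cat, genes in sorted(cmap.categories.items()):
        k = len(top_genes & genes)
        if k == 0 and not include_empty:
            continue
        tested.append((cat, k, len(genes)))
    if not tested:
        return []
    p_values = [hypergeom_upper_tail(k, K, n, N) for _, k, K in tested]
    q_values = bh_fdr(p_values)
    results = [
        EnrichmentResult(cat, k, n, K, N, float(p), float(q))
        for (cat, k, K), p, q in zip(tested, p_values, q_values)
    ]
    return sorted(results, key=lambda r: (r.q_value, r.p_value, r.category))


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tk\tK\tn\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                f"\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )
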