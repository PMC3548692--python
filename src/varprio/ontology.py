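"""Ontology-based gene similarity and gene-set expansion.

Two term-level semantic similarity measures are provided:

* **Wang**: each term t defines S-values over its ancestor closure —
  S_t(t) = 1 and S-values decay multiplicatively through edges (default
  contribution factors 0.8 for is_a, 0.6 for part_of), keeping the maximum
  over paths.  sim(a, b) = sum over shared terms of (S_a + S_b) divided by
  (SV_a + SV_b), the total semantic values.

* **Rel** (Schlicker relevance): with p(t) the annotation probability of t
  estimated from the propagated corpus and IC(t) = -ln p(t),
  sim(a, b) = [2 IC(c*) / (IC(a) + IC(b))] * (1 - p(c*)) where c* is the
  common ancestor with maximal IC.  The rarity factor (1 - p) sends
  similarity through the root to 0.

Gene-level similarity aggregates term similarities by best-match average
(BMA).  Expansion grows an input gene set g1 to g2 ⊇ g1 with every
annotated gene whose best similarity to a seed reaches the threshold.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet

from .errors import AmbiguousTermError, IntegrityError

logger = logging.getLogger(__name__)

KEPT_EDGE_TYPES = ("is_a", "part_of")
DEFAULT_CONTRIB = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDag:
    """Term DAG with typed child->parent edges (is_a / part_of only)."""

    parents: dict[str, list[tuple[str, str]]]  # term -> [(parent, edge_type)]
    names: dict[str, str]
    namespaces: dict[str, str]
    dropped_edges: int = 0
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for term, plist in self.parents.items():
            for p, _ in plist:
                if p not in self.parents:
                    raise IntegrityError(f"edge {term} -> missing parent {p}")
        g = nx.DiGraph(
            (t, p) for t, plist in self.parents.items() for p, _ in plist
        )
        if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
            raise IntegrityError("ontology graph contains a cycle")
        self._children = {t: [] for t in self.parents}
        for t, plist in self.parents.items():
            for p, _ in plist:
                self._children[p].append(t)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)

    @property
    def terms(self) -> list[str]:
        return list(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, plist in self.parents.items() if not plist}

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self.parents.values())

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of term, excluding term itself (cached)."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [p for p, _ in self.parents[term]]
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(p for p, _ in self.parents[t])
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self._children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self._children[t])
        return frozenset(out)


def parse_obo(path: str | Path) -> OntologyDag:
    """Parse an OBO 1.2 file.  Obsolete terms are excluded; only is_a and
    part_of edges are retained, others are dropped with a logged count."""
    graph = obonet.read_obo(str(path))  # skips obsolete terms by default
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in graph.nodes}
    names, namespaces = {}, {}
    dropped = 0
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "")
    for child, parent, etype in graph.edges(keys=True):
        if etype in KEPT_EDGE_TYPES:
            parents[child].append((parent, etype))
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d non is_a/part_of edge(s)", path, dropped)
    return OntologyDag(
        parents=parents, names=names, namespaces=namespaces, dropped_edges=dropped
    )


# --------------------------------------------------------------------------
# Annotation corpus
# --------------------------------------------------------------------------

@dataclass
class AnnotationCorpus:
    """Gene -> term annotations, direct and propagated over ancestors."""

    gene_terms: dict[str, set[str]]
    propagated: dict[str, set[str]]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_terms)

    @classmethod
    def from_direct(
        cls, direct: dict[str, set[str]], dag: OntologyDag
    ) -> "AnnotationCorpus":
        prop = {
            g: set().union(*(dag.ancestors(t) | {t} for t in terms)) if terms else set()
            for g, terms in direct.items()
        }
        return cls(gene_terms=direct, propagated=prop)


def load_annotations(
    path: str | Path,
    dag: OntologyDag,
    format: str = "tsv",
    namespace: str | None = "biological_process",
) -> AnnotationCorpus:
    """Load a gene->term annotation table.

    ``tsv``: columns gene_id, term_id[, evidence].  ``gaf``: GAF 2.x column
    order (object ID in column 2, GO ID in column 5).  Terms missing from
    the DAG, or outside the requested namespace, are dropped with a count.
    """
    direct: dict[str, set[str]] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")) or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if format == "gaf":
                gene, term = parts[1], parts[4]
            else:
                gene, term = parts[0], parts[1]
            if term not in dag or (namespace and dag.namespaces.get(term) not in (namespace, "")):
                skipped += 1
                continue
            direct.setdefault(gene, set()).add(term)
    if skipped:
        logger.warning("%s: skipped %d annotation(s) outside the DAG/namespace", path, skipped)
    return AnnotationCorpus.from_direct(direct, dag)


@dataclass
class TermInformationContent:
    """p(term) from propagated corpus frequencies and IC = -ln p."""

    p: dict[str, float]
    ic: dict[str, float]

    @classmethod
    def from_corpus(
        cls, corpus: AnnotationCorpus, dag: OntologyDag
    ) -> "TermInformationContent":
        n_genes = sum(1 for terms in corpus.propagated.values() if terms)
        counts: dict[str, int] = {}
        for terms in corpus.propagated.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        p = {t: counts[t] / n_genes for t in counts} if n_genes else {}
        ic = {t: float(-np.log(v)) for t, v in p.items()}
        return cls(p=p, ic=ic)


# --------------------------------------------------------------------------
# Term similarity
# --------------------------------------------------------------------------

def wang_svalues(
    dag: OntologyDag, term: str, contrib: dict[str, float] | None = None
) -> dict[str, float]:
    """S-values of a term over its ancestor closure: S(term) = 1, decaying
    multiplicatively through edges, maximum over paths."""
    contrib = contrib or DEFAULT_CONTRIB
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    best: dict[str, float] = {}
    heap = [(-1.0, term)]
    while heap:
        neg, t = heapq.heappop(heap)
        s = -neg
        if t in best:  # already settled at a value >= s
            continue
        best[t] = s
        for parent, etype in dag.parents[t]:
            cand = s * contrib.get(etype, 0.0)
            if cand > best.get(parent, 0.0) and parent not in best:
                heapq.heappush(heap, (-cand, parent))
    return best


def wang_term_sim(
    dag: OntologyDag, t1: str, t2: str, contrib: dict[str, float] | None = None
) -> float:
    s1 = wang_svalues(dag, t1, contrib)
    s2 = wang_svalues(dag, t2, contrib)
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


def rel_term_sim(
    dag: OntologyDag, ic: TermInformationContent, t1: str, t2: str
) -> float:
    if t1 not in ic.p or t2 not in ic.p:
        logger.warning("term outside corpus support: %s", t1 if t1 not in ic.p else t2)
        return 0.0
    common = (dag.ancestors(t1) | {t1}) & (dag.ancestors(t2) | {t2})
    common = {t for t in common if t in ic.ic}
    if not common:
        return 0.0
    c_star = max(common, key=lambda t: (ic.ic[t], t))
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 0.0
    return (2.0 * ic.ic[c_star] / denom) * (1.0 - ic.p[c_star])


# --------------------------------------------------------------------------
# Gene similarity and expansion
# --------------------------------------------------------------------------

class GeneSimilarity:
    """Best-match-average gene similarity over direct annotations."""

    def __init__(
        self,
        dag: OntologyDag,
        corpus: AnnotationCorpus,
        measure: str = "wang",
        contrib: dict[str, float] | None = None,
    ):
        if measure not in ("wang", "rel"):
            raise ValueError(f"unknown measure {measure!r}")
        self.dag = dag
        self.corpus = corpus
        self.measure = measure
        self.contrib = contrib or DEFAULT_CONTRIB
        self._ic = None
        self._term_cache: dict[tuple[str, str], float] = {}

    @property
    def ic(self) -> TermInformationContent:
        if self._ic is None:
            self._ic = TermInformationContent.from_corpus(self.corpus, self.dag)
        return self._ic

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        hit = self._term_cache.get(key)
        if hit is None:
            if self.measure == "wang":
                hit = wang_term_sim(self.dag, t1, t2, self.contrib)
            else:
                hit = rel_term_sim(self.dag, self.ic, t1, t2)
            self._term_cache[key] = hit
        return hit

    def gene_sim(self, g_a: str, g_b: str) -> float:
        ta = self.corpus.gene_terms.get(g_a) or set()
        tb = self.corpus.gene_terms.get(g_b) or set()
        if not ta or not tb:
            raise ValueError(f"gene without annotations: {g_a if not ta else g_b}")
        best_a = [max(self.term_sim(t, u) for u in tb) for t in ta]
        best_b = [max(self.term_sim(u, t) for t in ta) for u in tb]
        return (float(np.mean(best_a)) + float(np.mean(best_b))) / 2.0


def gene_sim(
    g_a: str, g_b: str, corpus: AnnotationCorpus, dag: OntologyDag,
    measure: str = "wang",
) -> float:
    return GeneSimilarity(dag, corpus, measure).gene_sim(g_a, g_b)


@dataclass
class ExpansionResult:
    """g2 ⊇ g1 with, per added gene, its best seed and similarity."""

    g1: set[str]
    g2: set[str]
    similarity_of: dict[str, tuple[str, float]]


def expand_gene_set(
    g1: set[str],
    corpus: AnnotationCorpus,
    dag: OntologyDag,
    measure: str = "wang",
    threshold: float = 0.2,
    top_k: int | None = None,
) -> ExpansionResult:
    """Expand g1 with every annotated gene whose best similarity against a
    seed reaches the threshold; optional top_k caps the number added."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    sim = GeneSimilarity(dag, corpus, measure)
    seeds = [g for g in g1 if corpus.gene_terms.get(g)]
    skipped = g1 - set(seeds)
    if skipped:
        logger.warning("expansion: %d unannotated seed(s) skipped: %s",
                       len(skipped), sorted(skipped))
    if not seeds:
        raise ValueError("no annotated seed genes to expand from")
    added: dict[str, tuple[str, float]] = {}
    for gene in corpus.genes:
        if gene in g1 or not corpus.gene_terms.get(gene):
            continue
        best_seed, best = None, -1.0
        for s in seeds:
            v = sim.gene_sim(gene, s)
            if v > best:
                best_seed, best = s, v
        if best >= threshold:
            added[gene] = (best_seed, best)
    if top_k is not None and len(added) > top_k:
        keep = sorted(added, key=lambda g: (-added[g][1], g))[:top_k]
        added = {g: added[g] for g in keep}
    return ExpansionResult(g1=set(g1), g2=set(g1) | set(added), similarity_of=added)


def genes_for_process(
    term: str, corpus: AnnotationCorpus, dag: OntologyDag
) -> set[str]:
    """All genes whose propagated annotations include the term (resolved by
    exact ID, else exact name; ambiguous names raise with candidates)."""
    if term in dag:
        tid = term
    else:
        matches = [t for t, n in dag.names.items() if n == term]
        if not matches:
            low = term.casefold()
            matches = [t for t, n in dag.names.items() if n.casefold() == low]
        if not matches:
            raise KeyError(f"no term with ID or name {term!r}")
        if len(matches) > 1:
            raise AmbiguousTermError(term, sorted(matches))
        tid = matches[0]
    return {g for g, terms in corpus.propagated.items() if tid in terms}
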