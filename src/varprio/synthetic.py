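"""Self-contained synthetic fixtures with planted disease signal.

The generator emulates, at desk scale, the three data families the pipeline
needs: (b) an annotation store — a toy genome of genes tiled on disjoint
intervals, SNPs placed uniformly within each gene's flanking window, and
per-feature annotation tracks; (c) a toy ontology DAG with gene
annotations arranged so genes of the same disease are semantically close;
(d) per-disease benchmarks (gene set + certified SNP set).

The planted signal is a two-rate model on the informative binary features:
certified SNPs carry each informative feature at rate p1 (default 0.8),
background SNPs at rate p0 (default 0.2); noise features fire at p0 for
everyone.  This is the simplest signal the linear score can exploit, so
weight recovery by the GA is well-posed.  An optional continuous variant
(shifted Gaussians through min-max scaling) sits behind a flag.

Everything is deterministic under the seed; identical seeds produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation_store import GeneRecord, GenomicInterval, SnpRecord
from .registry import FeatureDefinition, FeatureRegistry

LOCALIZATION_CLASSES = [
    ("intron", 0.50),
    ("intergenic", 0.20),
    ("near-gene", 0.10),
    ("UTR-3", 0.05),
    ("UTR-5", 0.05),
    ("missense", 0.05),
    ("start codon", 0.03),
    ("frame shift", 0.02),
]
ALLELES = ["A/C", "A/G", "A/T", "C/G", "C/T", "G/T"]

LOCALIZATION_SCORES = {
    "frame shift": 1.0, "missense": 0.9, "start codon": 0.85,
    "UTR-3": 0.6, "UTR-5": 0.6, "near-gene": 0.4,
    "intron": 0.2, "intergenic": 0.1, "unknown": 0.1,
}


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic world."""

    n_diseases: int = 16
    genes_per_disease: int = 3
    n_background_genes: int = 6
    snps_per_gene: int = 40
    n_features: int = 31
    n_informative: int = 5
    p0: float = 0.2                  # background informative-feature rate
    p1: float = 0.8                  # certified informative-feature rate
    certified_per_disease: int = 10
    flank_bp: int = 100_000
    gene_length: int = 20_000
    gene_spacing: int = 250_000
    ontology_depth: int = 3
    ontology_branching: int = 3
    continuous_informative: bool = False
    disease_gene_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p0 < self.p1 <= 1.0:
            raise ValueError("need 0 <= p0 < p1 <= 1")
        for name in ("n_diseases", "genes_per_disease", "snps_per_gene",
                     "n_features", "n_informative", "certified_per_disease"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_features < self.n_informative + 2:
            raise ValueError("n_features must cover informative + MAF + Localization")
        if self.ontology_depth < 2:
            raise ValueError("ontology_depth must be >= 2")
        if self.gene_spacing < self.gene_length + 2 * self.flank_bp:
            raise ValueError("gene_spacing too small: flanking windows would overlap")

    @property
    def n_genes(self) -> int:
        return self.n_diseases * self.genes_per_disease + self.n_background_genes

    @property
    def informative_features(self) -> list[str]:
        return [f"inf_{i + 1:02d}" for i in range(self.n_informative)]

    @property
    def noise_features(self) -> list[str]:
        n_noise = self.n_features - self.n_informative - 2
        return [f"noise_{i + 1:02d}" for i in range(n_noise)]


@dataclass
class World:
    """Fully materialized synthetic dataset (pre-serialization)."""

    spec: SimulationSpec
    genes: list[GeneRecord]
    snps: list[SnpRecord]
    disease_genes: dict[str, list[GeneRecord]]
    certified: dict[str, set[str]]
    feature_values: dict[str, dict[str, object]]   # feature -> rsid -> raw
    registry: FeatureRegistry
    ontology_terms: list[tuple[str, str, int]]     # (term_id, name, level)
    ontology_edges: list[tuple[str, str, str]]     # (child, parent, type)
    gene_annotations: dict[str, set[str]] = field(default_factory=dict)


def build_world(spec: SimulationSpec) -> World:
    """Materialize the synthetic world deterministically from the spec."""
    rng = np.random.default_rng(spec.seed)

    # -- genes on disjoint tiles of one chromosome -------------------------
    genes = []
    for i in range(spec.n_genes):
        start = 100_000 + i * spec.gene_spacing
        genes.append(GeneRecord(
            gene_id=i + 1,
            symbol=f"G{i + 1:03d}",
            aliases=frozenset({f"ALIAS{i + 1:03d}"}),
            locus=GenomicInterval("chr1", start, start + spec.gene_length, "+"),
        ))

    # -- disease gene panels (disjoint unless overlap requested) -----------
    disease_genes: dict[str, list[GeneRecord]] = {}
    for d in range(spec.n_diseases):
        panel = genes[d * spec.genes_per_disease:(d + 1) * spec.genes_per_disease]
        if spec.disease_gene_overlap > 0 and d > 0:
            n_shared = int(round(spec.disease_gene_overlap * spec.genes_per_disease))
            prev = disease_genes[f"disease_{d:02d}"]
            panel = prev[:n_shared] + panel[n_shared:]
        disease_genes[f"disease_{d + 1:02d}"] = panel

    # -- SNPs uniform within each gene's flanking window --------------------
    snps: list[SnpRecord] = []
    gene_snps: dict[int, list[str]] = {}
    loc_labels = [c for c, _ in LOCALIZATION_CLASSES]
    loc_probs = [p for _, p in LOCALIZATION_CLASSES]
    serial = 1_000_001
    for g in genes:
        lo = max(0, g.locus.start - spec.flank_bp)
        hi = g.locus.end + spec.flank_bp
        positions = np.sort(rng.integers(lo, hi, size=spec.snps_per_gene))
        rsids = []
        for pos in positions:
            rsid = f"rs{serial}"
            serial += 1
            snps.append(SnpRecord(
                rsid=rsid,
                locus=GenomicInterval("chr1", int(pos), int(pos) + 1, "+"),
                alleles=ALLELES[int(rng.integers(len(ALLELES)))],
                function_class=loc_labels[
                    int(rng.choice(len(loc_labels), p=loc_probs))
                ],
            ))
            rsids.append(rsid)
        gene_snps[g.gene_id] = rsids

    # -- certified SNPs per disease (subset of the panel's SNPs) -----------
    certified: dict[str, set[str]] = {}
    for d_id, panel in disease_genes.items():
        pool = [r for g in panel for r in gene_snps[g.gene_id]]
        picks = rng.choice(len(pool), size=spec.certified_per_disease, replace=False)
        certified[d_id] = {pool[i] for i in sorted(picks)}
    all_certified = set().union(*certified.values())

    # -- feature tracks with the planted two-rate signal -------------------
    feature_values: dict[str, dict[str, object]] = {}
    feature_values["Localization"] = {s.rsid: s.function_class for s in snps}
    feature_values["MAF"] = {
        s.rsid: round(float(rng.uniform(0.01, 0.5)), 4) for s in snps
    }
    for name in spec.informative_features:
        if spec.continuous_informative:
            vals = {}
            for s in snps:
                mu = 0.7 if s.rsid in all_certified else 0.3
                vals[s.rsid] = round(float(np.clip(rng.normal(mu, 0.15), 0, 1)), 4)
            feature_values[name] = vals
        else:
            feature_values[name] = {
                s.rsid: int(rng.random() < (spec.p1 if s.rsid in all_certified else spec.p0))
                for s in snps
            }
    for name in spec.noise_features:
        feature_values[name] = {
            s.rsid: int(rng.random() < spec.p0) for s in snps
        }

    # -- registry ------------------------------------------------------------
    feats = [
        FeatureDefinition("MAF", "SNPs and Genes", "continuous",
                          weight=0.5, value_range=(0.0, 0.5)),
        FeatureDefinition("Localization", "SNPs and Genes", "categorical",
                          weight=0.5, category_scores=dict(LOCALIZATION_SCORES)),
    ]
    kind = "continuous" if spec.continuous_informative else "binary"
    rng_range = (0.0, 1.0) if spec.continuous_informative else None
    for name in spec.informative_features:
        feats.append(FeatureDefinition(name, "Synthetic signal", kind,
                                       weight=0.5, value_range=rng_range))
    for name in spec.noise_features:
        feats.append(FeatureDefinition(name, "Synthetic noise", "binary", weight=0.5))
    registry = FeatureRegistry(feats)

    # -- toy ontology: rooted tree, is_a with periodic part_of edges --------
    terms: list[tuple[str, str, int]] = []
    edges: list[tuple[str, str, str]] = []
    counter = 1

    def new_term(name: str, level: int) -> str:
        nonlocal counter
        tid = f"VP:{counter:07d}"
        counter += 1
        terms.append((tid, name, level))
        return tid

    root = new_term("biological_process root", 0)
    frontier = [root]
    for level in range(1, spec.ontology_depth + 1):
        nxt = []
        for parent in frontier:
            for b in range(spec.ontology_branching):
                child = new_term(f"process {parent.split(':')[1]}.{b + 1} (level {level})", level)
                etype = "part_of" if (counter % 3 == 0) else "is_a"
                edges.append((child, parent, etype))
                nxt.append(child)
        frontier = nxt
    leaves = frontier

    # -- gene annotations: a distinct leaf pair per disease -----------------
    # Genes of one disease share {home, partner} (so within-disease
    # similarity is maximal) and no two diseases share the full pair, so
    # between-disease similarity stays strictly lower.
    if spec.n_diseases > len(leaves):
        raise ValueError("not enough ontology leaves for distinct disease homes")
    gene_annotations: dict[str, set[str]] = {}
    for d_idx, (d_id, panel) in enumerate(disease_genes.items()):
        home = leaves[d_idx]
        partner = leaves[(d_idx + spec.n_diseases) % len(leaves)]
        ann = {home} if partner == home else {home, partner}
        for g in panel:
            gene_annotations[str(g.gene_id)] = set(ann)
    for g in genes[spec.n_diseases * spec.genes_per_disease:]:
        ann = {leaves[int(rng.integers(len(leaves)))]}
        gene_annotations[str(g.gene_id)] = ann

    return World(
        spec=spec, genes=genes, snps=snps, disease_genes=disease_genes,
        certified=certified, feature_values=feature_values, registry=registry,
        ontology_terms=terms, ontology_edges=edges,
        gene_annotations=gene_annotations,
    )


# --------------------------------------------------------------------------
# Serialization to the reader formats of the other modules
# --------------------------------------------------------------------------

def simulate_store(spec: SimulationSpec, outdir: str | Path,
                   world: World | None = None) -> dict[str, Path]:
    """Write gene table, SNP table, feature tracks, registry, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = world or build_world(spec)
    paths: dict[str, Path] = {}

    genes_path = outdir / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tsymbol\taliases\tchrom\tstart\tend\tstrand\tcoordinate_convention\n")
        for g in world.genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{'|'.join(sorted(g.aliases))}\t"
                f"{g.locus.chrom}\t{g.locus.start}\t{g.locus.end}\t{g.locus.strand}\t"
                "0based-halfopen\n"
            )
    paths["genes"] = genes_path

    snps_path = outdir / "snps.tsv"
    with open(snps_path, "w") as fh:
        fh.write("rsid\tchrom\tstart\tend\tstrand\talleles\tfunction_class\n")
        for s in world.snps:
            fh.write(
                f"{s.rsid}\t{s.locus.chrom}\t{s.locus.start}\t{s.locus.end}\t"
                f"{s.locus.strand}\t{s.alleles}\t{s.function_class}\n"
            )
    paths["snps"] = snps_path

    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    pos_of = {s.rsid: s.locus for s in world.snps}
    for feat in world.registry:
        if feat.name == "Localization":
            continue  # carried by the SNP table's function_class column
        values = world.feature_values[feat.name]
        if feat.value_kind == "binary":
            track = tracks_dir / f"{feat.name}.bed"
            with open(track, "w") as fh:
                for s in world.snps:
                    if values.get(s.rsid):
                        loc = pos_of[s.rsid]
                        fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\n")
        else:
            track = tracks_dir / f"{feat.name}.tsv"
            with open(track, "w") as fh:
                fh.write("rsid\tvalue\n")
                for s in world.snps:
                    fh.write(f"{s.rsid}\t{values[s.rsid]}\n")
        paths[f"track:{feat.name}"] = track

    registry_path = outdir / "registry.yaml"
    world.registry.to_yaml(registry_path)
    paths["registry"] = registry_path

    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps({"spec": asdict(spec)}, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest
    return paths


def simulate_benchmarks(spec: SimulationSpec, outdir: str | Path,
                        world: World | None = None) -> dict[str, Path]:
    """Write one benchmark YAML per disease plus a disorder GMT category map.

    S is every SNP within the flanking window of the disease's genes;
    A ⊆ S holds by construction."""
    from .annotation_store import map_snps_to_genes
    from .ga import DiseaseBenchmark

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = world or build_world(spec)
    gene_map = map_snps_to_genes(world.snps, world.genes, spec.flank_bp)
    paths: dict[str, Path] = {}
    for d_id, panel in world.disease_genes.items():
        gene_ids = {g.gene_id for g in panel}
        S = sorted({r for g, r in gene_map.pairs if g in gene_ids})
        bench = DiseaseBenchmark(
            disease_id=d_id,
            genes={g.symbol for g in panel},
            S=S,
            A=set(world.certified[d_id]),
        )
        p = outdir / f"{d_id}.yaml"
        bench.to_yaml(p)
        paths[d_id] = p

    gmt = outdir / "disorders.gmt"
    with open(gmt, "w") as fh:
        for d_id, panel in world.disease_genes.items():
            members = "\t".join(str(g.gene_id) for g in panel)
            fh.write(f"{d_id}\tsynthetic disorder panel\t{members}\n")
    paths["disorders_gmt"] = gmt
    return paths


def simulate_ontology(spec: SimulationSpec, outdir: str | Path,
                      world: World | None = None) -> dict[str, Path]:
    """Write the toy OBO file and the gene->term annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = world or build_world(spec)

    obo = outdir / "ontology.obo"
    lines = ["format-version: 1.2", "ontology: varprio-toy", ""]
    parents: dict[str, list[tuple[str, str]]] = {}
    for c, p, t in world.ontology_edges:
        parents.setdefault(c, []).append((p, t))
    for tid, name, _level in world.ontology_terms:
        lines += ["[Term]", f"id: {tid}", f"name: {name}",
                  "namespace: biological_process"]
        for p, etype in parents.get(tid, []):
            if etype == "is_a":
                lines.append(f"is_a: {p}")
            else:
                lines.append(f"relationship: part_of {p}")
        lines.append("")
    obo.write_text("\n".join(lines))

    ann = outdir / "annotations.tsv"
    with open(ann, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(world.gene_annotations, key=int):
            for term in sorted(world.gene_annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    return {"obo": obo, "annotations": ann}


def simulate_all(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture set under one directory."""
    outdir = Path(outdir)
    world = build_world(spec)
    paths = simulate_store(spec, outdir / "store", world)
    paths.update(simulate_benchmarks(spec, outdir / "benchmarks", world))
    paths.update(simulate_ontology(spec, outdir / "ontology", world))
    return paths
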