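"""Gene-centric annotation store.

Loads gene and SNP tables plus per-feature annotation tracks from plain-text
fixtures, associates SNPs to genes through symmetric flanking regions
(default 100 kb), and assembles the raw per-SNP feature matrix consumed by
the scoring module.

Coordinate convention: internal coordinates are 0-based half-open, matching
UCSC-style interval tracks.  TSV inputs may declare ``1based-inclusive`` per
row and are converted on load; VCF positions are converted from 1-based.
Missing annotations are stored as *absent*, never as zero — the distinction
collapses only at score normalization.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .errors import IntegrityError, NoInputGenesError, ParseError, RegistryError
from .registry import FeatureDefinition, FeatureRegistry

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", "unknown")
CONVENTIONS = ("0based-halfopen", "1based-inclusive")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self):
        if not self.chrom:
            raise IntegrityError("interval with empty chromosome label")
        if self.start < 0 or self.end <= self.start:
            raise IntegrityError(
                f"bad interval {self.chrom}:{self.start}-{self.end} "
                "(need start >= 0 and end > start)"
            )
        if self.strand not in STRANDS:
            raise IntegrityError(f"bad strand {self.strand!r}")

    def overlaps_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SnpRecord:
    rsid: str
    locus: GenomicInterval
    alleles: str
    function_class: str = "unknown"

    def __post_init__(self):
        if self.locus.end - self.locus.start != 1:
            raise IntegrityError(f"{self.rsid}: SNP locus must span exactly one base")

    @property
    def position(self) -> int:
        return self.locus.start


@dataclass(frozen=True)
class GeneRecord:
    gene_id: int
    symbol: str
    locus: GenomicInterval
    aliases: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.symbol:
            raise IntegrityError(f"gene {self.gene_id}: empty symbol")


class SnpTable(list):
    """List of SnpRecords that also carries the rejected-row count."""

    def __init__(self, records=(), n_rejected: int = 0):
        super().__init__(records)
        self.n_rejected = n_rejected


# --------------------------------------------------------------------------
# Loaders
# --------------------------------------------------------------------------

def _convert(start: int, end: int, convention: str, where: str) -> tuple[int, int]:
    if convention == "0based-halfopen":
        return start, end
    if convention == "1based-inclusive":
        # 1-based inclusive [s, e] == 0-based half-open [s-1, e)
        return start - 1, end
    raise ParseError(f"{where}: unknown coordinate_convention {convention!r}")


def load_gene_table(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Load genes from a BED4+ file or a headed TSV.

    TSV columns: gene_id, symbol, aliases (pipe-separated), chrom, start,
    end, strand, coordinate_convention.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen_ids: set[int] = set()

    def add(gene: GeneRecord, lineno: int):
        if gene.gene_id in seen_ids:
            raise IntegrityError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id}")
        seen_ids.add(gene.gene_id)
        genes.append(gene)

    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: BED4+ row needs >= 4 columns")
                try:
                    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
                strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "unknown"
                add(
                    GeneRecord(
                        gene_id=len(genes) + 1,
                        symbol=name,
                        locus=GenomicInterval(chrom, start, end, strand),
                    ),
                    lineno,
                )
    elif format == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, 2):
                try:
                    start, end = _convert(
                        int(row["start"]), int(row["end"]),
                        row.get("coordinate_convention", "0based-halfopen"),
                        f"{path}:{lineno}",
                    )
                    aliases = frozenset(
                        a.strip() for a in (row.get("aliases") or "").split("|") if a.strip()
                    )
                    strand = row.get("strand") or "unknown"
                    add(
                        GeneRecord(
                            gene_id=int(row["gene_id"]),
                            symbol=row["symbol"],
                            aliases=aliases,
                            locus=GenomicInterval(row["chrom"], start, end, strand),
                        ),
                        lineno,
                    )
                except (KeyError, ValueError, TypeError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed gene row ({exc})") from None
    else:
        raise ValueError(f"unknown gene table format {format!r}")
    return genes


def load_snp_table(path: str | Path, format: str = "tsv") -> SnpTable:
    """Load SNPs from a headed TSV or a VCF (ID field mandatory).

    Rows without an rs identifier are rejected; the count of rejected rows
    is logged and exposed as ``result.n_rejected`` (no silent drops).
    """
    path = Path(path)
    records: list[SnpRecord] = []
    seen: set[str] = set()
    rejected = 0

    def add(rec: SnpRecord, where: str):
        if rec.rsid in seen:
            raise IntegrityError(f"{where}: duplicate rsid {rec.rsid}")
        seen.add(rec.rsid)
        records.append(rec)

    if format == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, 2):
                rsid = (row.get("rsid") or "").strip()
                if not rsid:
                    rejected += 1
                    continue
                try:
                    locus = GenomicInterval(
                        row["chrom"], int(row["start"]), int(row["end"]),
                        row.get("strand") or "unknown",
                    )
                    add(
                        SnpRecord(
                            rsid=rsid,
                            locus=locus,
                            alleles=row.get("alleles", ""),
                            function_class=row.get("function_class", "unknown"),
                        ),
                        f"{path}:{lineno}",
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed SNP row ({exc})") from None
    elif format == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.id is None or rec.id == ".":
                    rejected += 1
                    continue
                alleles = "/".join(a for a in rec.alleles if a)
                fc = rec.info.get("FC", "unknown")
                if isinstance(fc, tuple):
                    fc = fc[0]
                add(
                    SnpRecord(
                        rsid=rec.id,
                        locus=GenomicInterval(rec.chrom, rec.start, rec.start + 1),
                        alleles=alleles,
                        function_class=str(fc),
                    ),
                    f"{path}:{rec.pos}",
                )
    else:
        raise ValueError(f"unknown SNP table format {format!r}")

    if rejected:
        logger.warning("%s: rejected %d row(s) without an rs identifier", path, rejected)
    return SnpTable(records, n_rejected=rejected)


def resolve_gene_ids(
    tokens: str, genes: list[GeneRecord]
) -> tuple[list[GeneRecord], list[str]]:
    """Resolve comma-separated identifiers against the gene store.

    Each token is matched case-insensitively against gene_id, then symbol,
    then aliases (in that priority).  Unmatched tokens are returned, never
    silently dropped; if nothing resolves a NoInputGenesError is raised.
    """
    items = [t.strip() for t in tokens.split(",") if t.strip()]
    if not items:
        raise NoInputGenesError("empty gene token list")
    by_id = {str(g.gene_id): g for g in genes}
    by_symbol = {g.symbol.casefold(): g for g in genes}
    by_alias: dict[str, GeneRecord] = {}
    for g in genes:
        for a in g.aliases:
            by_alias.setdefault(a.casefold(), g)

    resolved, unresolved = [], []
    for tok in items:
        key = tok.casefold()
        gene = by_id.get(tok) or by_symbol.get(key) or by_alias.get(key)
        if gene is None:
            unresolved.append(tok)
        else:
            resolved.append(gene)
    if not resolved:
        raise NoInputGenesError(f"no input genes: none of {items} resolved")
    return resolved, unresolved


# --------------------------------------------------------------------------
# SNP <-> gene association through flanking regions
# --------------------------------------------------------------------------

@dataclass
class GeneSnpMap:
    """Associations gene_id <-> rsid under a flanking distance."""

    pairs: set[tuple[int, str]]
    flank_bp: int

    def genes_of(self, rsid: str) -> set[int]:
        return {g for g, r in self.pairs if r == rsid}

    def snps_of(self, gene_id: int) -> set[str]:
        return {r for g, r in self.pairs if g == gene_id}

    def rsid_to_genes(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = defaultdict(set)
        for g, r in self.pairs:
            out[r].add(g)
        return dict(out)


def map_snps_to_genes(
    snps: list[SnpRecord], genes: list[GeneRecord], flank_bp: int = 100_000
) -> GeneSnpMap:
    """Pair each SNP with every gene whose interval, extended by flank_bp on
    both sides (clipped at 0), covers the SNP position.  Strand is ignored;
    a SNP may map to several genes.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        lo = max(0, g.locus.start - flank_bp)
        hi = g.locus.end + flank_bp
        trees[g.locus.chrom].addi(lo, hi, g.gene_id)
    pairs: set[tuple[int, str]] = set()
    for s in snps:
        tree = trees.get(s.locus.chrom)
        if tree is None:
            continue
        for iv in tree.at(s.position):
            pairs.add((iv.data, s.rsid))
    return GeneSnpMap(pairs=pairs, flank_bp=flank_bp)


# --------------------------------------------------------------------------
# Feature tracks and the raw feature matrix
# --------------------------------------------------------------------------

def load_feature_track(
    path: str | Path,
    feature: FeatureDefinition,
    snps: list[SnpRecord],
) -> dict[str, object]:
    """Load one feature's raw values for the given SNPs.

    Interval (BED) tracks yield per-SNP membership (1 inside any interval,
    0 otherwise); a 4th BED column is read as the tissue/cell-line context.
    Value (TSV) tracks carry explicit ``rsid<TAB>value[<TAB>context]`` rows.
    Contextual features return ``{context: value}`` dicts with every context
    observed in the track filled in (absent membership = 0).
    """
    path = Path(path)
    if path.suffix == ".bed":
        return _load_bed_track(path, feature, snps)
    return _load_tsv_track(path, feature)


def _load_bed_track(path, feature, snps):
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    contexts: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED row needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            ctx = parts[3] if len(parts) >= 4 and feature.context_axis else None
            if ctx:
                contexts.add(ctx)
            trees[chrom].addi(start, end, ctx)
    values: dict[str, object] = {}
    for s in snps:
        hits = trees.get(s.locus.chrom, IntervalTree()).at(s.position)
        if contexts:
            per_ctx = {c: 0 for c in sorted(contexts)}
            for iv in hits:
                if iv.data:
                    per_ctx[iv.data] = 1
            if any(per_ctx.values()):
                values[s.rsid] = per_ctx
        elif hits:
            values[s.rsid] = 1
        else:
            values[s.rsid] = 0
    return values


def _load_tsv_track(path, feature):
    values: dict[str, object] = {}
    contexts: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("rsid\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: track row needs rsid and value")
            rsid, raw = parts[0], parts[1]
            value = raw if feature.value_kind == "categorical" else float(raw)
            if len(parts) >= 3 and parts[2]:
                contexts.add(parts[2])
                values.setdefault(rsid, {})[parts[2]] = value
            else:
                values[rsid] = value
    if contexts:  # fill absent contexts with 0 so the axis is rectangular
        for rsid, v in values.items():
            if isinstance(v, dict):
                for c in contexts:
                    v.setdefault(c, 0)
    return values


def track_from_function_class(snps: list[SnpRecord]) -> dict[str, str]:
    """Pseudo-track mapping each SNP to its localization class."""
    return {s.rsid: s.function_class for s in snps}


@dataclass
class FeatureMatrix:
    """Raw per-SNP annotations, |snps| x |registry|; missing values absent."""

    snps: list[str]
    features: list[str]
    values: dict[tuple[str, str], object] = field(default_factory=dict)

    def get(self, rsid: str, feature: str, default=None):
        return self.values.get((rsid, feature), default)

    @property
    def snps_set(self) -> set[str]:
        cached = self.__dict__.get("_snps_set")
        if cached is None or len(cached) != len(self.snps):
            cached = set(self.snps)
            self.__dict__["_snps_set"] = cached
        return cached

    def set(self, rsid: str, feature: str, value) -> None:
        if feature not in self.features:
            raise RegistryError(f"unknown feature {feature!r}")
        self.values[(rsid, feature)] = value

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.snps), len(self.features)

    # -- TSV round trip (long format: rsid, feature, context, value) -------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rsid\tfeature\tcontext\tvalue\n")
            for rsid in self.snps:
                for feat in self.features:
                    v = self.values.get((rsid, feat))
                    if v is None:
                        continue
                    if isinstance(v, dict):
                        for ctx in sorted(v):
                            fh.write(f"{rsid}\t{feat}\t{ctx}\t{v[ctx]}\n")
                    else:
                        fh.write(f"{rsid}\t{feat}\t\t{v}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, snps: list[str], features: list[str],
        registry: FeatureRegistry | None = None,
    ) -> "FeatureMatrix":
        m = cls(snps=list(snps), features=list(features))
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                rsid, feat, ctx, raw = line.rstrip("\n").split("\t")
                kind = registry[feat].value_kind if registry else None
                value = raw if kind == "categorical" else _num(raw)
                if ctx:
                    cell = m.values.setdefault((rsid, feat), {})
                    cell[ctx] = value
                else:
                    m.values[(rsid, feat)] = value
        return m


def _num(raw: str):
    x = float(raw)
    return int(x) if x.is_integer() else x


def build_feature_matrix(
    snps: list[SnpRecord],
    tracks: dict[str, dict[str, object]],
    registry: FeatureRegistry,
) -> FeatureMatrix:
    """Assemble the raw feature matrix from loaded tracks.

    ``tracks`` maps feature name -> per-rsid raw values.  Every referenced
    feature must be registered.  SNPs absent from a track stay missing —
    missingness is preserved here and only becomes a 0 score downstream.
    """
    for name in tracks:
        if name not in registry:
            raise RegistryError(f"track references unregistered feature {name!r}")
    matrix = FeatureMatrix(snps=[s.rsid for s in snps], features=registry.names)
    known = matrix.snps_set
    for name, per_snp in tracks.items():
        for rsid, value in per_snp.items():
            if rsid in known:
                matrix.values[(rsid, name)] = value
    return matrix
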