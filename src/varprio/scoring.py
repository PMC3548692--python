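"""SNP scoring: normalize raw annotations to [0, 1] and combine linearly.

Each SNP i carries a feature-score vector f = (f_1 ... f_n), f_j in [0, 1].
Its prioritization score is the weighted sum

    sigma_i(w) = w_1 f_1 + w_2 f_2 + ... + w_n f_n,   w_j in [0, 1],

over the user-selected feature subset (deselected features contribute 0).
Normalization rules: binary membership maps to {0, 1}; categorical labels go
through the registry's ordinal category_scores; continuous values are
min-max scaled to the declared range and clipped; a missing annotation
scores 0; a contextual (tissue/cell-line) value scores the selected
context, or the arithmetic mean over contexts when none is selected.

Ranking is deterministic: sigma descending, ties broken by rsid ascending.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation_store import FeatureMatrix, GeneSnpMap, SnpRecord
from .errors import ConfigurationError
from .registry import FeatureDefinition, FeatureRegistry


def normalize_feature(
    raw, feature: FeatureDefinition, context: str | None = None
) -> float:
    """Map one raw annotation value to a score in [0, 1]."""
    if raw is None:
        return 0.0
    if isinstance(raw, dict):  # contextual value: {context: raw}
        if context is not None:
            return normalize_feature(raw.get(context), feature)
        if not raw:
            return 0.0
        return float(
            np.mean([normalize_feature(v, feature) for v in raw.values()])
        )
    if feature.value_kind == "binary":
        return 1.0 if float(raw) != 0.0 else 0.0
    if feature.value_kind == "categorical":
        try:
            return float(feature.category_scores[raw])
        except KeyError:
            raise ConfigurationError(
                f"feature {feature.name!r}: label {raw!r} has no category score"
            ) from None
    lo, hi = feature.value_range
    return float(min(1.0, max(0.0, (float(raw) - lo) / (hi - lo))))


def feature_score_matrix(
    matrix: FeatureMatrix,
    registry: FeatureRegistry,
    contexts: dict[str, str] | None = None,
) -> np.ndarray:
    """Normalize the whole raw matrix: |snps| x |registry| float array."""
    contexts = contexts or {}
    out = np.zeros((len(matrix.snps), len(registry)), dtype=float)
    for j, feat in enumerate(registry):
        ctx = contexts.get(feat.name)
        for i, rsid in enumerate(matrix.snps):
            raw = matrix.values.get((rsid, feat.name))
            if raw is not None:
                out[i, j] = normalize_feature(raw, feat, context=ctx)
    return out


def score_snp(
    f: np.ndarray, w: np.ndarray, selected: np.ndarray | list[int] | None = None
) -> float:
    """sigma = sum over selected features of w_j * f_j."""
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    if f.shape != w.shape:
        raise ValueError(f"misaligned vectors: f has {f.shape}, w has {w.shape}")
    if selected is None:
        return float(f @ w)
    sel = np.asarray(selected)
    return float(f[sel] @ w[sel])


def score_matrix(
    F: np.ndarray, w: np.ndarray, selected: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized sigma for every row of a normalized feature matrix."""
    F = np.asarray(F, dtype=float)
    w = np.asarray(w, dtype=float)
    if F.shape[1] != w.shape[0]:
        raise ValueError(f"misaligned: matrix has {F.shape[1]} features, w has {w.shape[0]}")
    if selected is not None:
        sel = np.asarray(selected)
        return F[:, sel] @ w[sel]
    return F @ w


def selection_mask(registry: FeatureRegistry, selected: list[str] | None) -> np.ndarray:
    """Indices of selected feature names (all when selected is None)."""
    if selected is None:
        return np.arange(len(registry))
    unknown = [s for s in selected if s not in registry]
    if unknown:
        raise ConfigurationError(f"selected features not in registry: {unknown}")
    wanted = set(selected)
    return np.array([j for j, n in enumerate(registry.names) if n in wanted], dtype=int)


@dataclass(frozen=True)
class ScoredSnp:
    rsid: str
    sigma: float
    feature_scores: tuple[float, ...] = ()


@dataclass
class RankedList:
    """SNPs in descending sigma order; equal scores ordered by rsid."""

    entries: list[ScoredSnp]
    tie_rule: str = "sigma desc, rsid asc"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]


def rank_snps(scored: list[ScoredSnp]) -> RankedList:
    """Deterministic ranking: sigma descending, then rsid ascending."""
    return RankedList(sorted(scored, key=lambda e: (-e.sigma, e.rsid)))


def percentile_cut(ranked: RankedList, percentile: float) -> RankedList:
    """Keep the top ceil(percentile/100 * N) entries."""
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    if not ranked.entries:
        raise ValueError("cannot cut an empty ranked list")
    keep = math.ceil(percentile / 100 * len(ranked.entries))
    return RankedList(ranked.entries[:keep], tie_rule=ranked.tie_rule)


def score_and_rank(
    matrix: FeatureMatrix,
    registry: FeatureRegistry,
    weights: np.ndarray | None = None,
    selected: list[str] | None = None,
    contexts: dict[str, str] | None = None,
) -> RankedList:
    """Normalize, score with the given (default: registry) weights, rank."""
    w = np.asarray(weights if weights is not None else registry.weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ConfigurationError("weights must lie in [0, 1]")
    F = feature_score_matrix(matrix, registry, contexts=contexts)
    sel = selection_mask(registry, selected)
    sigma = score_matrix(F, w, sel)
    scored = [
        ScoredSnp(rsid, float(s), tuple(F[i, sel]))
        for i, (rsid, s) in enumerate(zip(matrix.snps, sigma))
    ]
    return rank_snps(scored)


def write_ranked_table(
    ranked: RankedList,
    path: str | Path,
    snps: dict[str, SnpRecord] | None = None,
    gene_map: GeneSnpMap | None = None,
    matrix: FeatureMatrix | None = None,
    registry: FeatureRegistry | None = None,
    selected: list[str] | None = None,
    compress: bool = False,
) -> Path:
    """Write the ranked output TSV: rsid, genes, chrom, position, sigma, and
    (when the raw matrix is supplied) one raw/score column pair per selected
    feature.  ``compress=True`` writes gzip alongside the plain text."""
    path = Path(path)
    feat_names = []
    if registry is not None:
        feat_names = selected if selected is not None else registry.names
    header = ["rsid", "genes", "chrom", "position", "sigma"]
    for n in feat_names:
        header += [f"{n} (raw)", f"{n} (score)"]
    rsid_genes = gene_map.rsid_to_genes() if gene_map else {}
    lines = ["\t".join(header)]
    for entry in ranked:
        rec = snps.get(entry.rsid) if snps else None
        genes = ";".join(str(g) for g in sorted(rsid_genes.get(entry.rsid, ())))
        row = [
            entry.rsid,
            genes,
            rec.locus.chrom if rec else "",
            str(rec.position) if rec else "",
            f"{entry.sigma:.6f}",
        ]
        for k, name in enumerate(feat_names):
            raw = matrix.values.get((entry.rsid, name)) if matrix else None
            row.append("" if raw is None else str(raw))
            score = entry.feature_scores[k] if k < len(entry.feature_scores) else ""
            row.append(f"{score:.6f}" if score != "" else "")
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    path.write_text(text)
    if compress:
        with gzip.open(path.with_suffix(path.suffix + ".gz"), "wt") as fh:
            fh.write(text)
    return path
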