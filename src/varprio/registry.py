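"""Feature registry: the catalogue of SNP annotation features.

Each feature is one biomolecular annotation contributing a normalized score
f in [0, 1] to the linear SNP score sigma = sum_i w_i * f_i.  The registry
records, per feature, how raw annotation values map to scores (binary
membership, an ordinal category map, or min-max scaling of a continuous
range), an optional tissue/cell-line context axis, and the default weight.

The packaged default registry (``data/default_features.yaml``) carries the
weights learned by the genetic-algorithm optimizer against the disease
benchmark panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, RegistryError

VALUE_KINDS = ("binary", "categorical", "continuous")


@dataclass(frozen=True)
class FeatureDefinition:
    """One scored SNP annotation feature."""

    name: str
    section: str
    value_kind: str
    weight: float = 0.5
    context_axis: str | None = None
    category_scores: dict[str, float] | None = None
    value_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.value_kind not in VALUE_KINDS:
            raise ConfigurationError(
                f"feature {self.name!r}: unknown value_kind {self.value_kind!r}"
            )
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"feature {self.name!r}: weight outside [0, 1]")
        if self.value_kind == "categorical":
            if not self.category_scores:
                raise ConfigurationError(
                    f"categorical feature {self.name!r} needs category_scores"
                )
            bad = {k: v for k, v in self.category_scores.items() if not 0 <= v <= 1}
            if bad:
                raise ConfigurationError(
                    f"feature {self.name!r}: category scores outside [0, 1]: {bad}"
                )
        if self.value_kind == "continuous":
            if self.value_range is None:
                raise ConfigurationError(
                    f"continuous feature {self.name!r} needs value_range"
                )
            lo, hi = self.value_range
            if not lo < hi:
                raise ConfigurationError(
                    f"feature {self.name!r}: value_range min must be < max"
                )


@dataclass
class FeatureRegistry:
    """Ordered collection of feature definitions with aligned default weights."""

    features: list[FeatureDefinition] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for f in self.features:
            if f.name in seen:
                raise ConfigurationError(f"duplicate feature name {f.name!r}")
            seen.add(f.name)
        self._by_name = {f.name: f for f in self.features}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureDefinition:
        try:
            return self._by_name[name]
        except KeyError:
            raise RegistryError(f"unknown feature {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def weights(self) -> "list[float]":
        return [f.weight for f in self.features]

    def with_weights(self, weights) -> "FeatureRegistry":
        """Return a copy carrying new default weights (aligned to order)."""
        if len(weights) != len(self.features):
            raise ConfigurationError(
                f"{len(weights)} weights for {len(self.features)} features"
            )
        from dataclasses import replace

        return FeatureRegistry(
            [replace(f, weight=float(w)) for f, w in zip(self.features, weights)]
        )

    # ---- I/O ------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc, source=str(path))

    @classmethod
    def _from_doc(cls, doc, source: str = "<registry>") -> "FeatureRegistry":
        if not isinstance(doc, dict) or "features" not in doc:
            raise ConfigurationError(f"{source}: registry file needs a 'features' list")
        feats = []
        for entry in doc["features"]:
            rng = entry.get("value_range")
            feats.append(
                FeatureDefinition(
                    name=str(entry["name"]),
                    section=str(entry.get("section", "")),
                    value_kind=str(entry["value_kind"]),
                    weight=float(entry.get("weight", 0.5)),
                    context_axis=entry.get("context_axis"),
                    category_scores=entry.get("category_scores"),
                    value_range=tuple(float(x) for x in rng) if rng else None,
                )
            )
        return cls(feats)

    def to_yaml(self, path: str | Path) -> None:
        doc = {"features": []}
        for f in self.features:
            entry = {
                "name": f.name,
                "section": f.section,
                "value_kind": f.value_kind,
                "weight": round(float(f.weight), 6),
            }
            if f.context_axis:
                entry["context_axis"] = f.context_axis
            if f.category_scores:
                entry["category_scores"] = dict(f.category_scores)
            if f.value_range:
                entry["value_range"] = [float(x) for x in f.value_range]
            doc["features"].append(entry)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def default_registry() -> FeatureRegistry:
    """The packaged registry with the learned default weights."""
    ref = resources.files("varprio").joinpath("data/default_features.yaml")
    doc = yaml.safe_load(ref.read_text())
    return FeatureRegistry._from_doc(doc, source="default_features.yaml")
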