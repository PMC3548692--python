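"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI lives in :mod:`varprio.cli`:
usage errors exit 2, data-integrity errors exit 3.
"""


class VarprioError(Exception):
    """Base class for all package errors."""


class ParseError(VarprioError):
    """A file could not be parsed; the message names the offending line."""


class IntegrityError(VarprioError):
    """Input data violates a structural invariant (duplicate IDs, cycles...)."""


class RegistryError(VarprioError):
    """A feature name or category label is unknown to the feature registry."""


class ConfigurationError(VarprioError):
    """An internally inconsistent configuration (e.g. GA pool sizes)."""


class NoInputGenesError(VarprioError):
    """None of the input tokens resolved against the gene store."""


class AmbiguousTermError(VarprioError):
    """An ontology term name matched more than one term; candidates attached."""

    def __init__(self, name: str, candidates: list[str]):
        super().__init__(f"term name {name!r} is ambiguous: {', '.join(candidates)}")
        self.candidates = candidates
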