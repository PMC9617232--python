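"""Exception hierarchy for pdscreen.

All errors raised by the library derive from :class:`PdscreenError` so callers
can catch the package's failures with a single except clause.
"""


class PdscreenError(Exception):
    """Base class for all pdscreen errors."""


class FormatError(PdscreenError):
    """A file could not be parsed in the expected on-disk format."""


class SchemaError(PdscreenError):
    """A landmark track does not satisfy the landmark schema."""


class IntegrityError(PdscreenError):
    """A table violates an integrity constraint (duplicates, missing label)."""


class InputError(PdscreenError):
    """An input violates an operation's precondition."""


class FeatureUndefinedError(PdscreenError):
    """A feature has no defined value for this input (e.g. all-pause audio)."""


class DegenerateGeometryError(PdscreenError):
    """Landmark geometry collapses (zero eye width, zero face width, ...)."""


class AssemblyError(PdscreenError):
    """Subjects are missing from a modality when assembling the feature table."""


class LeakageError(PdscreenError):
    """Train and validation cohorts share subjects."""
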