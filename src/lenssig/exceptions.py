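"""Exception hierarchy for lenssig.

Every user-facing failure mode raises a subclass of :class:`LenssigError`
so callers can catch pipeline errors without trapping programming bugs.
"""


class LenssigError(Exception):
    """Base class for all lenssig errors."""


class FormatError(LenssigError):
    """Malformed input file (duplicate ids, missing columns, bad header)."""


class ConsistencyError(LenssigError):
    """Metadata and matrix disagree (sample sets, missing labels)."""


class UnitError(LenssigError):
    """Operation applied to an expression matrix in the wrong unit."""


class DegenerateSampleError(LenssigError):
    """A sample column is unusable (e.g. all-zero under TPM conversion)."""


class ParameterError(LenssigError):
    """Parameter outside its documented domain."""


class SplitError(LenssigError):
    """Train/holdout split cannot satisfy its class-size requirements."""


class SelectionEmptyError(LenssigError):
    """A feature-selection stage produced an empty panel where one is required."""


class MetricError(LenssigError):
    """A performance metric is undefined for the given inputs."""
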