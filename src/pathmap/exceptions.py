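"""Exception hierarchy for pathmap."""


class PathmapError(ValueError):
    """Base class for all pathmap errors."""


class SingularDesignError(PathmapError):
    """Design matrix is rank deficient; names the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is singular: column {column!r} is "
                         "linearly dependent on the preceding columns")


class InsufficientDataError(PathmapError):
    """Fewer observations than free parameters."""


class InsufficientGroupsError(PathmapError):
    """A required group stratum is empty or too small."""


class AlignmentError(PathmapError):
    """Subject identifiers do not align across inputs."""


class ConfigError(PathmapError):
    """Invalid analysis configuration."""
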